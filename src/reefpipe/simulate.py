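"""Synthetic reef-monitoring data with known ground truth.

Three generators mirror the three input streams of the pipeline:

* ``simulate_temperature`` — seasonal + diurnal cosine signal with AR(1)
  noise, boxcar heatwaves and storm cold wakes at sub-daily sampling.
  A cold wake holds the full injected depth for one day and then recovers
  linearly, so the 7-day-background drop metric recovers the depth
  exactly on noiseless runs.
* ``simulate_meteo`` — station wind/rain baselines and a buoy wave
  baseline with exact injected storm-day values.
* ``simulate_benthic`` — Dirichlet-multinomial photo-point counts from
  per-area community compositions (transect-level overdispersion via the
  Dirichlet concentration), with a DHW-driven logistic bleaching layer
  on bleaching-potential OTUs.

Every generator is reproducible bit-for-bit under a fixed seed, and the
benthic generator emits a ground-truth manifest of the compositions and
bleaching probabilities actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TempSimConfig",
    "MeteoSimConfig",
    "BenthicSimConfig",
    "simulate_temperature",
    "simulate_meteo",
    "simulate_transect_counts",
    "simulate_benthic",
    "default_taxonomy",
    "default_benthic_config",
]


@dataclass(frozen=True)
class TempSimConfig:
    """Temperature-logger simulation settings.

    ``ar1_sd`` is the stationary (marginal) standard deviation of the
    AR(1) noise; innovations are scaled by sqrt(1 - rho^2) accordingly.
    ``heatwaves``: (start_date, duration_days, amplitude degC) boxcars.
    ``cold_wakes``: (start_date, depth degC, recovery_days); the full
    depth holds for one day, then decays linearly to zero.
    """

    site_id: str = "site-1"
    start: str = "2015-08-01"
    end: str = "2017-04-30"
    mean_temp: float = 26.0
    seasonal_amplitude: float = 3.0
    seasonal_peak_doy: int = 205  # late July
    diurnal_amplitude: float = 0.3
    diurnal_peak_hour: float = 14.0
    ar1_rho: float = 0.9
    ar1_sd: float = 0.0
    heatwaves: tuple[tuple[str, int, float], ...] = ()
    cold_wakes: tuple[tuple[str, float, int], ...] = ()
    sampling_interval: int = 30  # minutes
    seed: int = 0


@dataclass(frozen=True)
class MeteoSimConfig:
    """Meteorological simulation settings (5 stations, one wave buoy).

    Baselines are kept well below the storm thresholds (4 m/s, 50 mm,
    150 cm) so that only injected ``storm_days`` — (date, wind m/s,
    rain mm, wave cm), written identically at every station — flag.
    """

    start: str = "2015-08-01"
    end: str = "2017-04-30"
    n_stations: int = 5
    wind_mean: float = 2.5
    wind_sd: float = 0.5
    rain_scale: float = 3.0  # exponential daily totals, mm
    wave_mean: float = 80.0
    wave_sd: float = 15.0
    storm_days: tuple[tuple[str, float, float, float], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class BenthicSimConfig:
    """Benthic photo-point simulation settings.

    ``compositions`` maps each area to a Dirichlet concentration vector
    over the taxonomy's OTUs (order = taxonomy row order); per-transect
    compositions are drawn from it, so its total mass controls
    transect-level overdispersion. ``survey_multipliers`` scales the
    concentration of selected OTUs per survey (e.g. a macro-algae bloom).
    Bleaching: P(bleached) = logistic(beta0 + beta1 * DHW) on points of
    bleaching-potential OTUs; ``p_discolored`` applies to the remainder.
    """

    taxonomy: pd.DataFrame = None
    compositions: dict = None          # area -> np.ndarray concentration
    sites: dict = None                 # area -> list of site ids
    surveys: tuple[str, ...] = ("2015-08", "2016-04", "2016-09", "2016-10", "2017-04")
    survey_multipliers: dict = field(default_factory=dict)  # survey -> {otu_id: mult}
    transects: int = 5
    photos: int = 105
    points_per_photo: int = 50
    # defaults put ~6-7% of susceptible points bleached at DHW ~3 degC-weeks,
    # the regime a mild heat-stress season produces
    beta0: float = -5.0
    beta1: float = 0.75
    p_discolored: float = 0.0


def simulate_temperature(cfg: TempSimConfig) -> pd.DataFrame:
    """Generate a (site_id, timestamp, temp_c) logger series."""
    ts = pd.date_range(cfg.start, pd.Timestamp(cfg.end) + pd.Timedelta(days=1),
                       freq=f"{cfg.sampling_interval}min", inclusive="left")
    t_days = (ts - ts[0]) / pd.Timedelta(days=1)
    doy = ts.dayofyear + ts.hour / 24.0
    hour = ts.hour + ts.minute / 60.0

    temp = np.full(len(ts), cfg.mean_temp, dtype=float)
    temp += cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )
    temp += cfg.diurnal_amplitude * np.cos(
        2 * np.pi * (hour - cfg.diurnal_peak_hour) / 24.0
    )

    for start, duration, amplitude in cfg.heatwaves:
        d0 = (pd.Timestamp(start) - ts[0]) / pd.Timedelta(days=1)
        temp += np.where((t_days >= d0) & (t_days < d0 + duration), amplitude, 0.0)

    for start, depth, recovery in cfg.cold_wakes:
        d0 = (pd.Timestamp(start) - ts[0]) / pd.Timedelta(days=1)
        since = t_days - d0
        pulse = np.zeros(len(ts))
        hold = (since >= 0) & (since < 1)
        ramp = (since >= 1) & (since < 1 + recovery)
        pulse[hold] = -depth
        pulse[ramp] = -depth * (1.0 - (since[ramp] - 1.0) / recovery)
        temp += pulse

    if cfg.ar1_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        innov_sd = cfg.ar1_sd * np.sqrt(1.0 - cfg.ar1_rho**2)
        eps = rng.normal(0.0, innov_sd, size=len(ts))
        noise = np.empty(len(ts))
        noise[0] = rng.normal(0.0, cfg.ar1_sd)
        for i in range(1, len(ts)):
            noise[i] = cfg.ar1_rho * noise[i - 1] + eps[i]
        temp += noise

    return pd.DataFrame({"site_id": cfg.site_id, "timestamp": ts, "temp_c": temp})


def simulate_meteo(cfg: MeteoSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (station_series, wave_series) daily tables.

    Station series: station_id, timestamp (daily), wind_ms, rain_mm.
    Wave series: date, wave_cm. Injected storm-day values overwrite the
    baseline draws exactly, at every station.
    """
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(cfg.start, cfg.end, freq="D")
    nd = len(dates)
    storm = {pd.Timestamp(d): (w, r, v) for d, w, r, v in cfg.storm_days}

    frames = []
    for s in range(cfg.n_stations):
        wind = np.clip(rng.normal(cfg.wind_mean, cfg.wind_sd, nd), 0.0, None)
        rain = rng.exponential(cfg.rain_scale, nd)
        frames.append(pd.DataFrame({
            "station_id": f"station-{s + 1}", "timestamp": dates,
            "wind_ms": wind, "rain_mm": rain,
        }))
    stations = pd.concat(frames, ignore_index=True)
    wave = pd.DataFrame({
        "date": dates,
        "wave_cm": np.clip(rng.normal(cfg.wave_mean, cfg.wave_sd, nd), 0.0, None),
    })
    for d, (w, r, v) in storm.items():
        stations.loc[stations["timestamp"] == d, ["wind_ms", "rain_mm"]] = (w, r)
        wave.loc[wave["date"] == d, "wave_cm"] = v
    return stations, wave


def default_taxonomy(n_scleractinian: int = 18, n_algae: int = 8,
                     n_octocoral: int = 5, n_other: int = 9) -> pd.DataFrame:
    """A compact synthetic OTU taxonomy covering all groups and morphotypes.

    Scleractinian and octocoral OTUs cycle through the coral growth-form
    classes; algae include turf, macro-algae and calcareous classes;
    "other" spans hydrozoan/zoantharian/sea-anemone/sponge/ascidian/
    other-life plus abiotic substrate classes. Symbiodiniaceae-associated
    groups (corals, octocorals, hydrozoans, zoantharians, sea anemones)
    carry bleaching potential.
    """
    rows = []
    coral_morphs = ["encrusting", "branching", "massive", "foliose", "tabulate"]
    for i in range(n_scleractinian):
        rows.append((f"scler-{i + 1:02d}", "scleractinian", "Scleractinian",
                     coral_morphs[i % len(coral_morphs)], True))
    octo_morphs = ["clustered", "columnar", "bushy", "digitate", "lobate"]
    for i in range(n_octocoral):
        rows.append((f"octo-{i + 1:02d}", "octocoral", "Octocoral",
                     octo_morphs[i % len(octo_morphs)], True))
    algae_cats = (["Turf"] * 2 + ["Macro-algae"] * 4 + ["Encrusting Coralline Algae"] * 2)
    for i in range(n_algae):
        rows.append((f"alga-{i + 1:02d}", "algae", algae_cats[i % len(algae_cats)],
                     None, False))
    other = [
        ("hydro-01", "hydrozoan", "Hydrozoan", "branching", True),
        ("zoa-01", "zoantharian", "Zoantharian", None, True),
        ("anem-01", "sea_anemone", "Sea Anemone", None, True),
        ("spon-01", "sponge", "Sponge", None, False),
        ("asci-01", "ascidian", "Ascidian", None, False),
        ("other-01", "other_life", "Other Life", None, False),
        ("bare-01", "abiotic", "Bare", None, False),
        ("unst-01", "abiotic", "Unstable Substrate", None, False),
        ("unkn-01", "abiotic", "Unknown", None, False),
    ]
    rows.extend(other[:n_other])
    tax = pd.DataFrame(rows, columns=["otu_id", "group", "major_category",
                                      "morphotype", "bleaching_potential"])
    tax.insert(1, "label", tax["otu_id"].str.replace("-", " ").str.title())
    return tax


def _base_concentration(tax: pd.DataFrame, total_mass: float = 60.0) -> np.ndarray:
    """Concentration vector loosely mimicking a turf-dominated reef:
    turf ~38%, encrusting coral ~18%, octocoral ~7%, the rest spread."""
    w = np.full(len(tax), 1.0)
    turf = (tax["major_category"] == "Turf").to_numpy()
    w[turf] = 38.0 / turf.sum()
    enc = ((tax["group"] == "scleractinian")
           & (tax["morphotype"] == "encrusting")).to_numpy()
    w[enc] = 18.0 / enc.sum()
    octo = (tax["group"] == "octocoral").to_numpy()
    w[octo] = 7.0 / octo.sum()
    w[(tax["major_category"] == "Bare").to_numpy()] = 6.0
    w[(tax["major_category"] == "Unstable Substrate").to_numpy()] = 4.0
    return w / w.sum() * total_mass


def default_benthic_config(**overrides) -> BenthicSimConfig:
    """Study-layout benthic scenario: 3 + 3 + 5 sites in three areas,
    five surveys, 5 transects x 105 photos x 50 points, with mild
    between-area composition differences."""
    tax = default_taxonomy()
    base = _base_concentration(tax)
    east = base.copy()
    east[(tax["group"] == "scleractinian").to_numpy()] *= 0.6
    east[(tax["major_category"] == "Turf").to_numpy()] *= 1.3
    nanwan = base.copy()
    nanwan[(tax["group"] == "octocoral").to_numpy()] *= 1.8
    cfg = dict(
        taxonomy=tax,
        compositions={"west_coast": base, "east_coast": east, "nanwan": nanwan},
        sites={
            "west_coast": ["houwan", "wanlitung", "dabaisha"],
            "east_coast": ["longkeng", "jialeshui", "chufengbi"],
            "nanwan": ["leidashih", "outlet", "houbihu", "tiaoshih", "sangjiaowan"],
        },
    )
    cfg.update(overrides)
    return BenthicSimConfig(**cfg)


def _alpha_for(cfg: BenthicSimConfig, area: str, survey: str) -> np.ndarray:
    alpha = np.asarray(cfg.compositions[area], dtype=float).copy()
    mults = cfg.survey_multipliers.get(survey, {})
    if mults:
        otus = cfg.taxonomy["otu_id"].to_numpy()
        for otu, m in mults.items():
            alpha[otus == otu] *= m
    return alpha


def simulate_transect_counts(
    cfg: BenthicSimConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Transect x OTU count matrix (fast path, no per-point expansion).

    Returns ``(counts, manifest)``: counts has factor columns area,
    site_id, survey_id, transect plus one column per OTU; manifest maps
    (area, survey) to the expected composition alpha / sum(alpha).
    """
    rng = np.random.default_rng(seed)
    otus = cfg.taxonomy["otu_id"].tolist()
    n_points = cfg.photos * cfg.points_per_photo
    rows, meta = [], []
    manifest = {"compositions": {}}
    for area, sites in cfg.sites.items():
        for survey in cfg.surveys:
            alpha = _alpha_for(cfg, area, survey)
            manifest["compositions"][(area, survey)] = alpha / alpha.sum()
            for site in sites:
                for tr in range(1, cfg.transects + 1):
                    p = rng.dirichlet(alpha)
                    rows.append(rng.multinomial(n_points, p))
                    meta.append((area, site, survey, tr))
    counts = pd.DataFrame(rows, columns=otus)
    frame = pd.DataFrame(meta, columns=["area", "site_id", "survey_id", "transect"])
    return pd.concat([frame, counts], axis=1), manifest


def simulate_benthic(
    cfg: BenthicSimConfig,
    dhw_by_site_survey: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate photo-point records plus a ground-truth manifest.

    ``dhw_by_site_survey`` (columns site_id, survey_id, dhw) drives the
    logistic bleaching probability; absent, DHW is taken as 0 everywhere.
    Records carry one row per point: site_id, area, survey_id, transect,
    photo, point, otu_id, bleach_state.
    """
    rng = np.random.default_rng(seed)
    counts, manifest = simulate_transect_counts(cfg, seed=seed)
    tax = cfg.taxonomy
    otus = tax["otu_id"].to_numpy()
    potential = dict(zip(tax["otu_id"], tax["bleaching_potential"]))

    dhw_map: dict[tuple[str, str], float] = {}
    if dhw_by_site_survey is not None:
        for _, r in dhw_by_site_survey.iterrows():
            dhw_map[(r["site_id"], r["survey_id"])] = float(r["dhw"])
    manifest["bleach_prob"] = {}

    ppp = cfg.points_per_photo
    frames = []
    for _, row in counts.iterrows():
        c = row[otus].to_numpy(dtype=int)
        otu_col = np.repeat(otus, c)
        rng.shuffle(otu_col)
        n = otu_col.size
        idx = np.arange(n)
        dhw_val = dhw_map.get((row["site_id"], row["survey_id"]), 0.0)
        p_bleach = 1.0 / (1.0 + np.exp(-(cfg.beta0 + cfg.beta1 * dhw_val)))
        manifest["bleach_prob"][(row["site_id"], row["survey_id"])] = p_bleach

        can_bleach = np.array([potential[o] for o in otu_col])
        state = np.where(can_bleach, "none", "not_applicable").astype(object)
        u = rng.random(n)
        state[can_bleach & (u < p_bleach)] = "bleached"
        if cfg.p_discolored > 0:
            u2 = rng.random(n)
            disc = can_bleach & (u >= p_bleach) & (u2 < cfg.p_discolored)
            state[disc] = "discolored"

        frames.append(pd.DataFrame({
            "site_id": row["site_id"], "area": row["area"],
            "survey_id": row["survey_id"], "transect": row["transect"],
            "photo": idx // ppp + 1, "point": idx % ppp + 1,
            "otu_id": otu_col, "bleach_state": state,
        }))
    records = pd.concat(frames, ignore_index=True)
    return records, manifest
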