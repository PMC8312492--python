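"""Storm indicators and typhoon-induced seawater cooling.

Meteorological station series are aggregated to regional daily values
(station-day wind means averaged across stations; daily cumulative
rainfall per station averaged across stations; daily maximum buoy wave
height). Storm days are flagged by inclusive thresholds on any of the
three indicators. Typhoon cold wakes are quantified per site as the
lowest daily seawater temperature inside the event window minus the
7-day pre-typhoon background, then averaged (+- sample SD) across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TyphoonWindow",
    "CoolingResult",
    "WIND_THRESHOLD_MS",
    "RAIN_THRESHOLD_MM",
    "WAVE_THRESHOLD_CM",
    "aggregate_meteo",
    "detect_storm_days",
    "typhoon_background",
    "typhoon_drop",
    "regional_cooling",
    "max_consecutive_day_drop",
]

WIND_THRESHOLD_MS = 4.0
RAIN_THRESHOLD_MM = 50.0
WAVE_THRESHOLD_CM = 150.0


@dataclass(frozen=True)
class TyphoonWindow:
    """An event window (both endpoints inclusive)."""

    name: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    category: int = 0
    landed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date))
        object.__setattr__(self, "end_date", pd.Timestamp(self.end_date))
        if self.start_date > self.end_date:
            raise ValueError(f"typhoon {self.name!r}: start_date after end_date")


@dataclass(frozen=True)
class CoolingResult:
    """Per-site temperature drops for one typhoon with regional aggregation.

    ``drop`` is signed: negative means cooling; a warming window yields a
    positive drop and is reported as-is. ``regional_sd`` is the sample SD
    (n-1) and is NaN for a single site.
    """

    typhoon: str
    per_site: pd.DataFrame  # site_id, background, min_daily, drop
    regional_mean: float
    regional_sd: float
    n_sites: int


def aggregate_meteo(
    station_series: pd.DataFrame,
    wave_series: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate station wind/rain and buoy wave series to regional daily values.

    ``station_series``: columns station_id, timestamp, wind_ms, rain_mm
    (hourly or daily). Per station-day, wind is averaged and rain summed
    (daily cumulative); station-day values are then averaged across the
    stations reporting that day. ``wave_series``: columns date, wave_cm;
    the daily maximum is kept.

    Returns columns ``date, wind_mean, rain_total, wave_max, n_stations``.
    """
    st = station_series.copy()
    st["date"] = pd.to_datetime(st["timestamp"]).dt.normalize()
    per_station = st.groupby(["station_id", "date"]).agg(
        wind=("wind_ms", "mean"), rain=("rain_mm", "sum")
    )
    regional = per_station.groupby("date").agg(
        wind_mean=("wind", "mean"), rain_total=("rain", "mean"), n_stations=("wind", "size")
    )
    if wave_series is not None and not wave_series.empty:
        wv = wave_series.copy()
        wv["date"] = pd.to_datetime(wv["date"]).dt.normalize()
        wave = wv.groupby("date")["wave_cm"].max().rename("wave_max")
        regional = regional.join(wave, how="outer")
    else:
        regional["wave_max"] = np.nan
    if regional.empty:
        raise ValueError("no overlapping dates in meteorological inputs")
    return regional.reset_index()


def detect_storm_days(
    meteo: pd.DataFrame,
    *,
    wind_thr: float = WIND_THRESHOLD_MS,
    rain_thr: float = RAIN_THRESHOLD_MM,
    wave_thr: float = WAVE_THRESHOLD_CM,
) -> pd.DataFrame:
    """Flag storm days: wind >= 4 m/s, rain >= 50 mm and/or wave >= 150 cm.

    Thresholds are inclusive; a day is a storm day if any criterion hits.
    Missing indicators never hit.
    """
    if meteo.empty:
        raise ValueError("meteo table is empty")
    out = meteo.copy()
    out["wind_hit"] = out["wind_mean"].ge(wind_thr).fillna(False)
    out["rain_hit"] = out["rain_total"].ge(rain_thr).fillna(False)
    out["wave_hit"] = out["wave_max"].ge(wave_thr).fillna(False)
    out["is_storm_day"] = out["wind_hit"] | out["rain_hit"] | out["wave_hit"]
    return out


def _site_daily(daily: pd.DataFrame) -> pd.Series:
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    return d.set_index("date")["t_mean"].sort_index()


def typhoon_background(
    daily: pd.DataFrame, tw: TyphoonWindow, *, lookback_days: int = 7
) -> float:
    """Pre-typhoon background: mean daily temperature over the 7 prior days.

    The lookback window is [start - lookback_days, start - 1].
    """
    s = _site_daily(daily)
    window = s.loc[tw.start_date - pd.Timedelta(days=lookback_days) : tw.start_date - pd.Timedelta(days=1)]
    if window.empty:
        site = daily["site_id"].iloc[0] if "site_id" in daily else "<unknown>"
        raise ValueError(
            f"no daily temperatures in the {lookback_days}-day lookback before "
            f"typhoon {tw.name!r} at site {site!r}"
        )
    return float(window.mean())


def typhoon_drop(
    daily: pd.DataFrame, tw: TyphoonWindow, *, lookback_days: int = 7, basis: str = "mean"
) -> tuple[float, float, float]:
    """(background, min_daily, drop) for one site and typhoon.

    ``min_daily`` is the lowest daily temperature inside the inclusive
    event window (daily mean by default; ``basis="min"`` uses the daily
    minimum of the raw log). ``drop = min_daily - background``: negative
    is cooling, positive warming, sign preserved.
    """
    background = typhoon_background(daily, tw, lookback_days=lookback_days)
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    col = {"mean": "t_mean", "min": "t_min"}[basis]
    inwin = d[(d["date"] >= tw.start_date) & (d["date"] <= tw.end_date)]
    if inwin.empty:
        raise ValueError(f"no daily temperatures inside typhoon window {tw.name!r}")
    min_daily = float(inwin[col].min())
    return background, min_daily, min_daily - background


def regional_cooling(typhoon: str, drops: dict[str, float]) -> CoolingResult:
    """Aggregate per-site drops (site_id -> drop degC) for one typhoon."""
    if not drops:
        raise ValueError(f"no site drops for typhoon {typhoon!r}")
    vals = np.array(list(drops.values()), dtype=float)
    per_site = pd.DataFrame({"site_id": list(drops), "drop": vals})
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return CoolingResult(
        typhoon=typhoon,
        per_site=per_site,
        regional_mean=float(vals.mean()),
        regional_sd=sd,
        n_sites=len(vals),
    )


def cooling_table(
    daily_by_site: pd.DataFrame,
    typhoons: list[TyphoonWindow],
    *,
    lookback_days: int = 7,
    basis: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site and regional cooling for a list of typhoons.

    ``daily_by_site`` holds daily summaries for several sites (column
    ``site_id``). Sites without data for a window are omitted from that
    typhoon's regional aggregate (logged as reduced ``n_sites``), matching
    a no-imputation policy.

    Returns ``(per_site, regional)`` tables.
    """
    rows, reg = [], []
    for tw in typhoons:
        drops: dict[str, float] = {}
        for site, grp in daily_by_site.groupby("site_id", sort=False):
            try:
                bg, lo, dr = typhoon_drop(grp, tw, lookback_days=lookback_days, basis=basis)
            except ValueError:
                continue
            drops[site] = dr
            rows.append(
                {"typhoon": tw.name, "site_id": site, "background_c": bg,
                 "min_daily_c": lo, "drop_c": dr}
            )
        if drops:
            res = regional_cooling(tw.name, drops)
            reg.append(
                {"typhoon": tw.name, "mean_drop_c": res.regional_mean,
                 "sd_drop_c": res.regional_sd, "n_sites": res.n_sites}
            )
    return pd.DataFrame(rows), pd.DataFrame(reg)


def max_consecutive_day_drop(daily: pd.DataFrame) -> tuple[pd.Timestamp, float]:
    """Largest day-over-day decrease in daily mean temperature.

    Scans consecutive-calendar-day pairs only; returns (date, delta) where
    delta = t_mean(d) - t_mean(d-1) is the most negative difference (ties
    broken by earliest date). On a series with no decrease the smallest
    positive delta is returned.
    """
    s = _site_daily(daily)
    if len(s) < 2:
        raise ValueError("need at least two daily values")
    diffs = s.diff()
    consecutive = s.index.to_series().diff() == pd.Timedelta(days=1)
    diffs = diffs[consecutive.to_numpy()]
    if diffs.empty:
        raise ValueError("no consecutive-day pair in series")
    date = diffs.idxmin()  # idxmin returns the first occurrence on ties
    return date, float(diffs.loc[date])
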