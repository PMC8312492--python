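"""Thermal stress: daily summaries, MMM climatology, Degree Heating Weeks.

The coral-bleaching heat-stress chain implemented here follows the
operational Coral Reef Watch logic, anchored to a *local* climatology:

1. reduce a sub-daily logger series to daily min/mean/max;
2. build a monthly climatology over a fixed baseline period and take its
   warmest month, the Maximum Monthly Mean (MMM);
3. set the bleaching threshold at MMM + 1 degC;
4. daily thermal stress = daily maximum - threshold, clamped at zero;
5. Degree Heating Weeks (DHW) on day d = the sum over the 12 consecutive
   7-day blocks covering [d-83, d] of each block's mean clamped stress,
   in degC-weeks (algebraically: the 84-day clamped-stress sum / 7);
6. alert levels band DHW into Watch / Warning / Alert Level 1 / Level 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlertLevel",
    "Climatology",
    "ThresholdSpec",
    "daily_summaries",
    "monthly_climatology",
    "bleaching_threshold",
    "daily_thermal_stress",
    "dhw",
    "classify_alert",
]

#: default plausibility band for raw logger readings, degC
SANITY_BAND = (10.0, 40.0)

DHW_WINDOW_DAYS = 84
WEEK_LENGTH = 7


class AlertLevel(str, enum.Enum):
    """NOAA-style bleaching alert bands on DHW (degC-weeks)."""

    WATCH = "Watch"            # [0, 1)
    WARNING = "Warning"        # [1, 4)
    ALERT_LEVEL_1 = "AlertLevel1"  # [4, 8]
    ALERT_LEVEL_2 = "AlertLevel2"  # (8, inf)


@dataclass(frozen=True)
class Climatology:
    """Monthly-mean climatology over a fixed baseline, with its MMM."""

    baseline_start: pd.Timestamp
    baseline_end: pd.Timestamp
    monthly_means: np.ndarray  # 12 values, Jan..Dec, degC
    mmm: float = field(init=False)

    def __post_init__(self) -> None:
        means = np.asarray(self.monthly_means, dtype=float)
        if means.shape != (12,):
            raise ValueError("monthly_means must hold exactly 12 values (Jan..Dec)")
        object.__setattr__(self, "monthly_means", means)
        object.__setattr__(self, "mmm", float(means.max()))


@dataclass(frozen=True)
class ThresholdSpec:
    """Bleaching threshold = MMM + offset (default +1 degC)."""

    mmm: float
    offset: float = 1.0

    @property
    def bleaching_threshold(self) -> float:
        return self.mmm + self.offset


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    if series.empty:
        raise ValueError("temperature series is empty")
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    for site, grp in out.groupby("site_id", sort=False):
        ts = grp["timestamp"]
        bad = ts.diff().dt.total_seconds() <= 0
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-monotone timestamps for site {site!r}: "
                f"{ts.iloc[i - 1]} followed by {ts.iloc[i]}"
            )
    return out


def daily_summaries(
    series: pd.DataFrame,
    *,
    sanity_band: tuple[float, float] = SANITY_BAND,
    min_readings: int = 1,
) -> pd.DataFrame:
    """Reduce a (site_id, timestamp, temp_c) series to daily min/mean/max.

    Parameters
    ----------
    series
        Columns ``site_id``, ``timestamp`` (parseable datetimes, strictly
        increasing within a site), ``temp_c``.
    sanity_band
        Readings outside this band are flagged (``n_flagged``), not dropped.
    min_readings
        Days with fewer readings are omitted from the output.

    Returns
    -------
    DataFrame with columns ``site_id, date, t_min, t_mean, t_max,
    n_readings, n_flagged``; one row per site per calendar day holding at
    least ``min_readings`` readings. Days with no readings are simply
    absent (never interpolated).
    """
    ser = _validate_series(series)
    lo, hi = sanity_band
    ser["date"] = ser["timestamp"].dt.normalize()
    ser["flagged"] = (ser["temp_c"] < lo) | (ser["temp_c"] > hi)
    out = (
        ser.groupby(["site_id", "date"], sort=True)
        .agg(
            t_min=("temp_c", "min"),
            t_mean=("temp_c", "mean"),
            t_max=("temp_c", "max"),
            n_readings=("temp_c", "size"),
            n_flagged=("flagged", "sum"),
        )
        .reset_index()
    )
    return out[out["n_readings"] >= min_readings].reset_index(drop=True)


def monthly_climatology(
    daily: pd.DataFrame,
    baseline_start,
    baseline_end,
    *,
    method: str = "year-month",
) -> Climatology:
    """Monthly climatology of daily mean temperature over a baseline period.

    ``method="year-month"`` (default) averages each year-month's mean of
    daily means, then averages those across baseline years, so every year
    weighs equally regardless of missing days. ``method="pooled"`` pools
    all daily values of a calendar month directly.

    Raises if any calendar month has no data anywhere in the baseline.
    """
    start, end = pd.Timestamp(baseline_start), pd.Timestamp(baseline_end)
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    d = d[(d["date"] >= start) & (d["date"] <= end)]
    if d["date"].dt.to_period("M").nunique() < 12:
        raise ValueError("baseline must cover at least 12 distinct calendar months with data")

    if method == "year-month":
        ym = d.groupby([d["date"].dt.year, d["date"].dt.month])["t_mean"].mean()
        ym.index.names = ["year", "month"]
        monthly = ym.groupby("month").mean()
    elif method == "pooled":
        monthly = d.groupby(d["date"].dt.month)["t_mean"].mean()
    else:
        raise ValueError(f"unknown climatology method {method!r}")

    missing = sorted(set(range(1, 13)) - set(monthly.index))
    if missing:
        names = ", ".join(pd.Timestamp(2000, m, 1).strftime("%b") for m in missing)
        raise ValueError(f"no baseline data for calendar month(s): {names}")
    return Climatology(start, end, monthly.reindex(range(1, 13)).to_numpy())


def bleaching_threshold(clim: Climatology, offset: float = 1.0) -> ThresholdSpec:
    """Local bleaching threshold: the climatology's MMM plus ``offset`` degC."""
    return ThresholdSpec(mmm=clim.mmm, offset=offset)


def daily_thermal_stress(
    daily: pd.DataFrame,
    thr: ThresholdSpec,
    *,
    basis: str = "max",
) -> pd.DataFrame:
    """Daily exceedance of the bleaching threshold.

    ``raw_stress = t_<basis> - threshold``; ``clamped_stress`` floors it at
    zero, so only days at or above the threshold accumulate heat stress.
    ``basis`` is ``"max"`` (daily in-situ maximum, the default) or
    ``"mean"`` for daily-average-only inputs such as buoy series.
    """
    if daily.empty:
        raise ValueError("daily summaries are empty")
    if basis not in ("max", "mean"):
        raise ValueError(f"basis must be 'max' or 'mean', got {basis!r}")
    out = daily.copy()
    out["raw_stress"] = out[f"t_{basis}"] - thr.bleaching_threshold
    out["clamped_stress"] = out["raw_stress"].clip(lower=0.0)
    return out


def dhw(
    stress: pd.DataFrame,
    *,
    window_days: int = DHW_WINDOW_DAYS,
    week_length: int = WEEK_LENGTH,
    inclusive: bool = True,
    strict: bool = False,
) -> pd.DataFrame:
    """Degree Heating Weeks per site and day, with alert levels.

    For focal day d the window is the ``window_days`` days ending on d
    (inclusive of d by default; ``inclusive=False`` ends it on d-1).
    DHW(d) is the sum over the 12 consecutive ``week_length``-day blocks of
    each block's mean clamped stress — identically the window sum of daily
    clamped stress divided by ``week_length``.

    Days whose window has fewer than ``window_days`` daily values get
    ``complete_window=False`` and a DHW computed from the available days
    (missing days contribute nothing). ``strict=True`` raises instead.
    """
    frames = []
    for site, grp in stress.groupby("site_id", sort=False):
        g = grp.copy()
        g["date"] = pd.to_datetime(g["date"])
        g = g.set_index("date").sort_index()
        # reindex to a full daily grid so gaps are visible to the window
        full = g.reindex(pd.date_range(g.index.min(), g.index.max(), freq="D"))
        s = full["clamped_stress"]
        roll = s.rolling(window=window_days, min_periods=1)
        dhw_vals = roll.sum() / week_length
        n_avail = roll.count()
        if not inclusive:
            dhw_vals = dhw_vals.shift(1)
            n_avail = n_avail.shift(1).fillna(0)
        complete = n_avail >= window_days
        if strict and not complete.iloc[window_days - 1 :].all():
            raise ValueError(f"site {site!r}: DHW window with missing days under strict mode")
        res = pd.DataFrame(
            {
                "site_id": site,
                "date": full.index,
                "dhw": dhw_vals.to_numpy(),
                "complete_window": complete.to_numpy(),
            }
        )
        # report only days that actually have a stress observation
        res = res[full["clamped_stress"].notna().to_numpy()]
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["dhw"] = out["dhw"].fillna(0.0)
    out["alert_level"] = [classify_alert(v).value for v in out["dhw"]]
    return out


def classify_alert(dhw_value: float) -> AlertLevel:
    """Band a DHW value (degC-weeks) into a bleaching alert level.

    Half-open bands: Watch [0,1), Warning [1,4), Alert Level 1 [4,8],
    Alert Level 2 (8, inf). The printed operational bands overlap at their
    edges; 4 and 8 are assigned upward and to Level 1 respectively.
    """
    if dhw_value < 0:
        raise ValueError(f"DHW cannot be negative, got {dhw_value}")
    if dhw_value < 1:
        return AlertLevel.WATCH
    if dhw_value < 4:
        return AlertLevel.WARNING
    if dhw_value <= 8:
        return AlertLevel.ALERT_LEVEL_1
    return AlertLevel.ALERT_LEVEL_2
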