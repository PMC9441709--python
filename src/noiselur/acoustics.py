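"""Energy-based noise metrics from minute-resolution A-weighted levels.

All aggregation is done on the energy scale: a set of levels ``L_i`` (dBA)
with durations ``w_i`` combines to the equivalent continuous level

    LAeq = 10 log10( sum_i w_i 10^(L_i/10) / sum_i w_i ).

Clock conventions (no daylight saving):

* day     06:00-21:59 (16 h) — used for L_day and the day LUR model,
* night   22:00-05:59 (8 h)  — used for L_night and the night model,
* L_den   splits the day block into day 06:00-18:59 (13 h, no penalty) and
  evening 19:00-21:59 (3 h, +5 dBA); night carries +10 dBA.

The intermittency ratio (IR) of a period is the percentage of the period's
acoustic energy contributed by minutes at or above a threshold set a fixed
offset (default +3 dBA) above the period's own LAeq.  A steady drone has
IR near 0; a quiet background punctuated by loud events approaches 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAY_HOURS = tuple(range(6, 22))
NIGHT_HOURS = tuple(list(range(22, 24)) + list(range(0, 6)))
DEN_DAY_HOURS = tuple(range(6, 19))
DEN_EVENING_HOURS = (19, 20, 21)

#: L_den of a flat 24 h profile exceeds the level by this many dBA:
#: 10 log10((13 + 3*10^0.5 + 8*10)/24).
FLAT_PROFILE_LDEN_OFFSET = 10.0 * np.log10((13 + 3 * 10**0.5 + 8 * 10) / 24)


def _to_energy(levels) -> np.ndarray:
    return np.power(10.0, np.asarray(levels, dtype=float) / 10.0)


def laeq(levels, weights=None) -> float:
    """Equivalent continuous level of ``levels`` (dBA), optionally weighted
    by positive durations."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("laeq of an empty collection is undefined")
    energy = _to_energy(levels)
    if weights is None:
        mean_energy = energy.mean()
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != levels.shape:
            raise ValueError("weights must match levels in length")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        mean_energy = float(np.sum(weights * energy) / np.sum(weights))
    return float(10.0 * np.log10(mean_energy))


def hourly_levels(minutes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate 1-minute levels to LAeq_1hr per (site, date, hour).

    ``minutes`` needs columns ``site_id``, ``timestamp`` (datetime-like) and
    ``laeq_1min_dba``.  Hours with no minutes are simply absent; ``n_minutes``
    records how many minutes entered each hour.
    """
    if minutes.empty:
        return pd.DataFrame(
            columns=["site_id", "date", "hour", "laeq_1hr_dba", "n_minutes"]
        )
    ts = pd.to_datetime(minutes["timestamp"])
    df = pd.DataFrame(
        {
            "site_id": pd.Categorical(minutes["site_id"]),
            "hour_start": ts.dt.floor("h").to_numpy(),
            "energy": _to_energy(minutes["laeq_1min_dba"].to_numpy()),
        }
    )
    grouped = df.groupby(["site_id", "hour_start"], sort=True, observed=True)[
        "energy"
    ].agg(["mean", "size"])
    out = grouped.reset_index()
    hour_start = pd.DatetimeIndex(out["hour_start"])
    out["date"] = hour_start.date
    out["hour"] = hour_start.hour
    out["laeq_1hr_dba"] = 10.0 * np.log10(out.pop("mean"))
    out = out.rename(columns={"size": "n_minutes"})
    out["site_id"] = out["site_id"].astype(str)
    return out[["site_id", "date", "hour", "laeq_1hr_dba", "n_minutes"]]


def long_term_hourly_profile(hourly: pd.DataFrame) -> pd.DataFrame:
    """Long-term average LAeq_1hr per (site, hour-of-day).

    The average across days is energetic, consistent with the equivalent
    continuous level being an energy mean.  Returns columns ``site_id``,
    ``hour``, ``laeq_1hr_dba``, ``n_hours``.
    """
    df = hourly.copy()
    df["energy"] = _to_energy(df["laeq_1hr_dba"].to_numpy())
    grouped = df.groupby(["site_id", "hour"], sort=True)["energy"].agg(["mean", "size"])
    out = grouped.reset_index()
    out["laeq_1hr_dba"] = 10.0 * np.log10(out.pop("mean"))
    return out.rename(columns={"size": "n_hours"})[
        ["site_id", "hour", "laeq_1hr_dba", "n_hours"]
    ]


@dataclass(frozen=True)
class NoiseMetrics:
    """Period-aggregate noise descriptors of one location (dBA)."""

    laeq_24hr_dba: float
    l_den_dba: float
    l_day_dba: float
    l_night_dba: float

    def as_dict(self) -> dict[str, float]:
        return {
            "laeq_24hr": self.laeq_24hr_dba,
            "l_den": self.l_den_dba,
            "l_day": self.l_day_dba,
            "l_night": self.l_night_dba,
        }


def period_metrics(hourly_profile) -> NoiseMetrics:
    """LAeq_24hr, L_den, L_day, L_night from 24 hour-of-day levels.

    ``hourly_profile`` is indexable by hour 0..23 (list/array of length 24).
    Hours with no acoustic energy may be ``-inf``.
    """
    prof = np.asarray(hourly_profile, dtype=float)
    if prof.shape != (24,):
        raise ValueError(f"expected 24 hourly values, got shape {prof.shape}")
    # single code path with the gridded variant so per-cell aggregates of a
    # surface agree bit-for-bit with the scalar computation
    grid = period_metrics_grid(prof[:, None])
    return NoiseMetrics(
        float(grid["laeq_24hr"][0]),
        float(grid["l_den"][0]),
        float(grid["l_day"][0]),
        float(grid["l_night"][0]),
    )


def period_metrics_grid(hourly_stack: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised :func:`period_metrics` over a (24, ...) stack of levels."""
    if hourly_stack.shape[0] != 24:
        raise ValueError("leading axis must be the 24 hours of the day")
    energy = np.power(10.0, hourly_stack / 10.0)
    with np.errstate(divide="ignore"):
        laeq24 = 10.0 * np.log10(energy.mean(axis=0))
        l_day = 10.0 * np.log10(energy[list(DAY_HOURS)].mean(axis=0))
        l_night = 10.0 * np.log10(energy[list(NIGHT_HOURS)].mean(axis=0))
        den = (
            energy[list(DEN_DAY_HOURS)].sum(axis=0)
            + (energy[list(DEN_EVENING_HOURS)] * 10.0**0.5).sum(axis=0)
            + (energy[list(NIGHT_HOURS)] * 10.0).sum(axis=0)
        )
        l_den = 10.0 * np.log10(den / 24.0)
    return {"laeq_24hr": laeq24, "l_den": l_den, "l_day": l_day, "l_night": l_night}


@dataclass(frozen=True)
class IntermittencyResult:
    ir_day_pct: float
    ir_night_pct: float
    threshold_dba_offset: float = 3.0


def intermittency_ratio(
    minutes: pd.DataFrame, period: str, offset_c: float = 3.0
) -> float:
    """Percentage of period energy contributed by event minutes.

    The threshold is ``K = LAeq(period) + offset_c``; minutes with level >= K
    are events.  With 1-minute integration no within-minute event
    reconstruction is possible, so the event unit is the minute.
    """
    if period not in ("day", "night"):
        raise ValueError("period must be 'day' or 'night'")
    hours = DAY_HOURS if period == "day" else NIGHT_HOURS
    ts = pd.to_datetime(minutes["timestamp"])
    sel = ts.dt.hour.isin(hours).to_numpy()
    levels = minutes.loc[sel, "laeq_1min_dba"].to_numpy(dtype=float)
    if levels.size == 0:
        raise ValueError(f"no minutes fall in the {period} period")
    energy = _to_energy(levels)
    total = energy.sum()
    threshold = 10.0 * np.log10(energy.mean()) + offset_c
    ir = 100.0 * energy[levels >= threshold].sum() / total
    return float(np.clip(ir, 0.0, 100.0))


def site_metrics_table(minutes: pd.DataFrame, ir_offset_c: float = 3.0) -> pd.DataFrame:
    """Per-site summary: LAeq_24hr, L_den, L_day, L_night, IR_day, IR_night.

    Sites missing any hour of the day in their long-term profile are skipped
    (the aggregates are only defined on a full 24 h profile).
    """
    hourly = hourly_levels(minutes)
    profile = long_term_hourly_profile(hourly)
    rows = []
    for site_id, grp in minutes.groupby("site_id", sort=True):
        prof = profile[profile["site_id"] == site_id].set_index("hour")["laeq_1hr_dba"]
        if len(prof) < 24:
            continue
        metrics = period_metrics(prof.reindex(range(24)).to_numpy())
        rows.append(
            {
                "site_id": site_id,
                **metrics.as_dict(),
                "ir_day": intermittency_ratio(grp, "day", ir_offset_c),
                "ir_night": intermittency_ratio(grp, "night", ir_offset_c),
            }
        )
    return pd.DataFrame(rows)
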