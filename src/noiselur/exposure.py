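"""Population exposure and socioeconomic inequality at enumeration-area level.

The predicted surface is overlaid on census enumeration areas (EAs): each
EA gets the arithmetic mean of the masked-in cell values whose centres fall
inside it (an energetic variant is available), its whole population is
assigned to the 5 dBA bin of that mean, and exceedance of the WHO
road-traffic guidance values (L_den 53 dBA, L_night 45 dBA) is summarised.
Inequality contrasts noise across quintiles of an EA socioeconomic measure
(consumption, education, unemployment): per-quintile median/IQR, Pearson
correlation with a Fisher-z confidence interval, and a Welch test between
the bottom and top quintiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.strtree import STRtree

from .geo import VectorLayer
from .surfaces import METRIC_NAMES, NoiseSurface

log = logging.getLogger(__name__)

WHO_THRESHOLDS = {"l_den": 53.0, "l_night": 45.0}
SES_COLUMNS = {
    "consumption": "ses_consumption",
    "education": "ses_education",
    "unemployment": "ses_unemployed",
}


def ea_average(
    surface: NoiseSurface, eas: VectorLayer, energetic: bool = False
) -> pd.DataFrame:
    """Per-EA average of each metric over masked-in cell centres.

    EAs covering no predictable cell get NaN and are flagged by
    ``n_cells == 0``.  ``energetic=True`` averages on the energy scale
    instead of arithmetically on dBA.
    """
    cells = surface.cell_table()
    if cells.empty:
        warnings.warn("surface has no predictable cells; empty EA table")
        return pd.DataFrame(
            columns=["ea_id", "n_cells", *METRIC_NAMES]
        )
    pts = shapely.points(cells["x"].to_numpy(), cells["y"].to_numpy())
    tree = STRtree(pts)
    rows = []
    for geom, (_, attrs) in zip(eas.geometries, eas.attributes.iterrows()):
        idx = tree.query(geom, predicate="covers")
        row = {"ea_id": attrs["ea_id"], "n_cells": int(len(idx))}
        for name in METRIC_NAMES:
            if len(idx) == 0:
                row[name] = np.nan
                continue
            vals = cells[name].to_numpy()[idx]
            if energetic:
                row[name] = float(10 * np.log10(np.mean(10 ** (vals / 10))))
            else:
                row[name] = float(np.mean(vals))
        rows.append(row)
    out = pd.DataFrame(rows)
    n_missing = int((out["n_cells"] == 0).sum())
    if n_missing:
        log.info("%d EAs cover no predictable cell (flagged NaN)", n_missing)
    return out


@dataclass
class ExposureSummary:
    metric: str
    bins: pd.DataFrame  # bin_low, bin_high, population, share
    cumulative: pd.DataFrame  # level, cum_share (population below level)
    threshold_dba: float
    population_above: int
    percent_above: float
    total_population: int


def exposure_distribution(
    ea_levels: pd.DataFrame,
    eas: VectorLayer,
    metric: str = "l_den",
    bin_width: float = 5.0,
    thresholds: dict[str, float] | None = None,
) -> ExposureSummary:
    """Population in 5 dBA bins of EA-mean level plus guideline exceedance.

    Bins are [5k, 5k+5); an EA's whole population goes to its mean's bin.
    EAs without a level (no covered cells) are excluded and logged.
    """
    thresholds = thresholds or WHO_THRESHOLDS
    merged = ea_levels.merge(eas.attributes[["ea_id", "population"]], on="ea_id")
    usable = merged[np.isfinite(merged[metric])]
    dropped = len(merged) - len(usable)
    if dropped:
        log.info("%d EAs without a %s level excluded from binning", dropped, metric)
    if usable["population"].lt(0).any():
        raise ValueError("population must be nonnegative")

    levels = usable[metric].to_numpy()
    pop = usable["population"].to_numpy()
    lo = np.floor(levels / bin_width) * bin_width
    bins = (
        pd.DataFrame({"bin_low": lo, "population": pop})
        .groupby("bin_low", as_index=False)["population"]
        .sum()
        .sort_values("bin_low")
    )
    bins["bin_high"] = bins["bin_low"] + bin_width
    total = int(pop.sum())
    bins["share"] = bins["population"] / total if total else 0.0

    order = np.argsort(levels)
    cum = pd.DataFrame(
        {
            "level": levels[order],
            "cum_share": np.cumsum(pop[order]) / total if total else 0.0,
        }
    )
    thr = thresholds.get(metric)
    if thr is None:
        raise ValueError(f"no threshold configured for metric {metric!r}")
    above = int(pop[levels >= thr].sum())
    return ExposureSummary(
        metric=metric,
        bins=bins[["bin_low", "bin_high", "population", "share"]].reset_index(drop=True),
        cumulative=cum,
        threshold_dba=float(thr),
        population_above=above,
        percent_above=100.0 * above / total if total else 0.0,
        total_population=total,
    )


def plot_cumulative_exposure(summaries: list[ExposureSummary], path) -> None:
    """Cumulative population share vs level, one curve per metric, with the
    guideline thresholds as vertical lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in summaries:
        ax.step(
            s.cumulative["level"], s.cumulative["cum_share"], where="post",
            label=s.metric,
        )
        ax.axvline(s.threshold_dba, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("EA-mean level (dBA)")
    ax.set_ylabel("cumulative population share")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class InequalityResult:
    measure: str
    quintile_summary: pd.DataFrame  # quintile, n, median/q1/q3 of l_den & l_night
    correlations: pd.DataFrame  # metric, r, ci_low, ci_high, n
    welch: pd.DataFrame  # metric, statistic, p (bottom vs top quintile)
    assignments: pd.DataFrame  # ea_id, quintile


def plot_quintile_distributions(
    result: InequalityResult, ea_levels: pd.DataFrame, path, metric: str = "l_den"
) -> None:
    """Per-quintile level distribution: box (median/IQR) plus jittered EAs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    merged = ea_levels.merge(result.assignments, on="ea_id")
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [merged.loc[merged["quintile"] == q, metric].dropna() for q in range(1, 6)]
    ax.boxplot(data, positions=range(1, 6), showfliers=False)
    rng = np.random.default_rng(0)
    for q, vals in zip(range(1, 6), data):
        ax.plot(q + rng.uniform(-0.15, 0.15, len(vals)), vals, "o", alpha=0.5, ms=3)
    ax.set_xlabel(f"{result.measure} quintile (1 = lowest)")
    ax.set_ylabel(f"EA-mean {metric} (dBA)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh r +- z / sqrt(n-3))."""
    if n <= 3:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def assign_quintiles(values: pd.Series) -> pd.Series:
    """Five rank-based groups with sizes differing by at most one.

    Ranks are stable in the index order, so ties break by EA id and any
    strictly increasing transform of ``values`` yields the same grouping.
    """
    if values.nunique() < 2:
        raise ValueError("constant SES measure cannot be split into quintiles")
    order = np.argsort(values.to_numpy(), kind="stable")
    n = len(values)
    sizes = np.full(5, n // 5)
    sizes[: n % 5] += 1
    labels = np.repeat(np.arange(1, 6), sizes)
    out = np.empty(n, dtype=int)
    out[order] = labels
    return pd.Series(out, index=values.index, name="quintile")


def ses_inequality(
    ea_levels: pd.DataFrame,
    eas: VectorLayer,
    measure: str = "consumption",
) -> InequalityResult:
    """Noise inequality across quintiles of one SES measure.

    Quintile 1 is the lowest-SES fifth of EAs.  The Welch two-sample test
    compares the bottom against the top quintile for each metric.
    """
    if measure not in SES_COLUMNS:
        raise ValueError(f"measure must be one of {sorted(SES_COLUMNS)}")
    col = SES_COLUMNS[measure]
    merged = ea_levels.merge(eas.attributes[["ea_id", col]], on="ea_id")
    merged = merged[np.isfinite(merged["l_den"]) & np.isfinite(merged[col])]
    merged = merged.sort_values("ea_id").reset_index(drop=True)
    if len(merged) < 10:
        raise ValueError("need at least 10 EAs with level and SES data")

    quintile = assign_quintiles(merged[col])
    merged["quintile"] = quintile.to_numpy()

    metrics = ("l_den", "l_night")
    qrows = []
    for q, grp in merged.groupby("quintile"):
        row = {"quintile": int(q), "n": len(grp)}
        for m in metrics:
            q1, q3 = np.percentile(grp[m], [25, 75])
            row[f"{m}_median"] = float(grp[m].median())
            row[f"{m}_q1"], row[f"{m}_q3"] = float(q1), float(q3)
        qrows.append(row)

    crows, wrows = [], []
    n = len(merged)
    for m in metrics:
        r = float(np.corrcoef(merged[col], merged[m])[0, 1])
        lo, hi = fisher_ci(r, n)
        crows.append({"metric": m, "r": r, "ci_low": lo, "ci_high": hi, "n": n})
        bottom = merged.loc[merged["quintile"] == 1, m]
        top = merged.loc[merged["quintile"] == 5, m]
        t, p = stats.ttest_ind(bottom, top, equal_var=False)
        wrows.append({"metric": m, "statistic": float(t), "p": float(p)})

    return InequalityResult(
        measure=measure,
        quintile_summary=pd.DataFrame(qrows),
        correlations=pd.DataFrame(crows),
        welch=pd.DataFrame(wrows),
        assignments=merged[["ea_id", "quintile"]].copy(),
    )
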