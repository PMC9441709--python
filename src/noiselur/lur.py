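"""Mixed-effect land-use-regression models of hourly noise levels.

Separate LAeq_1hr models are fitted for the day (06-21) and night (22-05)
periods.  Each is a Gaussian mixed model with crossed random intercepts for
monitoring site and hour of the day, adjusted for monitor height.  Model
selection is two-step: (1) per candidate variable, pick the buffer radius
whose feature correlates most strongly (|Pearson r|) with site-level mean
levels and discard variables whose realised sign contradicts the a-priori
expectation; (2) forward stepwise on the fixed-effect R^2 with a minimum
gain to enter, followed by a stability prune of wide zero-crossing
coefficients, a challenge round over the excluded candidates, and a
pairwise collinearity filter.

``r2_fixed`` throughout is the squared Pearson correlation between the
fixed-effect predictions and the observed hourly levels; a marginal-R^2
variant (fixed-effect variance over total variance) is logged alongside.

Intermittency-ratio (IR) models reuse the same selection machinery on
site-level ordinary least squares, with the period noise level (L_day /
L_night) as an additional candidate and an optional land-use interaction
on the noise-level term.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .acoustics import DAY_HOURS, NIGHT_HOURS, _to_energy
from .features import FeatureMatrix, FeatureSpec, column_name, parse_buffer
from .mixedlm import CrossedLMMResult, FitError, fit_crossed_lmm

log = logging.getLogger(__name__)

PERIOD_HOURS = {"day": DAY_HOURS, "night": NIGHT_HOURS}


@dataclass(frozen=True)
class SelectionConfig:
    r2_gain_threshold: float = 0.01
    collinearity_r: float = 0.8
    sign_constraint: bool = True
    vif_report: bool = True
    stability_t: float = 1.0  # drop when CI crosses zero and |t| < this

    def __post_init__(self) -> None:
        for name in ("r2_gain_threshold", "collinearity_r"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class LurModel:
    """A fitted LAeq_1hr mixed model for one period."""

    period: str
    variables: list[str]
    intercept: float
    intercept_ci: tuple[float, float]
    coefficients: dict[str, float]
    conf_ints: dict[str, tuple[float, float]]
    height_coef: float
    hour_intercepts: dict[int, float]
    site_variance: float
    hour_variance: float
    residual_variance: float
    r2_fixed: float
    r2_marginal: float
    selection_trace: list[str] = dc_field(default_factory=list)
    standardization: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    n_sites: int = 0
    n_obs: int = 0

    def predict_fixed(self, features: pd.DataFrame) -> np.ndarray:
        """Fixed-effect prediction (monitor height included) per row."""
        out = np.full(len(features), self.intercept, dtype=float)
        out += self.height_coef * features["monitor_height_m"].to_numpy(dtype=float)
        for var, coef in self.coefficients.items():
            out += coef * features[var].to_numpy(dtype=float)
        return out

    def predict_hour(self, features: pd.DataFrame, hour: int) -> np.ndarray:
        """Fixed effects plus the hour intercept (no site intercept)."""
        if hour not in self.hour_intercepts:
            raise ValueError(f"hour {hour} outside the {self.period} model")
        return self.predict_fixed(features) + self.hour_intercepts[hour]

    def to_json(self, path) -> None:
        doc = {
            "period": self.period,
            "variables": self.variables,
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "coefficients": self.coefficients,
            "conf_ints": {k: list(v) for k, v in self.conf_ints.items()},
            "height_coef": self.height_coef,
            "hour_intercepts": {str(k): v for k, v in self.hour_intercepts.items()},
            "site_variance": self.site_variance,
            "hour_variance": self.hour_variance,
            "residual_variance": self.residual_variance,
            "r2_fixed": self.r2_fixed,
            "r2_marginal": self.r2_marginal,
            "selection_trace": self.selection_trace,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "n_sites": self.n_sites,
            "n_obs": self.n_obs,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LurModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            period=d["period"],
            variables=d["variables"],
            intercept=d["intercept"],
            intercept_ci=tuple(d["intercept_ci"]),
            coefficients=d["coefficients"],
            conf_ints={k: tuple(v) for k, v in d["conf_ints"].items()},
            height_coef=d["height_coef"],
            hour_intercepts={int(k): v for k, v in d["hour_intercepts"].items()},
            site_variance=d["site_variance"],
            hour_variance=d["hour_variance"],
            residual_variance=d["residual_variance"],
            r2_fixed=d["r2_fixed"],
            r2_marginal=d["r2_marginal"],
            selection_trace=d["selection_trace"],
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            n_sites=d["n_sites"],
            n_obs=d["n_obs"],
        )

    def report(self) -> str:
        """Human-readable coefficient table (one row per predictor)."""
        lines = [
            f"LAeq_1hr model, {self.period} hours "
            f"(n={self.n_obs} site-hours, {self.n_sites} sites)",
            f"  R2 (fixed effects, squared correlation): {self.r2_fixed:.3f}",
            f"  R2 (marginal): {self.r2_marginal:.3f}",
            f"  sigma2 site / hour / residual: "
            f"{self.site_variance:.2f} / {self.hour_variance:.2f} / "
            f"{self.residual_variance:.2f}",
            f"  Intercept: {self.intercept:.1f} "
            f"[{self.intercept_ci[0]:.1f}, {self.intercept_ci[1]:.1f}]",
        ]
        for var in self.variables:
            lo, hi = self.conf_ints[var]
            lines.append(
                f"  {var}: {self.coefficients[var]:.2f} [{lo:.2f}, {hi:.2f}]"
            )
        return "\n".join(lines)


def filter_period(hourly: pd.DataFrame, period: str) -> pd.DataFrame:
    if period not in PERIOD_HOURS:
        raise ValueError("period must be 'day' or 'night'")
    return hourly[hourly["hour"].isin(PERIOD_HOURS[period])]


def site_mean_levels(hourly: pd.DataFrame, period: str) -> pd.Series:
    """Per-site period LAeq (energetic mean over the period's hourly rows).

    Used for bivariate screening to avoid pseudo-replicating hourly rows.
    """
    sub = filter_period(hourly, period)
    energy = pd.Series(_to_energy(sub["laeq_1hr_dba"].to_numpy()), index=sub.index)
    mean_energy = energy.groupby(sub["site_id"]).mean()
    return 10.0 * np.log10(mean_energy)


def _design(
    hourly: pd.DataFrame, fm: FeatureMatrix, variables: list[str], period: str
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    sub = filter_period(hourly, period)
    feats = fm.table
    missing = [v for v in variables if v not in feats.columns]
    if missing:
        raise FitError(f"variables not in the feature matrix: {missing}")
    rows = feats.loc[sub["site_id"]]
    cols = {"intercept": np.ones(len(sub))}
    heights = rows["monitor_height_m"].to_numpy()
    if np.std(heights) > 0:  # constant height is unidentifiable next to the intercept
        cols["monitor_height_m"] = heights
    for v in variables:
        cols[v] = rows[v].to_numpy()
    return (
        sub["laeq_1hr_dba"].to_numpy(),
        pd.DataFrame(cols),
        sub["site_id"].to_numpy(),
        sub["hour"].to_numpy(),
    )


def fit_mixed(
    hourly: pd.DataFrame,
    fm: FeatureMatrix,
    variables: list[str],
    period: str,
    trace: list[str] | None = None,
    drop_constant: bool = False,
) -> LurModel:
    """Fit the crossed-intercepts mixed model for one period.

    ``drop_constant=True`` silently removes variables that are constant over
    the rows being fitted (their effect is unidentifiable there) instead of
    raising — used when refitting a fixed variable set on data subsets such
    as cross-validation training folds.
    """
    if hourly["site_id"].nunique() < 10:
        raise FitError("need at least 10 sites for a mixed LUR fit")
    trace = trace if trace is not None else []
    if drop_constant:
        sub = filter_period(hourly, period)
        rows = fm.table.loc[sub["site_id"].unique()]
        kept = []
        for v in variables:
            if v in rows.columns and rows[v].nunique() > 1:
                kept.append(v)
            else:
                trace.append(f"drop {v}: constant over the fitted sites")
        variables = kept
    y, X, site_ids, hour_ids = _design(hourly, fm, variables, period)
    res = fit_crossed_lmm(y, X, site_ids, hour_ids)
    return _package(res, variables, period, fm, trace)


def _package(
    res: CrossedLMMResult,
    variables: list[str],
    period: str,
    fm: FeatureMatrix,
    trace: list[str],
) -> LurModel:
    ci = res.conf_int()
    var_fixed = float(np.var(res.fitted_fixed))
    total = var_fixed + res.sigma2_site + res.sigma2_hour + res.sigma2_resid
    return LurModel(
        period=period,
        variables=list(variables),
        intercept=float(res.beta["intercept"]),
        intercept_ci=(float(ci.loc["intercept", "low"]), float(ci.loc["intercept", "high"])),
        coefficients={v: float(res.beta[v]) for v in variables},
        conf_ints={
            v: (float(ci.loc[v, "low"]), float(ci.loc[v, "high"])) for v in variables
        },
        height_coef=float(res.beta.get("monitor_height_m", 0.0)),
        hour_intercepts={int(h): float(b) for h, b in res.hour_blups.items()},
        site_variance=res.sigma2_site,
        hour_variance=res.sigma2_hour,
        residual_variance=res.sigma2_resid,
        r2_fixed=res.r2_fixed,
        r2_marginal=var_fixed / total if total > 0 else 0.0,
        selection_trace=trace,
        standardization=dict(fm.params),
        n_sites=int(len(res.site_blups)),
        n_obs=res.n_obs,
    )


def best_buffer_per_variable(
    hourly: pd.DataFrame,
    fm: FeatureMatrix,
    catalogue: list[FeatureSpec] | None = None,
    period: str = "day",
) -> pd.DataFrame:
    """Step one of selection: per variable, the most correlated buffer.

    Returns a frame indexed by variable with columns ``column`` (the winning
    matrix column), ``buffer`` (radius or NaN for distance variables), ``r``
    and ``direction_ok``.  Ties in |r| below 1e-6 go to the smaller buffer.
    """
    catalogue = catalogue if catalogue is not None else fm.catalogue
    outcome = site_mean_levels(hourly, period)
    feats = fm.table.loc[outcome.index]
    rows = []
    for spec in catalogue:
        cols = (
            [
                column_name(spec, r)
                for r in fm.buffers.radii_m
                if column_name(spec, r) in feats.columns
            ]
            if spec.buffered
            else ([spec.name] if spec.name in feats.columns else [])
        )
        if not cols:
            continue
        best_col, best_r = None, 0.0
        for col in cols:  # ascending radius order; strict > keeps smaller buffer on ties
            x = feats[col].to_numpy()
            if np.std(x) == 0:
                continue
            r = float(np.corrcoef(x, outcome.to_numpy())[0, 1])
            if best_col is None or abs(r) > abs(best_r) + 1e-6:
                best_col, best_r = col, r
        if best_col is None:
            continue
        _, radius = parse_buffer(best_col, catalogue)
        direction_ok = (
            spec.expected_sign == "either"
            or (spec.expected_sign == "+" and best_r > 0)
            or (spec.expected_sign == "-" and best_r < 0)
        )
        rows.append(
            {
                "variable": spec.name,
                "column": best_col,
                "buffer": radius if radius is not None else np.nan,
                "r": best_r,
                "direction_ok": direction_ok,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def _collinearity_filter(
    candidates: list[str],
    feats: pd.DataFrame,
    outcome_r: dict[str, float],
    threshold: float,
    trace: list[str],
) -> list[str]:
    """Among pairs with |r| > threshold keep the one closer to the outcome."""
    keep = list(candidates)
    i = 0
    while i < len(keep):
        j = i + 1
        while j < len(keep):
            a, b = keep[i], keep[j]
            r = float(np.corrcoef(feats[a], feats[b])[0, 1])
            if abs(r) > threshold:
                drop = b if abs(outcome_r[a]) >= abs(outcome_r[b]) else a
                trace.append(
                    f"collinearity |r|={abs(r):.3f} between {a} and {b}: drop {drop}"
                )
                keep.remove(drop)
                if drop == a:
                    j = i + 1
                    continue
            else:
                j += 1
        i += 1
    return keep


def forward_stepwise(
    hourly: pd.DataFrame,
    fm: FeatureMatrix,
    catalogue: list[FeatureSpec] | None = None,
    config: SelectionConfig | None = None,
    period: str = "day",
) -> LurModel:
    """Two-step forward selection of the period LUR model."""
    config = config or SelectionConfig()
    trace: list[str] = []
    screen = best_buffer_per_variable(hourly, fm, catalogue, period)
    if config.sign_constraint:
        for var, row in screen[~screen["direction_ok"]].iterrows():
            trace.append(
                f"screen: {var} ({row['column']}) excluded, sign of r={row['r']:.3f} "
                "contradicts the a-priori direction"
            )
        screen = screen[screen["direction_ok"]]
    screen = screen.reindex(screen["r"].abs().sort_values(ascending=False).index)
    outcome = site_mean_levels(hourly, period)
    feats = fm.table.loc[outcome.index]
    outcome_r = {row["column"]: row["r"] for _, row in screen.iterrows()}
    candidates = _collinearity_filter(
        list(screen["column"]), feats, outcome_r, config.collinearity_r, trace
    )
    trace.append(f"candidates after screening: {candidates}")

    if not candidates:
        warnings.warn("no candidates survive screening; intercept-only model")
        model = fit_mixed(hourly, fm, [], period, trace)
        trace.append("intercept-only model (no candidates)")
        return model

    selected: list[str] = []
    current = fit_mixed(hourly, fm, selected, period, trace)
    remaining = list(candidates)
    while remaining:
        gains = []
        for col in remaining:
            try:
                m = fit_mixed(hourly, fm, selected + [col], period, trace)
            except FitError:
                gains.append((col, -np.inf, None))
                continue
            gains.append((col, m.r2_fixed - current.r2_fixed, m))
        col, gain, m = max(gains, key=lambda t: t[1])
        if gain < config.r2_gain_threshold or m is None:
            trace.append(
                f"stop: best gain {gain:.4f} from {col} below "
                f"{config.r2_gain_threshold}"
            )
            break
        trace.append(f"add {col}: R2 {current.r2_fixed:.4f} -> {m.r2_fixed:.4f}")
        selected.append(col)
        current = m
        remaining.remove(col)

    current = stability_prune(current, hourly, fm, config)
    trace.extend(current.selection_trace[len(trace):])

    # challenge: excluded candidates re-offered one by one
    for col in candidates:
        if col in current.variables:
            continue
        try:
            m = fit_mixed(hourly, fm, current.variables + [col], period, trace)
        except FitError:
            continue
        gain = m.r2_fixed - current.r2_fixed
        if gain >= config.r2_gain_threshold:
            trace.append(f"challenge: adopt {col}, R2 gain {gain:.4f}")
            current = stability_prune(m, hourly, fm, config)
            trace.extend(current.selection_trace[len(trace):])
        else:
            trace.append(f"challenge: reject {col}, R2 gain {gain:.4f}")

    current.selection_trace = trace
    return current


def is_unstable(
    coef: float, ci: tuple[float, float], t_threshold: float = 1.0
) -> bool:
    """Unstable coefficient rule: CI crosses zero AND |t| below threshold.

    A zero-crossing CI with |t| >= threshold (coefficient magnitude at least
    one standard error) is retained as informative-but-imprecise.
    """
    lo, hi = ci
    if not (lo < 0 < hi):
        return False
    half = (hi - lo) / 2
    if half <= 0:
        return False
    se = half / stats.norm.ppf(0.975)
    return bool(abs(coef) / se < t_threshold)


def stability_prune(
    model: LurModel,
    hourly: pd.DataFrame,
    fm: FeatureMatrix,
    config: SelectionConfig | None = None,
) -> LurModel:
    """Drop unstable coefficients: CI crossing zero with |t| below threshold.

    A zero-crossing CI alone does not disqualify a variable — only when the
    CI half-width also exceeds the coefficient magnitude (|t| < 1 by
    default) is the estimate considered unstable.  Refits after each drop,
    removing the least stable variable first.
    """
    config = config or SelectionConfig()
    trace = list(model.selection_trace)
    current = model
    while current.variables:
        unstable = {}
        for var in current.variables:
            lo, hi = current.conf_ints[var]
            coef = current.coefficients[var]
            if is_unstable(coef, (lo, hi), config.stability_t):
                se = ((hi - lo) / 2) / stats.norm.ppf(0.975)
                unstable[var] = abs(coef) / se
        if not unstable:
            break
        drop = min(unstable, key=unstable.get)
        trace.append(
            f"prune {drop}: CI {current.conf_ints[drop]} crosses zero with "
            f"|t|={unstable[drop]:.2f} < {config.stability_t}"
        )
        variables = [v for v in current.variables if v != drop]
        current = fit_mixed(hourly, fm, variables, current.period, trace)
    current.selection_trace = trace
    return current


def vif(fm: FeatureMatrix, variables: list[str]) -> dict[str, float]:
    """Variance inflation factors of the selected fixed-effect set."""
    if len(variables) < 2:
        raise ValueError("VIF needs at least two variables")
    feats = fm.table[variables].to_numpy(dtype=float)
    out = {}
    for k, var in enumerate(variables):
        yk = feats[:, k]
        Xk = np.column_stack(
            [np.ones(len(yk)), np.delete(feats, k, axis=1)]
        )
        beta, _, _, _ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ beta
        ssr = float(resid @ resid)
        sst = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1 - ssr / sst if sst > 0 else 1.0
        out[var] = float(np.inf) if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# intermittency-ratio models (site-level OLS)


@dataclass
class IrModel:
    """Site-level linear model of the intermittency ratio for one period."""

    period: str
    variables: list[str]
    params: dict[str, float]
    conf_ints: dict[str, tuple[float, float]]
    r2: float
    interaction_terms: list[str] = dc_field(default_factory=list)
    selection_trace: list[str] = dc_field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "period": self.period,
                    "variables": self.variables,
                    "params": self.params,
                    "conf_ints": {k: list(v) for k, v in self.conf_ints.items()},
                    "r2": self.r2,
                    "interaction_terms": self.interaction_terms,
                    "selection_trace": self.selection_trace,
                },
                fh,
                indent=1,
            )


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, X).fit()


def fit_ir_models(
    site_table: pd.DataFrame,
    fm: FeatureMatrix,
    land_use_class: pd.Series | None = None,
    config: SelectionConfig | None = None,
    interaction: bool = True,
) -> dict[str, IrModel]:
    """Forward-selected OLS models for IR_day and IR_night.

    ``site_table`` needs per-site columns ``ir_day``, ``ir_night``,
    ``l_day``, ``l_night`` indexed (or keyed by ``site_id``).  The period
    noise level enters the candidate pool; when ``interaction`` is on and
    sites span >= 2 land-use classes, class interactions on the noise-level
    term are offered after selection.
    """
    config = config or SelectionConfig()
    tab = site_table.set_index("site_id") if "site_id" in site_table.columns else site_table
    out: dict[str, IrModel] = {}
    for period, ir_col, level_col in (
        ("day", "ir_day", "l_day"),
        ("night", "ir_night", "l_night"),
    ):
        y = tab[ir_col].to_numpy(dtype=float)
        trace: list[str] = []
        feats = fm.table.loc[tab.index]
        if np.std(y) == 0:
            out[period] = IrModel(
                period, [], {"intercept": float(y[0]) if len(y) else np.nan},
                {}, 0.0, [], ["constant IR: intercept-only model"],
            )
            continue
        # candidate pool: best-buffer spatial features + the period level
        corr_rows = []
        for col in feats.columns:
            if col in FeatureMatrix.META:
                continue
            x = feats[col].to_numpy(dtype=float)
            if np.std(x) == 0:
                continue
            corr_rows.append((col, float(np.corrcoef(x, y)[0, 1])))
        level = tab[level_col].to_numpy(dtype=float)
        pool = pd.DataFrame(feats[[c for c, _ in corr_rows]])
        pool[level_col] = level
        corr_rows.append((level_col, float(np.corrcoef(level, y)[0, 1])))
        if len(tab) < len(corr_rows) + 2:
            # keep the strongest candidates only so the fit stays identified
            corr_rows = sorted(corr_rows, key=lambda t: -abs(t[1]))[: max(1, len(tab) - 3)]
        # pick one column per variable stem (best |r| buffer), strongest first
        best: dict[str, tuple[str, float]] = {}
        for col, r in corr_rows:
            stem = col if col == level_col else parse_buffer(col, fm.catalogue)[0]
            if stem not in best or abs(r) > abs(best[stem][1]) + 1e-6:
                best[stem] = (col, r)
        ordered = sorted(best.values(), key=lambda t: -abs(t[1]))
        outcome_r = {c: r for c, r in ordered}
        candidates = _collinearity_filter(
            [c for c, _ in ordered], pool, outcome_r, config.collinearity_r, trace
        )

        selected: list[str] = []
        X = pd.DataFrame({"intercept": np.ones(len(y))})
        current = _ols(y, X)
        while candidates:
            gains = []
            for col in candidates:
                Xc = X.copy()
                for s in selected:
                    Xc[s] = pool[s].to_numpy()
                Xc[col] = pool[col].to_numpy()
                m = _ols(y, Xc)
                gains.append((col, m.rsquared - current.rsquared, m))
            col, gain, m = max(gains, key=lambda t: t[1])
            if gain < config.r2_gain_threshold:
                trace.append(f"stop: best gain {gain:.4f} from {col}")
                break
            trace.append(f"add {col}: R2 -> {m.rsquared:.4f}")
            selected.append(col)
            X[col] = pool[col].to_numpy()
            current = m
            candidates.remove(col)

        interaction_terms: list[str] = []
        if interaction and level_col in selected and land_use_class is not None:
            classes = land_use_class.loc[tab.index]
            if classes.nunique() >= 2:
                ref = classes.value_counts().idxmax()
                Xi = X.copy()
                for cls in sorted(classes.unique()):
                    if cls == ref:
                        continue
                    term = f"{level_col}:{cls}"
                    Xi[term] = (classes == cls).to_numpy(dtype=float) * pool[
                        level_col
                    ].to_numpy()
                    interaction_terms.append(term)
                try:
                    mi = _ols(y, Xi)
                    trace.append(
                        f"interaction on {level_col} (ref={ref}): "
                        f"R2 {current.rsquared:.4f} -> {mi.rsquared:.4f}"
                    )
                    current, X = mi, Xi
                except Exception as exc:  # pragma: no cover - defensive
                    trace.append(f"interaction dropped: {exc}")
                    interaction_terms = []
            else:
                warnings.warn("single land-use class: interaction dropped")
                trace.append("interaction dropped: single land-use class")

        ci = current.conf_int()
        out[period] = IrModel(
            period=period,
            variables=selected,
            params={k: float(v) for k, v in current.params.items()},
            conf_ints={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in current.params.index},
            r2=float(current.rsquared),
            interaction_terms=interaction_terms,
            selection_trace=trace,
        )
    return out
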