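"""Model evaluation: site-grouped cross-validation and spatial diagnostics.

Cross-validation always partitions *sites*, never observations, because the
model must generalise to unmonitored locations: a held-out site's hourly
levels are predicted from fixed effects plus the training-data hour
intercepts only (its own site intercept is unobservable).  Errors are
pooled over all held-out site-hour observations across folds.

Moran's I uses row-standardised inverse-distance weights and a seeded
permutation test; its null expectation is -1/(n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .lur import SelectionConfig, filter_period, fit_mixed, forward_stepwise


@dataclass
class CVResult:
    scheme: str  # cv10_sites | loocv
    pooled: dict[str, float]
    per_fold: pd.DataFrame
    predictions: pd.DataFrame = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        pooled_row = pd.DataFrame([{"fold": "pooled", **self.pooled}])
        pd.concat([self.per_fold, pooled_row], ignore_index=True).to_csv(
            path, index=False
        )


def _error_metrics(obs: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    err = pred - obs
    r = float(np.corrcoef(obs, pred)[0, 1]) if np.std(pred) > 0 and np.std(obs) > 0 else 0.0
    return {
        "median_abs_error": float(np.median(np.abs(err))),
        "mean_abs_error": float(np.mean(np.abs(err))),
        "mean_error": float(np.mean(err)),
        "r": r,
        "r2": r * r,
    }


def make_site_folds(site_ids, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of unique sites into k folds (sizes differ by <= 1)."""
    sites = np.asarray(sorted(pd.unique(np.asarray(site_ids))))
    if not 2 <= k <= len(sites):
        raise ValueError("fold count must be between 2 and the number of sites")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    return [sites[order[i::k]] for i in range(k)]


def cross_validate(
    hourly: pd.DataFrame,
    fm: FeatureMatrix,
    variables: list[str],
    period: str,
    scheme: str = "cv10_sites",
    seed: int = 0,
    reselect: bool = False,
    config: SelectionConfig | None = None,
) -> CVResult:
    """Site-grouped cross-validation of a period LUR model.

    ``variables`` is the final fixed set refit in every training fold; with
    ``reselect=True`` the full forward-stepwise selection is instead re-run
    inside each fold (slower, guards against selection optimism).
    """
    sub = filter_period(hourly, period)
    sites = sorted(sub["site_id"].unique())
    if scheme == "loocv":
        k = len(sites)
    elif scheme == "cv10_sites":
        k = 10
    else:
        raise ValueError("scheme must be 'cv10_sites' or 'loocv'")
    folds = make_site_folds(sites, k, seed)

    fold_rows = []
    all_obs, all_pred, all_site = [], [], []
    for i, held_out in enumerate(folds):
        train = sub[~sub["site_id"].isin(held_out)]
        test = sub[sub["site_id"].isin(held_out)]
        if reselect:
            model = forward_stepwise(train, fm, fm.catalogue, config, period)
        else:
            model = fit_mixed(train, fm, variables, period, drop_constant=True)
        feats = fm.table.loc[test["site_id"]]
        pred = model.predict_fixed(feats)
        pred += np.array([model.hour_intercepts.get(int(h), 0.0) for h in test["hour"]])
        obs = test["laeq_1hr_dba"].to_numpy()
        fold_rows.append({"fold": i, "n_sites": len(held_out), **_error_metrics(obs, pred)})
        all_obs.append(obs)
        all_pred.append(pred)
        all_site.append(test["site_id"].to_numpy())

    obs = np.concatenate(all_obs)
    pred = np.concatenate(all_pred)
    preds = pd.DataFrame(
        {"site_id": np.concatenate(all_site), "observed": obs, "predicted": pred}
    )
    return CVResult(
        scheme="loocv" if scheme == "loocv" else "cv10_sites",
        pooled=_error_metrics(obs, pred),
        per_fold=pd.DataFrame(fold_rows),
        predictions=preds,
    )


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Moran's I with row-standardised inverse-distance weights.

    Returns ``I``, ``expected_I`` = -1/(n-1) and a one-sided permutation
    p-value on the observed side of the expectation.
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 8:
        raise ValueError("Moran's I needs at least 8 locations")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if np.any((d == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("coincident locations make inverse-distance weights undefined")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)  # row standardisation

    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant residuals")
    w_sum = w.sum()

    def stat(v: np.ndarray) -> float:
        return float(n / w_sum * (v @ w @ v) / (v @ v))

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        perm[b] = stat(rng.permutation(z))
    if i_obs >= expected:
        p = (1 + np.sum(perm >= i_obs)) / (n_permutations + 1)
    else:
        p = (1 + np.sum(perm <= i_obs)) / (n_permutations + 1)
    return {"I": i_obs, "expected_I": expected, "p": float(p)}


def site_residuals(
    hourly: pd.DataFrame, fm: FeatureMatrix, model, period: str
) -> pd.DataFrame:
    """Per-site mean residual of the fixed-effect + hour-intercept fit."""
    sub = filter_period(hourly, period).copy()
    feats = fm.table.loc[sub["site_id"]]
    pred = model.predict_fixed(feats) + np.array(
        [model.hour_intercepts.get(int(h), 0.0) for h in sub["hour"]]
    )
    sub["resid"] = sub["laeq_1hr_dba"].to_numpy() - pred
    agg = sub.groupby("site_id")["resid"].mean().reset_index()
    coords = fm.table.loc[agg["site_id"], ["x", "y"]].to_numpy()
    agg["x"], agg["y"] = coords[:, 0], coords[:, 1]
    return agg
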