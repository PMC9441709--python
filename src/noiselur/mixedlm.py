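"""Gaussian linear mixed model with two crossed random intercepts.

The model is

    y = X beta + Z_s b_s + Z_h b_h + e,
    b_s ~ N(0, sigma_s^2 I),  b_h ~ N(0, sigma_h^2 I),  e ~ N(0, sigma^2 I),

with site and hour-of-day intercepts crossed (every site is observed in
every hour).  The two variance ratios lambda = sigma_u^2 / sigma^2 are
profiled out of the (RE)ML criterion and optimised directly; all
likelihood evaluations work on precomputed Gram matrices via the Woodbury
identity, so a fit costs O(q^3) per evaluation with q = n_sites + n_hours,
independent of the number of observations.  Fixed-effect covariances are
conditional on the estimated variance parameters (the usual Wald CIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG_LAMBDA_BOUNDS = (-16.0, 12.0)  # lambda in [~1e-7, ~1.6e5]


class FitError(RuntimeError):
    """The model could not be fitted (singular design, degenerate data)."""


@dataclass
class CrossedLMMResult:
    """REML/ML estimates for the crossed random-intercepts model."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_site: float
    sigma2_hour: float
    sigma2_resid: float
    site_blups: pd.Series
    hour_blups: pd.Series
    loglike: float
    reml: bool
    n_obs: int
    fitted_fixed: np.ndarray  # X beta on the training rows
    r2_fixed: float  # squared Pearson r of fixed-effect fit vs observed

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.beta.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se()
        return pd.DataFrame(
            {"low": self.beta - z * se, "high": self.beta + z * se},
            index=self.beta.index,
        )

    def tvalues(self) -> pd.Series:
        return self.beta / self.se()


def _design_checks(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise FitError("more fixed-effect columns than observations")
    # flag the offending columns, not just "singular matrix"
    sd = X.std(axis=0)
    const = [n for n, s, col in zip(names, sd, X.T) if s == 0 and not np.all(col == 1)]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, sd > 0].T) if (sd > 0).sum() > 1 else np.ones((1, 1))
        dup = []
        nz = [n for n, s in zip(names, sd) if s > 0]
        for i in range(len(nz)):
            for j in range(i + 1, len(nz)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    dup.append((nz[i], nz[j]))
        raise FitError(
            f"singular fixed-effect design; constant columns: {const or 'none'}; "
            f"duplicated pairs: {dup or 'none'}"
        )


def fit_crossed_lmm(
    y: np.ndarray,
    X: pd.DataFrame,
    site_ids: np.ndarray,
    hour_ids: np.ndarray,
    reml: bool = True,
) -> CrossedLMMResult:
    """Fit by profiled (RE)ML over the two variance ratios."""
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if y.shape[0] != n:
        raise ValueError("y and X disagree on length")
    _design_checks(Xm, names)

    sites, site_idx = np.unique(site_ids, return_inverse=True)
    hours, hour_idx = np.unique(hour_ids, return_inverse=True)
    S, H = len(sites), len(hours)
    q = S + H

    # sparse-free Gram matrices of the indicator design Z = [Z_s Z_h]
    ZtZ = np.zeros((q, q))
    np.add.at(ZtZ, (site_idx, site_idx), 1.0)
    np.add.at(ZtZ, (S + hour_idx, S + hour_idx), 1.0)
    cross = np.zeros((S, H))
    np.add.at(cross, (site_idx, hour_idx), 1.0)
    ZtZ[:S, S:] = cross
    ZtZ[S:, :S] = cross.T

    ZtX = np.zeros((q, p))
    np.add.at(ZtX, site_idx, Xm)
    np.add.at(ZtX, S + hour_idx, Xm)
    Zty = np.zeros(q)
    np.add.at(Zty, site_idx, y)
    np.add.at(Zty, S + hour_idx, y)

    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)
    dof = n - p if reml else n

    def profile(theta: np.ndarray):
        lam = np.exp(np.clip(theta, *_LOG_LAMBDA_BOUNDS))
        inv_lam = np.concatenate([np.full(S, 1.0 / lam[0]), np.full(H, 1.0 / lam[1])])
        M = ZtZ + np.diag(inv_lam)
        try:
            cM = linalg.cho_factor(M, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise FitError(f"random-effect system not positive definite: {exc}")
        # log|I + Lambda Z'Z| = log|M| + sum log lam
        logdet_V0 = 2.0 * np.log(np.diag(cM[0])).sum() + S * np.log(
            lam[0]
        ) + H * np.log(lam[1])
        Minv_ZtX = linalg.cho_solve(cM, ZtX, check_finite=False)
        Minv_Zty = linalg.cho_solve(cM, Zty, check_finite=False)
        XtViX = XtX - ZtX.T @ Minv_ZtX
        XtViy = Xty - ZtX.T @ Minv_Zty
        ytViy = yty - Zty @ Minv_Zty
        try:
            cX = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"fixed-effect system singular at lambda={lam}: {exc}")
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - beta @ XtViy, 1e-300)  # r' V0^{-1} r at the GLS solution
        crit = logdet_V0 + dof * np.log(rss)
        if reml:
            crit += 2.0 * np.log(np.diag(cX)).sum()
        return crit, beta, XtViX, rss, M, lam

    def objective(theta: np.ndarray) -> float:
        return profile(theta)[0]

    # the 2-parameter profiled criterion is smooth; a coarse grid seeds a
    # quasi-Newton run (finite-difference gradients), with a simplex polish
    # as a fallback against a sloppy line search
    grid = [-6.0, -2.0, 0.0, 2.0]
    start = min(
        ([a, b] for a in grid for b in grid), key=lambda t: objective(np.asarray(t))
    )
    best = optimize.minimize(
        objective,
        np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=[_LOG_LAMBDA_BOUNDS] * 2,
        options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 200},
    )
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 100},
    )
    if polish.fun < best.fun:
        best = polish
    theta = np.clip(best.x, *_LOG_LAMBDA_BOUNDS)
    crit, beta, XtViX, rss, M, lam = profile(theta)

    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    resid_contracted = (Zty - ZtX @ beta)
    blups = np.linalg.solve(M, resid_contracted)

    const = dof * (1 + np.log(2 * np.pi / dof))
    loglike = -0.5 * (crit + const)

    fitted_fixed = Xm @ beta
    denom = float(np.std(fitted_fixed) * np.std(y))
    r2_fixed = (
        float(np.corrcoef(fitted_fixed, y)[0, 1] ** 2) if denom > 1e-300 else 0.0
    )

    return CrossedLMMResult(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2_site=float(lam[0] * sigma2),
        sigma2_hour=float(lam[1] * sigma2),
        sigma2_resid=float(sigma2),
        site_blups=pd.Series(blups[:S], index=sites),
        hour_blups=pd.Series(blups[S:], index=hours),
        loglike=float(loglike),
        reml=reml,
        n_obs=n,
        fitted_fixed=fitted_fixed,
        r2_fixed=r2_fixed,
    )
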