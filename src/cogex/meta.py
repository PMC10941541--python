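"""Random-effects pooling of regional standardized betas across cohorts.

DerSimonian-Laird (method-of-moments) estimation is the default, with
Benjamini-Hochberg FDR control applied within each morphometry measure's
family of regions, and weighted meta-regression for cohort mean-age
moderation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, InvalidParameterError, NotIdentifiableError


@dataclass
class MetaResult:
    """Pooled estimate for one region x measure cell."""

    beta: float
    se: float
    tau2: float
    q: float
    k: int
    p: float
    degenerate: bool = False  # k == 1


def dersimonian_laird(betas, ses) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates.

    Fixed-effect weights w_i = 1/SE_i^2 give the heterogeneity statistic
    Q = sum w_i (b_i - b_F)^2; tau^2 = max(0, (Q - (k-1)) / (sum w - sum
    w^2 / sum w)); the pooled estimate uses random-effects weights
    1/(SE_i^2 + tau^2).  The p-value uses the standard normal reference.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.ndim != 1 or b.shape != s.shape or b.size < 1:
        raise InvalidParameterError("betas and ses must be equal-length vectors")
    if np.any(s <= 0):
        raise InvalidParameterError("all standard errors must be positive")
    k = b.size
    if k == 1:
        p = 2 * stats.norm.sf(abs(b[0] / s[0]))
        return MetaResult(float(b[0]), float(s[0]), 0.0, 0.0, 1, float(p),
                          degenerate=True)
    w = 1.0 / s**2
    b_fixed = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - b_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (s**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MetaResult(beta, se, tau2, q, k, p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_meta_grid(
    associations: pd.DataFrame,
    fdr_family: str = "measure",
) -> pd.DataFrame:
    """Pool stacked per-cohort regional associations into one row per
    region x measure.

    ``associations`` needs columns ``cohort, region, measure, beta, se``.
    Regions present in only some cohorts are pooled over the cohorts
    available, with ``k`` recording how many.  FDR is controlled within each
    measure's family of regions by default (``fdr_family="global"`` pools all
    cells into one family).
    """
    required = {"cohort", "region", "measure", "beta", "se"}
    missing = required - set(associations.columns)
    if missing:
        raise InvalidParameterError(f"missing columns: {sorted(missing)}")
    rows = []
    for (region, measure), grp in associations.groupby(["region", "measure"],
                                                       sort=True):
        res = dersimonian_laird(grp["beta"].to_numpy(), grp["se"].to_numpy())
        rows.append(
            {
                "region": region,
                "measure": measure,
                "beta": res.beta,
                "se": res.se,
                "tau2": res.tau2,
                "q_het": res.q,
                "k": res.k,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = np.nan
    if fdr_family == "global":
        out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    else:
        for measure, grp in out.groupby("measure"):
            out.loc[grp.index, "fdr_q"] = bh_fdr(grp["p"].to_numpy())
    return out


def _moderator_tau2(b, s, x) -> float:
    """Method-of-moments residual tau^2 under a linear moderator model."""
    k = b.size
    w = 1.0 / s**2
    X = np.column_stack([np.ones(k), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ (w * b))
    resid = b - X @ coef
    q_e = float(np.sum(w * resid**2))
    # trace correction: tr(W) - tr((X'WX)^-1 X'W^2X)
    denom = np.sum(w) - np.trace(np.linalg.solve(xtwx, X.T @ np.diag(w**2) @ X))
    return max(0.0, (q_e - (k - 2)) / denom)


def age_moderation(betas, ses, mean_ages) -> dict:
    """Meta-regression of cohort estimates on cohort mean age.

    Weighted least squares with weights 1/(SE_i^2 + tau^2), tau^2
    re-estimated by method of moments under the moderator model (floored at
    0).  Returns the moderator slope, its SE and a normal-reference p-value.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    x = np.asarray(mean_ages, dtype=float)
    k = b.size
    if k < 3:
        raise NotIdentifiableError("age moderation needs at least 3 cohorts")
    if np.ptp(x) == 0:
        raise CollinearityError(["mean_age"], "mean ages identical across cohorts")
    tau2 = _moderator_tau2(b, s, x)
    w = 1.0 / (s**2 + tau2)
    X = np.column_stack([np.ones(k), x])
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)
    coef = cov @ (X.T @ (w * b))
    slope = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.norm.sf(abs(slope / se)))
    return {"slope": slope, "se": se, "p": p, "tau2": tau2, "k": k}


def age_moderation_grid(associations: pd.DataFrame, cohort_ages: dict) -> pd.DataFrame:
    """Age-moderation meta-regression for every region x measure cell,
    FDR-corrected across the grid (one family)."""
    rows = []
    for (region, measure), grp in associations.groupby(["region", "measure"]):
        ages = grp["cohort"].map(cohort_ages).to_numpy(dtype=float)
        res = age_moderation(grp["beta"].to_numpy(), grp["se"].to_numpy(), ages)
        rows.append({"region": region, "measure": measure, **res})
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out
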