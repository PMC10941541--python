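"""Per-region standardized associations between g and cortical morphometry.

Each association is the coefficient of the g factor score in a least-squares
regression of a z-standardized regional measure on g plus nuisance
covariates (age, sex, scanner head position, site dummies, optional
test-to-scan lag, optional global measure).  Outliers are removed beforehand
with a fixed SD rule computed once from the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, DegenerateInputError, InvalidParameterError

MEASURES = ("volume", "surface_area", "thickness")


@dataclass
class RegionalAssociation:
    cohort: str
    region: str
    measure: str
    beta: float
    se: float
    n_effective: int
    p: float


def exclude_outliers(values, sd_threshold: float = 4.0):
    """Set values beyond ``sd_threshold`` sample SDs from the mean to NaN.

    The z-scores are computed once from the full sample (per column for a
    DataFrame).  Returns ``(filtered, n_excluded)`` where ``n_excluded`` is a
    per-column Series for DataFrame input.
    """
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        if arr.shape[0] < 10:
            raise InvalidParameterError("need at least 10 observations")
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
        zero = sd == 0
        sd = np.where(zero, 1.0, sd)
        z = (arr - mean) / sd
        mask = np.abs(z) > sd_threshold
        mask &= ~zero[None, :]
        out = arr.copy()
        out[mask] = np.nan
        counts = pd.Series(mask.sum(axis=0), index=values.columns)
        return pd.DataFrame(out, index=values.index, columns=values.columns), counts
    series = pd.Series(values, dtype=float)
    if series.notna().sum() < 10:
        raise InvalidParameterError("need at least 10 observations")
    sd = series.std(ddof=1)
    if sd == 0:
        return series.copy(), 0
    z = (series - series.mean()) / sd
    mask = z.abs() > sd_threshold
    out = series.copy()
    out[mask] = np.nan
    return out, int(mask.sum())


def _check_design(X: np.ndarray, names, cond_limit: float = 1e10) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1] or np.linalg.cond(X) > cond_limit:
        # locate the offending columns: those whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):  # skip intercept
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise CollinearityError(bad or names)


def regional_beta(
    morphometry,
    g,
    covariates: pd.DataFrame | None = None,
    global_measure=None,
    cohort: str = "",
    region: str = "",
    measure: str = "",
    min_n: int = 50,
) -> RegionalAssociation:
    """Standardized association between g and one regional measure.

    The measure and g are z-standardized on the complete-case analysis
    sample; the coefficient of g from OLS of the measure on g + covariates
    (+ optional global measure) is returned with its SE and two-sided
    t-based p-value.  Missing covariates cause casewise deletion.
    """
    y = pd.Series(np.asarray(morphometry, dtype=float))
    gz = pd.Series(np.asarray(g, dtype=float))
    parts = {"g": gz}
    if covariates is not None:
        for name, col in covariates.items():
            parts[str(name)] = pd.Series(np.asarray(col, dtype=float))
    if global_measure is not None:
        parts["global"] = pd.Series(np.asarray(global_measure, dtype=float))
    frame = pd.DataFrame(parts)
    frame["y"] = y.to_numpy()
    frame = frame.dropna()
    n = len(frame)
    if n < min_n:
        raise InvalidParameterError(f"only {n} complete cases (< {min_n})")

    def z(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("zero variance in analysis sample")
        return (v - v.mean()) / sd

    yv = z(frame["y"]).to_numpy()
    gv = z(frame["g"]).to_numpy()
    names = ["intercept", "g"]
    cols = [np.ones(n), gv]
    for name in frame.columns:
        if name in ("y", "g"):
            continue
        cols.append(frame[name].to_numpy())
        names.append(name)
    X = np.column_stack(cols)
    _check_design(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df if df > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    if se > 0:
        p = float(2 * stats.t.sf(abs(beta / se), df))
    else:
        p = 0.0
    return RegionalAssociation(cohort, region, measure, beta, se, n, p)


def site_dummies(site: pd.Series) -> pd.DataFrame:
    """Dummy-code a categorical site column (first level as reference)."""
    d = pd.get_dummies(pd.Series(site).astype("category"), prefix="site",
                       drop_first=True, dtype=float)
    return d


def cohort_regional_betas(
    cohort_df: pd.DataFrame,
    g_scores: pd.Series,
    region_ids,
    measures=MEASURES,
    covariate_columns=("age", "sex", "head_x", "head_y", "head_z"),
    site_column: str | None = "site",
    lag_column: str | None = None,
    sd_threshold: float = 4.0,
    global_correct: bool = False,
    cohort: str = "",
    measure_prefix: str = "{measure}__{region}",
) -> pd.DataFrame:
    """All region x measure associations for one cohort, as a tidy table.

    Morphometry columns are located as ``<measure>__<region>``; outliers are
    excluded per column with the SD rule before standardization.  With
    ``global_correct`` the whole-cortex measure (sum for volume and surface
    area, mean for thickness) is added as a covariate.
    """
    covs = cohort_df.loc[:, list(covariate_columns)].astype(float).copy()
    if site_column is not None and site_column in cohort_df:
        covs = pd.concat([covs, site_dummies(cohort_df[site_column])], axis=1)
    if lag_column is not None and lag_column in cohort_df:
        covs["lag"] = cohort_df[lag_column].astype(float)

    rows = []
    for measure in measures:
        cols = [measure_prefix.format(measure=measure, region=r) for r in region_ids]
        block = cohort_df.loc[:, cols].astype(float)
        block, _ = exclude_outliers(block, sd_threshold=sd_threshold)
        global_series = None
        if global_correct:
            agg = block.mean(axis=1) if measure == "thickness" else block.sum(axis=1)
            global_series = agg
        for region, col in zip(region_ids, cols):
            res = regional_beta(
                block[col],
                g_scores,
                covariates=covs,
                global_measure=global_series,
                cohort=cohort,
                region=region,
                measure=measure,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def whole_cortex_beta(
    cohort_df: pd.DataFrame,
    g_scores: pd.Series,
    region_ids,
    measure: str,
    covariate_columns=("age", "sex", "head_x", "head_y", "head_z"),
    site_column: str | None = "site",
    cohort: str = "",
    measure_prefix: str = "{measure}__{region}",
) -> RegionalAssociation:
    """Association between g and the whole-cortex measure (sum of volume or
    surface area, mean thickness) — the same code path as regional betas."""
    cols = [measure_prefix.format(measure=measure, region=r) for r in region_ids]
    block = cohort_df.loc[:, cols].astype(float)
    agg = block.mean(axis=1) if measure == "thickness" else block.sum(axis=1)
    covs = cohort_df.loc[:, list(covariate_columns)].astype(float).copy()
    if site_column is not None and site_column in cohort_df:
        covs = pd.concat([covs, site_dummies(cohort_df[site_column])], axis=1)
    return regional_beta(
        agg, g_scores, covariates=covs, cohort=cohort,
        region="whole_cortex", measure=measure,
    )
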