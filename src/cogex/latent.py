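"""One-factor latent g model via full-information maximum likelihood (FIML).

The measurement model is x = mu + lambda * g + e with Var(g) fixed to 1 for
identification, diagonal residual variances, and optional residual
covariances between tests sharing a cognitive domain (the usual way to
absorb domain structure without a second-order factor).  The likelihood is
the casewise multivariate normal evaluated per missingness pattern, so all
observed data contribute (MCAR/MAR-consistent).  Fit is judged against the
FIML-saturated model (EM-estimated under missingness) with the conventional
CFI / TLI / RMSEA / SRMR indices, and factor scores use the regression
method per pattern.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidParameterError,
    NotIdentifiableError,
)

logger = logging.getLogger(__name__)

_LOGV_FLOOR = np.log(1e-6)


@dataclass
class LatentGModel:
    """Fitted one-factor model: loadings, residual structure, fit, scores."""

    lambda_: pd.Series
    theta: pd.DataFrame  # full residual covariance matrix
    mu: pd.Series
    fit: dict
    loglik: float
    n: int
    df: int
    converged: bool
    heywood: bool = False
    orientation: int = 1
    n_free: int = 0
    sample_cov: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def implied_cov(self) -> np.ndarray:
        lam = self.lambda_.to_numpy()
        return np.outer(lam, lam) + self.theta.to_numpy()


def residualize_tests(scores: pd.DataFrame, age, sex) -> pd.DataFrame:
    """Per-test residuals of OLS regression on age and sex.

    Missingness is preserved; each test needs >= 10 complete cases and
    non-zero variance.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    out = scores.astype(float).copy()
    X_full = np.column_stack([np.ones_like(age), age, sex])
    for col in scores.columns:
        y = out[col].to_numpy()
        ok = np.isfinite(y) & np.isfinite(age) & np.isfinite(sex)
        if ok.sum() < 10:
            raise InvalidParameterError(f"test {col!r}: fewer than 10 complete cases")
        if np.ptp(y[ok]) == 0:
            raise DegenerateInputError(f"test {col!r} is constant")
        coef, *_ = np.linalg.lstsq(X_full[ok], y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - X_full[ok] @ coef
        out[col] = resid
    return out


def _pattern_groups(values: np.ndarray):
    """Group rows by missingness pattern -> list of (obs_idx, n, xbar, scatter).

    ``scatter`` is the average outer-product matrix around the pattern mean,
    so the FIML objective only needs one rank-1 update per pattern.
    """
    mask = np.isfinite(values)
    patterns = {}
    for i, row in enumerate(mask):
        key = row.tobytes()
        patterns.setdefault(key, []).append(i)
    groups = []
    for key, rows in patterns.items():
        obs = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if obs.size == 0:
            continue
        block = values[np.ix_(rows, obs)]
        n_p = block.shape[0]
        xbar = block.mean(axis=0)
        centered = block - xbar
        scatter = centered.T @ centered / n_p
        groups.append((obs, n_p, xbar, scatter))
    return groups


def _fiml_nll_grad(params, groups, p, cov_pairs):
    """Negative FIML log-likelihood and analytic gradient.

    Parameter vector: [lambda (p), log residual variances (p),
    residual covariances (len(cov_pairs)), mu (p)].
    """
    q = len(cov_pairs)
    lam = params[:p]
    logv = params[p : 2 * p]
    covs = params[2 * p : 2 * p + q]
    mu = params[2 * p + q :]
    theta = np.diag(np.exp(logv))
    for c, (i, j) in zip(covs, cov_pairs):
        theta[i, j] = theta[j, i] = c
    sigma = np.outer(lam, lam) + theta

    nll = 0.0
    G = np.zeros((p, p))  # d nll / d Sigma (symmetric accumulation)
    gmu = np.zeros(p)
    log2pi = np.log(2 * np.pi)
    for obs, n_p, xbar, scatter in groups:
        sub = sigma[np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(params)
        logdet = 2 * np.sum(np.log(np.diag(chol)))
        inv = np.linalg.inv(sub)
        d = xbar - mu[obs]
        s_star = scatter + np.outer(d, d)
        nll += 0.5 * n_p * (obs.size * log2pi + logdet + np.sum(inv * s_star))
        g_sub = 0.5 * n_p * (inv - inv @ s_star @ inv)
        G[np.ix_(obs, obs)] += g_sub
        gmu[obs] += -n_p * (inv @ d)

    grad = np.empty_like(params)
    grad[:p] = 2 * (G @ lam)
    grad[p : 2 * p] = np.diag(G) * np.exp(logv)
    for a, (i, j) in enumerate(cov_pairs):
        grad[2 * p + a] = 2 * G[i, j]
    grad[2 * p + q :] = gmu
    return nll, grad


def _model_loglik(params, groups, p, cov_pairs) -> float:
    return -_fiml_nll_grad(params, groups, p, cov_pairs)[0]


def _pairwise_cov(values: np.ndarray):
    """Pairwise-complete mean vector and covariance (ridge-fixed to PD)."""
    df = pd.DataFrame(values)
    mu = df.mean().to_numpy()
    S = df.cov(ddof=0).to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    w = np.linalg.eigvalsh(S)
    if w.min() < 1e-8:
        S += (1e-8 - min(w.min(), 0.0)) * np.eye(S.shape[0])
    return mu, S


def saturated_loglik(values: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """FIML log-likelihood, mean and covariance of the saturated MVN model.

    Closed form for complete data; EM for arbitrary missingness patterns.
    """
    n, p = values.shape
    mask = np.isfinite(values)
    if mask.all():
        mu = values.mean(axis=0)
        centered = values - mu
        S = centered.T @ centered / n
        sign, logdet = np.linalg.slogdet(S)
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
        return ll, mu, S
    mu, S = _pairwise_cov(values)
    groups = _pattern_groups(values)
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step sufficient statistics
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        n_tot = 0
        for obs, n_p, xbar, scatter in groups:
            mis = np.setdiff1d(np.arange(p), obs)
            S_oo = S[np.ix_(obs, obs)]
            inv = np.linalg.inv(S_oo)
            d = xbar - mu[obs]
            s_star = scatter + np.outer(d, d)  # E[(x_o-mu)(x_o-mu)'] per case
            ex = np.zeros(p)
            ex[obs] = xbar
            exx = np.zeros((p, p))
            exx[np.ix_(obs, obs)] = scatter + np.outer(xbar, xbar)
            if mis.size:
                B = S[np.ix_(mis, obs)] @ inv  # regression of mis on obs
                m_mis = mu[mis] + B @ d
                ex[mis] = m_mis
                C = S[np.ix_(mis, mis)] - B @ S[np.ix_(obs, mis)]
                # E[x_m x_o'] and E[x_m x_m'] averaged over the pattern
                cross = np.outer(mu[mis], xbar) + B @ (
                    scatter + np.outer(d, xbar)
                )
                exx[np.ix_(mis, obs)] = cross
                exx[np.ix_(obs, mis)] = cross.T
                exx[np.ix_(mis, mis)] = (
                    C
                    + np.outer(mu[mis], mu[mis])
                    + np.outer(mu[mis], B @ d)
                    + np.outer(B @ d, mu[mis])
                    + B @ s_star @ B.T
                )
            sum_x += n_p * ex
            sum_xx += n_p * exx
            n_tot += n_p
        mu = sum_x / n_tot
        S = sum_xx / n_tot - np.outer(mu, mu)
        ll = _gaussian_pattern_loglik(groups, mu, S)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return ll, mu, S


def _gaussian_pattern_loglik(groups, mu, S) -> float:
    ll = 0.0
    log2pi = np.log(2 * np.pi)
    for obs, n_p, xbar, scatter in groups:
        sub = S[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(sub)
        inv = np.linalg.inv(sub)
        d = xbar - mu[obs]
        ll -= 0.5 * n_p * (
            obs.size * log2pi + logdet + np.sum(inv * (scatter + np.outer(d, d)))
        )
    return ll


def baseline_loglik(values: np.ndarray) -> tuple[float, int]:
    """Independence (diagonal covariance) FIML log-likelihood and df."""
    n, p = values.shape
    ll = 0.0
    for j in range(p):
        x = values[:, j]
        x = x[np.isfinite(x)]
        var = x.var(ddof=0)
        ll -= 0.5 * x.size * (np.log(2 * np.pi) + np.log(var) + 1)
    df = p * (p - 1) // 2
    return ll, df


def _domain_cov_pairs(columns, domain_labels, residual_cov_domains):
    if domain_labels is None or not residual_cov_domains:
        return []
    labels = pd.Series(domain_labels)
    pairs = []
    for dom in residual_cov_domains:
        members = [i for i, col in enumerate(columns) if labels.get(col) == dom]
        pairs.extend(itertools.combinations(members, 2))
    return pairs


def fit_one_factor(
    data: pd.DataFrame,
    domain_labels=None,
    residual_cov_domains=None,
    max_iter: int = 2000,
    n_restarts: int = 5,
    chi2_denominator: str = "n",
    seed: int = 0,
) -> LatentGModel:
    """Fit the one-factor g model by FIML.

    ``data`` holds the (age/sex-residualized) test scores, one column per
    test, NaN for missing.  ``residual_cov_domains`` lists the domains (as
    labelled in ``domain_labels``, a mapping test -> domain) whose member
    tests receive free within-domain residual covariances.  Identification
    fixes the factor variance to 1; loadings are oriented so their sum is
    positive.  Negative residual variances are floored at 1e-6 and flagged
    (Heywood).
    """
    if data.shape[1] < 3:
        raise InvalidParameterError("one-factor model needs at least 3 tests")
    values = data.to_numpy(dtype=float)
    n, p = values.shape
    cov_pairs = _domain_cov_pairs(list(data.columns), domain_labels,
                                  residual_cov_domains)
    q = len(cov_pairs)
    n_free = 2 * p + q  # covariance-structure parameters (means are saturated)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise NotIdentifiableError(f"negative df ({df}): too many free parameters")

    groups = _pattern_groups(values)
    mu0, S0 = _pairwise_cov(values)
    w, v = np.linalg.eigh(S0)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
    if lam0.sum() < 0:
        lam0 = -lam0
    theta0 = np.clip(np.diag(S0) - lam0**2, 0.05 * np.diag(S0), None)
    theta0 = np.clip(theta0, 1e-4, None)

    x0 = np.concatenate([lam0, np.log(theta0), np.zeros(q), mu0])
    bounds = (
        [(None, None)] * p
        + [(_LOGV_FLOOR, 20.0)] * p
        + [(None, None)] * q
        + [(None, None)] * p
    )
    rng = np.random.default_rng(seed)
    best = None
    trace = []
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.1, size=x0.size)
        res = optimize.minimize(
            _fiml_nll_grad,
            start,
            args=(groups, p, cov_pairs),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        trace.append((attempt, res.fun, res.message))
        if res.success or res.status == 0:
            best = res
            break
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("FIML optimization failed", trace=trace)
    converged = bool(best.success)
    if not converged:
        logger.warning("FIML optimizer stopped without clean convergence: %s",
                       best.message)

    params = best.x
    lam = params[:p].copy()
    logv = params[p : 2 * p]
    covs = params[2 * p : 2 * p + q]
    mu = params[2 * p + q :]
    heywood = bool(np.any(logv <= _LOGV_FLOOR + 1e-9))
    if heywood:
        logger.warning("Heywood case: residual variance floored at 1e-6")
    if lam.sum() < 0:
        lam = -lam
    theta = np.diag(np.exp(logv))
    for c, (i, j) in zip(covs, cov_pairs):
        theta[i, j] = theta[j, i] = c

    ll_model = -best.fun
    ll_sat, mu_sat, S_sat = saturated_loglik(values)
    ll_base, df_base = baseline_loglik(values)
    chi2_m = max(0.0, 2 * (ll_sat - ll_model))
    chi2_b = max(0.0, 2 * (ll_sat - ll_base))
    if chi2_denominator == "n-1":
        chi2_m *= (n - 1) / n
        chi2_b *= (n - 1) / n
    sigma_model = np.outer(lam, lam) + theta
    indices = fit_indices(chi2_m, df, chi2_b, df_base, n, S=S_sat,
                          sigma=sigma_model)
    indices.update({"chi2": chi2_m, "df": df, "chi2_baseline": chi2_b,
                    "df_baseline": df_base})

    cols = data.columns
    return LatentGModel(
        lambda_=pd.Series(lam, index=cols, name="lambda"),
        theta=pd.DataFrame(theta, index=cols, columns=cols),
        mu=pd.Series(mu, index=cols, name="mu"),
        fit=indices,
        loglik=ll_model,
        n=n,
        df=df,
        converged=converged,
        heywood=heywood,
        n_free=n_free,
        sample_cov=pd.DataFrame(S_sat, index=cols, columns=cols),
    )


def fit_indices(chi2_m, df_m, chi2_b, df_b, n, S=None, sigma=None) -> dict:
    """CFI, TLI, RMSEA and SRMR from model and baseline chi-square values.

    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    TLI = ((chi2_b/df_b) - (chi2_m/df_m)) / ((chi2_b/df_b) - 1);
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m * n)); SRMR is the root mean
    squared standardized covariance residual over the lower triangle
    including the diagonal.  With df_m = 0: RMSEA = 0 and TLI is reported as
    NaN.
    """
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_m == 0:
        tli = np.nan
        rmsea = 0.0
    else:
        ratio_b = chi2_b / df_b if df_b > 0 else np.nan
        tli = (ratio_b - chi2_m / df_m) / (ratio_b - 1) if ratio_b != 1 else np.nan
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * n)))
    out = {"CFI": float(cfi), "TLI": float(tli) if np.isfinite(tli) else np.nan,
           "RMSEA": float(rmsea)}
    if S is not None and sigma is not None:
        S = np.asarray(S, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
        resid = (S - sigma) / d
        tril = resid[np.tril_indices_from(resid)]
        out["SRMR"] = float(np.sqrt(np.mean(tril**2)))
    return out


def factor_scores(model: LatentGModel, data: pd.DataFrame) -> pd.Series:
    """Regression-method g scores, per missingness pattern.

    score = lambda_o' Sigma_oo^{-1} (x_o - mu_o) with factor variance 1.
    Participants with all tests missing get NaN.
    """
    values = data.loc[:, model.lambda_.index].to_numpy(dtype=float)
    lam = model.lambda_.to_numpy()
    mu = model.mu.to_numpy()
    sigma = model.implied_cov
    mask = np.isfinite(values)
    out = np.full(values.shape[0], np.nan)
    cache = {}
    for i in range(values.shape[0]):
        key = mask[i].tobytes()
        obs = np.flatnonzero(mask[i])
        if obs.size == 0:
            continue
        if key not in cache:
            inv = np.linalg.inv(sigma[np.ix_(obs, obs)])
            cache[key] = lam[obs] @ inv
        out[i] = cache[key] @ (values[i, obs] - mu[obs])
    return pd.Series(out, index=data.index, name="g") * model.orientation


def orient_g(scores: pd.Series, reference_test) -> pd.Series:
    """Flip scores so they correlate positively with a higher-is-better test."""
    ref = np.asarray(reference_test, dtype=float)
    s = scores.to_numpy(dtype=float)
    ok = np.isfinite(ref) & np.isfinite(s)
    if ok.sum() < 3:
        raise InvalidParameterError("too few joint observations to orient scores")
    r = np.corrcoef(s[ok], ref[ok])[0, 1]
    return -scores if r < 0 else scores.copy()
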