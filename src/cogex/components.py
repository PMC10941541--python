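"""Principal components of regional gene expression and their validation.

The decomposition is a correlation-matrix PCA with regions as observations and
genes as variables: every gene is standardized across regions, the
standardized matrix is decomposed by singular values, and loadings are scaled
to gene-component correlations.  Regional scores are the standardized data
projected on unit-norm weights and then z-scaled separately per hemisphere to
remove the left/right sampling artefact.  Validation follows the factor
congruence (Tucker phi) tradition: split-region stability and cross-model
comparison with best-match component assignment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import scale_by_hemisphere
from .errors import (
    InsufficientOverlapError,
    InvalidParameterError,
    UndefinedCongruenceError,
)

logger = logging.getLogger(__name__)


@dataclass
class ComponentModel:
    """Loadings, scores and variance shares of a fitted component solution."""

    loadings: pd.DataFrame  # genes x k, correlation scale
    scores: pd.DataFrame  # regions x k, z-units per hemisphere
    variance_explained: np.ndarray  # per component, percent of total
    rotation: str  # "none" | "varimax"
    k: int
    eigenvalue_shares: np.ndarray = field(default=None, repr=False)  # full spectrum, %

    def __post_init__(self):
        if np.any(np.abs(self.loadings.to_numpy()) > 1 + 1e-8):
            raise InvalidParameterError("correlation-scale loadings exceed 1")


@dataclass
class CongruenceReport:
    """Pairwise congruence coefficients plus per-component summaries."""

    pairs: pd.DataFrame  # columns: comp_a, comp_b, phi (+ context columns)
    summary: pd.DataFrame  # per component: mean and SD of |phi|
    context: str = ""
    assignment: list | None = None  # [(comp_a, comp_b), ...] for matched reports
    matrix: pd.DataFrame | None = None  # full |phi| matrix for matched reports


def congruence(a, b) -> float:
    """Tucker congruence coefficient between two loading vectors.

    phi = sum(a*b) / sqrt(sum(a^2) * sum(b^2)); scale-invariant, in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InvalidParameterError("congruence requires equal-length vectors")
    na = np.sum(a * a)
    nb = np.sum(b * b)
    if na == 0 or nb == 0:
        raise UndefinedCongruenceError("congruence undefined for a zero vector")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def _varimax_rotation(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """Orthogonal varimax rotation matrix for a p x k loading block."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return rot


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 1000):
    """Varimax-rotate loading columns; returns (rotated, rotation_matrix).

    With ``kaiser=True`` rows are normalized to unit communality before
    rotation and rescaled afterwards (Kaiser normalization).
    """
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        rot = _varimax_rotation(L / h[:, None], tol=tol, max_iter=max_iter)
    else:
        rot = _varimax_rotation(L, tol=tol, max_iter=max_iter)
    return L @ rot, rot


def _standardize_columns(X: np.ndarray):
    """Z-score columns (ddof=1); returns (Z, kept_column_mask)."""
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def _decompose(Z: np.ndarray):
    """SVD of a standardized matrix -> (scores_basis U, eigvals, weights V)."""
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    return U, s, Vt.T, eigvals


def _canonicalize_sign(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Flip components so the largest-magnitude loading is positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            if scores is not None:
                scores[:, j] *= -1
    return loadings, scores


def fit_components(
    X: pd.DataFrame,
    k: int = 2,
    rotate: str = "varimax",
    hemisphere_scale_scores: bool = True,
) -> ComponentModel:
    """Fit the first ``k`` components of a region x gene expression matrix.

    Zero-variance gene columns are dropped with a warning.  ``rotate`` is
    ``"varimax"`` (Kaiser-normalized, applied to the first k loading columns)
    or ``"none"``.  Variance explained per component is the column sum of
    squared correlation-scale loadings divided by the number of genes.
    """
    if rotate not in ("varimax", "none"):
        raise InvalidParameterError(f"unknown rotation {rotate!r}")
    n_regions, n_genes = X.shape
    if k > min(n_regions - 1, n_genes):
        raise InvalidParameterError(
            f"k={k} exceeds min(regions-1, genes) = {min(n_regions - 1, n_genes)}"
        )
    values = X.to_numpy(dtype=float)
    Z, keep = _standardize_columns(values)
    if not keep.all():
        logger.warning("dropped %d zero-variance gene column(s)", int((~keep).sum()))
    genes = X.columns[keep]
    p = Z.shape[1]
    n = Z.shape[0]

    U, s, V, eigvals = _decompose(Z)
    # correlation-scale loadings for the full spectrum
    loadings_full = V * (s / np.sqrt(n - 1))
    eig_shares = eigvals / p * 100.0

    Lk = loadings_full[:, :k].copy()
    Wk = V[:, :k].copy()  # unit-norm projection weights
    if rotate == "varimax" and k >= 2:
        Lk, rot = varimax(Lk, kaiser=True)
        Wk = Wk @ rot
    raw_scores = Z @ Wk
    Lk, raw_scores = _canonicalize_sign(Lk, raw_scores)

    ve = (Lk**2).sum(axis=0) / p * 100.0
    scores = pd.DataFrame(
        raw_scores, index=X.index, columns=[f"C{j + 1}" for j in range(k)]
    )
    if hemisphere_scale_scores:
        scores = scale_by_hemisphere(scores)
    loadings = pd.DataFrame(Lk, index=genes, columns=scores.columns)
    return ComponentModel(
        loadings=loadings,
        scores=scores,
        variance_explained=ve,
        rotation=rotate,
        k=k,
        eigenvalue_shares=eig_shares,
    )


def _fold_loadings(values: np.ndarray, k: int):
    """Unrotated correlation-scale loadings of a region subset (within-fold
    standardization); returns loadings for the first k components and the
    kept-gene mask."""
    Z, keep = _standardize_columns(values)
    n = Z.shape[0]
    _, s, V, _ = _decompose(Z)
    k_eff = min(k, Z.shape[0] - 1, Z.shape[1])
    L = V[:, :k_eff] * (s[:k_eff] / np.sqrt(n - 1))
    return L, keep, k_eff


def partition_stability(
    X: pd.DataFrame,
    n_folds: int = 5,
    n_reps: int = 50,
    k: int = 10,
    seed: int | None = 0,
) -> CongruenceReport:
    """Split-region stability of unrotated components.

    Per repetition the regions are randomly partitioned into ``n_folds``
    near-equal sets; each set in turn is the small set and the union of the
    others the large set.  Components are fit on both (genes standardized
    within fold) and the absolute congruence per component index is recorded,
    giving ``n_folds * n_reps`` train/test evaluations.
    """
    n_regions = X.shape[0]
    if n_regions < n_folds * 2:
        raise InvalidParameterError("need at least 2 regions per fold")
    rng = np.random.default_rng(seed)
    values = X.to_numpy(dtype=float)
    rows = []
    for rep in range(n_reps):
        order = rng.permutation(n_regions)
        folds = np.array_split(order, n_folds)
        for f, fold in enumerate(folds):
            small = np.sort(fold)
            large = np.sort(np.setdiff1d(order, fold))
            if len(small) < k + 1:
                k_fold = min(k, len(small) - 1)
                logger.warning(
                    "fold of %d regions supports only %d components (k=%d)",
                    len(small),
                    k_fold,
                    k,
                )
            La, keep_a, ka = _fold_loadings(values[small], k)
            Lb, keep_b, kb = _fold_loadings(values[large], k)
            both = keep_a & keep_b
            sub_a = La[both[keep_a]]
            sub_b = Lb[both[keep_b]]
            for j in range(min(ka, kb)):
                rows.append(
                    {
                        "rep": rep,
                        "fold": f,
                        "component": j + 1,
                        "abs_phi": abs(congruence(sub_a[:, j], sub_b[:, j])),
                    }
                )
    pairs = pd.DataFrame(rows)
    summary = (
        pairs.groupby("component")["abs_phi"].agg(["mean", "std"]).reset_index()
    )
    return CongruenceReport(pairs=pairs, summary=summary, context="partition-fold")


def _best_assignment(abs_phi: np.ndarray) -> list[tuple[int, int]]:
    """Assignment of rows to columns maximizing total |phi|.

    Exhaustive search for min(dim) <= 6 (ties broken towards lower index
    pairs), greedy otherwise.
    """
    ka, kb = abs_phi.shape
    if min(ka, kb) <= 6:
        best, best_total = None, -np.inf
        if ka <= kb:
            for perm in itertools.permutations(range(kb), ka):
                total = sum(abs_phi[i, perm[i]] for i in range(ka))
                if total > best_total + 1e-15:
                    best_total = total
                    best = [(i, perm[i]) for i in range(ka)]
        else:
            for perm in itertools.permutations(range(ka), kb):
                total = sum(abs_phi[perm[j], j] for j in range(kb))
                if total > best_total + 1e-15:
                    best_total = total
                    best = [(perm[j], j) for j in range(kb)]
        return best
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-abs_phi, axis=None), abs_phi.shape))[0]
    for i, j in order:
        if i not in used_a and j not in used_b:
            pairs.append((int(i), int(j)))
            used_a.add(int(i))
            used_b.add(int(j))
    return sorted(pairs)


def cross_model_congruence(
    a: ComponentModel,
    b: ComponentModel,
    matched_gene_ids=None,
    context: str = "pipeline",
) -> CongruenceReport:
    """Compare two component models on their shared genes.

    Loadings are subset to the matched genes, the full pairwise |phi| matrix
    over components is computed, and a best-match assignment maximizing total
    |phi| is reported (so e.g. a PC2-to-PC3 correspondence is representable).
    """
    if matched_gene_ids is None:
        matched_gene_ids = a.loadings.index.intersection(b.loadings.index)
    matched_gene_ids = pd.Index(matched_gene_ids)
    if len(matched_gene_ids) < 2:
        raise InsufficientOverlapError(
            f"only {len(matched_gene_ids)} matched genes; need >= 2"
        )
    La = a.loadings.loc[matched_gene_ids].to_numpy()
    Lb = b.loadings.loc[matched_gene_ids].to_numpy()
    phi = np.empty((La.shape[1], Lb.shape[1]))
    for i in range(La.shape[1]):
        for j in range(Lb.shape[1]):
            phi[i, j] = congruence(La[:, i], Lb[:, j])
    abs_phi = np.abs(phi)
    assignment = _best_assignment(abs_phi)
    rows = [
        {"comp_a": i + 1, "comp_b": j + 1, "phi": phi[i, j]} for i, j in assignment
    ]
    pairs = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "component": [i + 1 for i, _ in assignment],
            "mean": [abs_phi[i, j] for i, j in assignment],
            "std": [0.0] * len(assignment),
        }
    )
    matrix = pd.DataFrame(
        abs_phi,
        index=[f"A{i + 1}" for i in range(La.shape[1])],
        columns=[f"B{j + 1}" for j in range(Lb.shape[1])],
    )
    return CongruenceReport(
        pairs=pairs,
        summary=summary,
        context=context,
        assignment=[(i + 1, j + 1) for i, j in assignment],
        matrix=matrix,
    )
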