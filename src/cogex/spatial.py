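"""Spatial map-map association tests with spin-permutation null models.

The spin test builds a null that preserves the spatial autocorrelation of a
parcellated cortical map: parcel centroids on the unit sphere are rotated by
a uniformly random 3D rotation (mirrored across the sagittal plane for the
right hemisphere) and a bijective original-to-rotated region assignment is
formed by greedy nearest-centroid matching in random order.  Each resulting
hemisphere-preserving permutation reindexes one map while the other stays
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import (
    AmbiguousAssignmentError,
    DegenerateInputError,
    InvalidParameterError,
)

FORMS = ("linear", "absolute", "quadratic")


@dataclass
class SpatialTestResult:
    """One map-map association with parametric and spin p-values."""

    form: str
    statistic: float  # Pearson r, or the quadratic coefficient
    coefficients: tuple | None  # (beta1, beta2) for the quadratic form
    p_parametric: float
    p_spin: float | None
    n_perm: int
    seed: int | None = None


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _greedy_assignment(
    rotated: np.ndarray, original: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """perm[i] = j: rotated region i takes the value of original region j."""
    d = cdist(rotated, original)
    n = d.shape[0]
    perm = np.full(n, -1, dtype=int)
    available = np.ones(n, dtype=bool)
    for i in rng.permutation(n):
        j = int(np.argmin(np.where(available, d[i], np.inf)))
        perm[i] = j
        available[j] = False
    return perm


def validate_parcellation(parcellation: pd.DataFrame) -> None:
    """Check centroid norms, hemisphere balance and duplicate centroids."""
    required = {"region", "hemisphere", "x", "y", "z"}
    if not required <= set(parcellation.columns):
        raise InvalidParameterError(f"parcellation needs columns {sorted(required)}")
    xyz = parcellation[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(xyz, axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise InvalidParameterError("centroids must be unit-norm")
    counts = parcellation["hemisphere"].value_counts()
    if set(counts.index) != {"lh", "rh"} or counts["lh"] != counts["rh"]:
        raise InvalidParameterError("hemisphere counts must be equal lh/rh")


def spin_permutations(
    parcellation: pd.DataFrame, n_perm: int = 1000, seed: int | None = 0
) -> np.ndarray:
    """Generate ``n_perm`` hemisphere-preserving spin permutations.

    Returns an integer array of shape (n_perm, n_regions); row ``p`` is a
    permutation such that a spun map is ``map[perm[p]]``, in the region order
    of ``parcellation``.
    """
    validate_parcellation(parcellation)
    hemis = parcellation["hemisphere"].to_numpy()
    xyz = parcellation[["x", "y", "z"]].to_numpy(dtype=float)
    idx_l = np.flatnonzero(hemis == "lh")
    idx_r = np.flatnonzero(hemis == "rh")
    if len(idx_l) < 3:
        raise InvalidParameterError("need at least 3 regions per hemisphere")
    for idx in (idx_l, idx_r):
        d = cdist(xyz[idx], xyz[idx])
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise AmbiguousAssignmentError("duplicate centroids within a hemisphere")

    mirror = np.diag([-1.0, 1.0, 1.0])  # sagittal plane: flip the x (L-R) axis
    rng = np.random.default_rng(seed)
    n = len(parcellation)
    perms = np.empty((n_perm, n), dtype=int)
    for p in range(n_perm):
        rot_l = _random_rotation(rng)
        rot_r = mirror @ rot_l @ mirror
        perm = np.arange(n)
        perm[idx_l] = idx_l[_greedy_assignment(xyz[idx_l] @ rot_l.T, xyz[idx_l], rng)]
        perm[idx_r] = idx_r[_greedy_assignment(xyz[idx_r] @ rot_r.T, xyz[idx_r], rng)]
        perms[p] = perm
    return perms


def _statistic(map_a: np.ndarray, map_b: np.ndarray, form: str):
    """(statistic, p_parametric, extra coefficients) for one map pair."""
    if form == "linear":
        r, p = stats.pearsonr(map_a, map_b)
        return float(r), float(p), None
    if form == "absolute":
        r, p = stats.pearsonr(np.abs(map_a), map_b)
        return float(r), float(p), None
    if form == "quadratic":
        X = np.column_stack([np.ones_like(map_a), map_a, map_a**2])
        coef, _, rank, _ = np.linalg.lstsq(X, map_b, rcond=None)
        resid = map_b - X @ coef
        df = len(map_b) - X.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t = coef[2] / np.sqrt(cov[2, 2])
        p = float(2 * stats.t.sf(abs(t), df))
        return float(coef[2]), p, (float(coef[1]), float(coef[2]))
    raise InvalidParameterError(f"unknown form {form!r}; use one of {FORMS}")


def spatial_correlation(
    map_a,
    map_b,
    perms: np.ndarray | None = None,
    form: str = "linear",
    seed: int | None = None,
) -> SpatialTestResult:
    """Association between two aligned regional maps.

    Forms: ``linear`` (Pearson r of A vs B), ``absolute`` (Pearson r of |A|
    vs B), ``quadratic`` (least squares B ~ A + A^2; the quadratic
    coefficient is the statistic).  The spin p-value applies each permutation
    to ``map_a`` only and uses the two-sided +1-corrected estimator
    ``(1 + #{|stat_null| >= |stat_obs|}) / (1 + n_perm)``.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("maps must be aligned 1-D vectors")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise InvalidParameterError("maps must not contain missing values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("zero-variance map")
    stat, p_param, coefs = _statistic(a, b, form)
    p_spin = None
    n_perm = 0
    if perms is not None:
        n_perm = perms.shape[0]
        if form in ("linear", "absolute"):
            src = np.abs(a) if form == "absolute" else a
            A = src[perms]  # n_perm x n; row means/SDs equal the original's
            Ac = A - A.mean(axis=1, keepdims=True)
            bc = b - b.mean()
            null = (Ac @ bc) / np.sqrt((Ac**2).sum(axis=1) * (bc @ bc))
        else:
            null = np.empty(n_perm)
            for i in range(n_perm):
                null[i] = _statistic(a[perms[i]], b, form)[0]
        p_spin = float((1 + np.sum(np.abs(null) >= abs(stat))) / (1 + n_perm))
    return SpatialTestResult(
        form=form,
        statistic=stat,
        coefficients=coefs,
        p_parametric=p_param,
        p_spin=p_spin,
        n_perm=n_perm,
        seed=seed,
    )
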