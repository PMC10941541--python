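"""Regional expression matrices: assembly, donor-consistency QC, hemisphere scaling.

An expression matrix is a :class:`pandas.DataFrame` with regions as rows and
genes as columns.  Region identifiers carry a hemisphere tag as a ``lh_`` or
``rh_`` prefix (e.g. ``lh_region07``); values are log2-intensity-like medians
of donor-level expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, InvalidParameterError, MissingRegionError

logger = logging.getLogger(__name__)

LEFT_PREFIX = "lh_"
RIGHT_PREFIX = "rh_"

#: Between-donor consistency threshold on the mean donor-to-median Spearman
#: correlation of a gene's left-hemisphere regional profile.  Replicated as a
#: published constant (one-sided p < .05 equivalent), not recomputed from n.
DEFAULT_CONSISTENCY_THRESHOLD = 0.446


def hemisphere_of(region_ids) -> np.ndarray:
    """Return an array of ``"lh"``/``"rh"`` tags for region identifiers."""
    out = []
    for rid in region_ids:
        if str(rid).startswith(LEFT_PREFIX):
            out.append("lh")
        elif str(rid).startswith(RIGHT_PREFIX):
            out.append("rh")
        else:
            raise InvalidParameterError(
                f"region id {rid!r} lacks a lh_/rh_ hemisphere prefix"
            )
    return np.asarray(out)


def validate_expression_matrix(matrix: pd.DataFrame) -> None:
    """Check the structural invariants of a region x gene matrix."""
    if matrix.index.has_duplicates:
        raise InvalidParameterError("duplicate region ids")
    if matrix.columns.has_duplicates:
        raise InvalidParameterError("duplicate gene ids")
    hemis = hemisphere_of(matrix.index)
    n_left = int(np.sum(hemis == "lh"))
    n_right = int(np.sum(hemis == "rh"))
    if n_left != n_right:
        raise InvalidParameterError(
            f"unequal hemisphere counts: {n_left} left vs {n_right} right"
        )
    if not np.all(np.isfinite(matrix.to_numpy(dtype=float))):
        raise InvalidParameterError("non-finite expression values")


@dataclass
class DonorProfiles:
    """Per-donor regional expression matrices with a shared gene order.

    Donors may be missing regions (rows); all matrices must share columns.
    """

    donors: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        mats = list(self.donors.values())
        if not mats:
            raise InvalidParameterError("at least one donor required")
        genes = mats[0].columns
        for donor_id, mat in self.donors.items():
            if not mat.columns.equals(genes):
                raise InvalidParameterError(
                    f"donor {donor_id!r} does not share the common gene order"
                )
            if mat.shape[0] < 2:
                raise InvalidParameterError(
                    f"donor {donor_id!r} has fewer than 2 regions"
                )

    @property
    def donor_ids(self):
        return list(self.donors)

    @property
    def gene_ids(self):
        return next(iter(self.donors.values())).columns

    @property
    def region_ids(self):
        seen = {}
        for mat in self.donors.values():
            for rid in mat.index:
                seen.setdefault(rid, None)
        return pd.Index(seen)


def median_across_donors(
    profiles: DonorProfiles, regions=None
) -> pd.DataFrame:
    """Element-wise median over donors, per region and gene.

    Each cell is the median over the donors that cover that region.  With an
    explicit target ``regions`` list, any region covered by no donor raises
    :class:`MissingRegionError` (by default the region universe is the union
    of donor regions).
    """
    regions = pd.Index(regions) if regions is not None else profiles.region_ids
    genes = profiles.gene_ids
    stack = np.full((len(profiles.donors), len(regions), len(genes)), np.nan)
    for d, mat in enumerate(profiles.donors.values()):
        aligned = mat.reindex(regions)
        stack[d] = aligned.to_numpy(dtype=float)
    coverage = np.any(np.isfinite(stack), axis=(0, 2))
    if not coverage.all():
        raise MissingRegionError(regions[~coverage])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    return pd.DataFrame(med, index=regions, columns=genes)


def _spearman_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Spearman correlation of two equally-shaped matrices.

    Ties get average ranks.  Columns with zero rank variance in either input
    yield NaN (handled by the caller).
    """
    ra = rankdata(a, axis=0)
    rb = rankdata(b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=0) / denom
    return rho


def donor_consistency_filter(
    profiles: DonorProfiles,
    median_matrix: pd.DataFrame | None = None,
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
    hemisphere: str = "lh",
) -> tuple[pd.Index, pd.Series]:
    """Retain genes whose regional profiles are consistent across donors.

    For every gene, each donor's regional profile over the designated
    hemisphere is Spearman-correlated with the cross-donor median profile;
    genes whose *mean* correlation across donors strictly exceeds
    ``threshold`` are retained.  Donor-gene profiles with zero rank variance
    contribute a correlation of 0 (with a logged warning).  Regions missing
    within a donor are dropped pairwise from that donor's correlations.

    Returns ``(retained_gene_ids, mean_rho)``.
    """
    if median_matrix is None:
        median_matrix = median_across_donors(profiles)
    hemi_mask = hemisphere_of(median_matrix.index) == hemisphere
    hemi_regions = median_matrix.index[hemi_mask]
    med = median_matrix.loc[hemi_regions]

    rho_sum = np.zeros(len(profiles.gene_ids))
    n_donors = 0
    for donor_id, mat in profiles.donors.items():
        common = mat.index.intersection(hemi_regions)
        if len(common) < 2:
            raise InvalidParameterError(
                f"donor {donor_id!r} has fewer than 2 regions in hemisphere "
                f"{hemisphere!r}"
            )
        a = mat.loc[common].to_numpy(dtype=float)
        b = med.loc[common].to_numpy(dtype=float)
        rho = _spearman_columns(a, b)
        n_const = int(np.isnan(rho).sum())
        if n_const:
            logger.warning(
                "donor %s: %d constant gene profile(s) contribute rho = 0",
                donor_id,
                n_const,
            )
            rho = np.nan_to_num(rho, nan=0.0)
        rho_sum += rho
        n_donors += 1

    mean_rho = pd.Series(rho_sum / n_donors, index=profiles.gene_ids, name="mean_rho")
    retained = mean_rho.index[mean_rho.to_numpy() > threshold]
    return retained, mean_rho


def scale_by_hemisphere(values, region_ids=None):
    """Z-standardize a regional map (or matrix columns) within each hemisphere.

    Within each hemisphere the output has mean 0 and sample SD 1 (n-1
    denominator).  Accepts a Series or DataFrame indexed by tagged region ids,
    or an array plus explicit ``region_ids``.  Idempotent.
    """
    if isinstance(values, (pd.Series, pd.DataFrame)):
        ids = values.index if region_ids is None else region_ids
        arr = values.to_numpy(dtype=float)
    else:
        if region_ids is None:
            raise InvalidParameterError("region_ids required for array input")
        ids = region_ids
        arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    mat = arr[:, None] if squeeze else arr.copy()
    hemis = hemisphere_of(ids)
    out = np.empty_like(mat, dtype=float)
    for tag in ("lh", "rh"):
        mask = hemis == tag
        if mask.sum() < 2:
            raise InvalidParameterError(f"fewer than 2 regions in hemisphere {tag}")
        block = mat[mask]
        sd = block.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError(
                f"zero within-hemisphere variance in hemisphere {tag}"
            )
        out[mask] = (block - block.mean(axis=0)) / sd
    res = out[:, 0] if squeeze else out
    if isinstance(values, pd.Series):
        return pd.Series(res, index=values.index, name=values.name)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(res, index=values.index, columns=values.columns)
    return res


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a region x gene TSV (first column = tagged region ids)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression_matrix(mat)
    return mat


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="region")


def qc_report(mean_rho: pd.Series, retained: pd.Index) -> pd.DataFrame:
    """QC summary table: one row per gene with its mean rho and retention flag."""
    return pd.DataFrame(
        {
            "gene": mean_rho.index,
            "mean_rho": mean_rho.to_numpy(),
            "retained": mean_rho.index.isin(retained),
        }
    )
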