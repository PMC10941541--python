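"""Component-adjusted single-gene and cell-type associations with g maps.

A gene's regional expression profile (hemisphere-scaled) is regressed
against a regional g-association map while controlling for the two major
component score maps, so that only spatial signal beyond the shared
expression dimensions is attributed to the gene.  Selection of candidate
genes requires FDR significance on all three morphometry measures plus spin
significance on all three.  Cell-type analyses apply the same adjusted
regression to mean marker-gene profiles, and loading-distribution tests
compare per-cell-type loading distributions against the unclassified pool
(Kruskal-Wallis with Dunn post-hocs, Holm-adjusted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import scale_by_hemisphere
from .errors import IncompleteInputError, InvalidParameterError
from .meta import bh_fdr

logger = logging.getLogger(__name__)

COLLINEARITY_R = 0.999


@dataclass
class GeneAssociation:
    gene: str
    measure: str
    beta: float
    se: float
    p: float
    fdr_q: float | None = None
    p_spin: float | None = None
    collinear: bool = False


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _adjusted_fit(g_map, profile, score1, score2):
    """OLS of z(g_map) on z(profile) + score maps; returns (beta, se, p)."""
    n = len(g_map)
    X = np.column_stack([np.ones(n), _zscore(profile), score1, score2])
    coef, _, _, _ = np.linalg.lstsq(X, g_map, rcond=None)
    resid = g_map - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    return beta, se, p


def _spin_p(profile, g_resid, Q, perms, beta_obs) -> float:
    """Spin p-value for one gene coefficient, vectorized over permutations.

    By Frisch-Waugh-Lovell the gene coefficient equals the simple-regression
    slope of the component-residualized g map on the component-residualized
    (z-scored) permuted profile, so the whole null sweep is two matmuls.
    """
    Pm = profile[perms].T  # regions x n_perm
    R = Pm - Q @ (Q.T @ Pm)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = (R * g_resid[:, None]).sum(axis=0) / (R**2).sum(axis=0)
    null = null[np.isfinite(null)]
    return float((1 + np.sum(np.abs(null) >= abs(beta_obs))) / (1 + len(null)))


def adjusted_gene_association(
    gene_profile,
    g_map,
    score1_map,
    score2_map,
    perms: np.ndarray | None = None,
    gene: str = "",
    measure: str = "",
) -> GeneAssociation:
    """Association of one hemisphere-scaled gene profile with a g map,
    controlling for the two component score maps.

    The spin p-value permutes the gene profile (covariates fixed) with the
    shared permutation set and uses the +1-corrected two-sided estimator.
    A profile correlating > .999 with either score map is flagged collinear.
    """
    prof = np.asarray(gene_profile, dtype=float)
    g = _zscore(np.asarray(g_map, dtype=float))
    s1 = np.asarray(score1_map, dtype=float)
    s2 = np.asarray(score2_map, dtype=float)
    if not (prof.shape == g.shape == s1.shape == s2.shape):
        raise InvalidParameterError("maps must be aligned 1-D vectors")
    collinear = False
    for s in (s1, s2):
        if abs(np.corrcoef(prof, s)[0, 1]) > COLLINEARITY_R:
            collinear = True
            logger.warning("gene %s: profile nearly collinear with a component "
                           "score map", gene)
    beta, se, p = _adjusted_fit(g, prof, s1, s2)
    p_spin = None
    if perms is not None:
        C = np.column_stack([np.ones_like(g), s1, s2])
        Q, _ = np.linalg.qr(C)
        g_resid = g - Q @ (Q.T @ g)
        p_spin = _spin_p(_zscore(prof), g_resid, Q, perms, beta)
    return GeneAssociation(gene, measure, beta, se, p, p_spin=p_spin,
                           collinear=collinear)


def gene_association_table(
    expression: pd.DataFrame,
    g_maps: dict,
    score1_map,
    score2_map,
    perms: np.ndarray | None = None,
    spin_genes=None,
) -> pd.DataFrame:
    """Adjusted associations for every gene x measure, vectorized.

    ``g_maps`` maps measure name -> regional map aligned with the expression
    matrix rows.  FDR Q is computed within each measure across all genes.
    Spin p-values are computed only for ``spin_genes`` (default: the genes in
    the cross-measure FDR < .05 intersection) because each needs the full
    permutation sweep.
    """
    region_ids = expression.index
    profiles = scale_by_hemisphere(expression).to_numpy()  # regions x genes
    s1 = np.asarray(score1_map, dtype=float)
    s2 = np.asarray(score2_map, dtype=float)
    n, n_genes = profiles.shape
    C = np.column_stack([np.ones(n), s1, s2])
    # Frisch-Waugh-Lovell: residualize everything on the component maps once
    Q, _ = np.linalg.qr(C)
    proj = lambda M: M - Q @ (Q.T @ M)  # noqa: E731
    P = proj(profiles / profiles.std(axis=0, ddof=1))  # z-scored gene columns
    df = n - 4  # intercept + gene + two score maps

    frames = []
    for measure, g_map in g_maps.items():
        g = _zscore(np.asarray(g_map, dtype=float))
        gr = proj(g[:, None])[:, 0]
        pss = (P**2).sum(axis=0)
        beta = (P.T @ gr) / pss
        resid_ss = (gr**2).sum() - beta**2 * pss
        sigma2 = resid_ss / df
        se = np.sqrt(sigma2 / pss)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        frames.append(
            pd.DataFrame(
                {
                    "gene": expression.columns,
                    "measure": measure,
                    "beta": beta,
                    "se": se,
                    "p": pvals,
                    "fdr_q": bh_fdr(pvals),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["p_spin"] = np.nan

    if perms is not None:
        if spin_genes is None:
            sig = {
                m: set(grp.loc[grp["fdr_q"] < 0.05, "gene"])
                for m, grp in table.groupby("measure")
            }
            spin_genes = set.intersection(*sig.values()) if sig else set()
        spin_genes = list(spin_genes)
        if spin_genes:
            gidx = [expression.columns.get_loc(g) for g in spin_genes]
            scaled = scale_by_hemisphere(expression.iloc[:, gidx]).to_numpy()
            scaled = scaled / scaled.std(axis=0, ddof=1)
            for measure, g_map in g_maps.items():
                g = _zscore(np.asarray(g_map, dtype=float))
                gr = proj(g[:, None])[:, 0]
                for gene, j in zip(spin_genes, range(len(gidx))):
                    prof = scaled[:, j]
                    obs = _adjusted_fit(g, prof, s1, s2)[0]
                    p_spin = _spin_p(prof, gr, Q, perms, obs)
                    sel = (table["gene"] == gene) & (table["measure"] == measure)
                    table.loc[sel, "p_spin"] = p_spin
    _ = region_ids
    return table


def select_candidate_genes(
    associations: pd.DataFrame,
    fdr_threshold: float = 0.05,
    spin_threshold: float = 0.05,
    measures=("volume", "surface_area", "thickness"),
) -> tuple[list, dict]:
    """Three-stage candidate selection with an audit trail.

    Stage 1: per-measure FDR Q < threshold sets; stage 2: intersection over
    all measures; stage 3: within the intersection, spin p < threshold on
    every measure.  Returns the selected genes and the stage-by-stage sizes.
    """
    present = set(associations["measure"])
    missing = set(measures) - present
    if missing:
        raise IncompleteInputError(f"missing measures: {sorted(missing)}")
    stage1 = {}
    for m in measures:
        grp = associations[associations["measure"] == m]
        stage1[m] = set(grp.loc[grp["fdr_q"] < fdr_threshold, "gene"])
    inter = set.intersection(*stage1.values())
    selected = []
    for gene in sorted(inter):
        rows = associations[
            (associations["gene"] == gene)
            & (associations["measure"].isin(measures))
        ]
        spins = rows["p_spin"].to_numpy(dtype=float)
        if np.all(np.isfinite(spins)) and np.all(spins < spin_threshold):
            selected.append(gene)
    audit = {
        "per_measure_fdr": {m: len(stage1[m]) for m in measures},
        "intersection": len(inter),
        "selected": len(selected),
    }
    return selected, audit


def celltype_profile_association(
    expression: pd.DataFrame,
    cell_map: pd.Series,
    g_maps: dict,
    score1_map,
    score2_map,
    perms: np.ndarray | None = None,
) -> pd.DataFrame:
    """Adjusted associations of mean cell-type marker profiles with g maps.

    ``cell_map`` maps gene id -> cell-type label; genes absent from it are
    unclassified and not tested.  Cell types with < 2 genes present in the
    matrix are skipped with a warning.  BH-FDR is applied across the full
    cell-type x measure family.
    """
    rows = []
    for cell_type in sorted(cell_map.dropna().unique()):
        genes = cell_map.index[cell_map == cell_type]
        genes = expression.columns.intersection(genes)
        if len(genes) < 2:
            logger.warning("cell type %s has < 2 genes in the matrix; skipped",
                           cell_type)
            continue
        mean_profile = expression.loc[:, genes].mean(axis=1)
        scaled = scale_by_hemisphere(mean_profile).to_numpy()
        for measure, g_map in g_maps.items():
            res = adjusted_gene_association(
                scaled, g_map, score1_map, score2_map, perms=perms,
                gene=str(cell_type), measure=measure,
            )
            rows.append(
                {
                    "cell_type": cell_type,
                    "measure": measure,
                    "n_genes": len(genes),
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p,
                    "p_spin": res.p_spin,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out


def _dunn_vs_reference(groups: dict, reference: str) -> pd.DataFrame:
    """Dunn z tests of each group against the reference group, Holm-adjusted.

    Uses the tie-corrected rank variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    labels, values = [], []
    for name, vals in groups.items():
        labels.extend([name] * len(vals))
        values.extend(vals)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n_total = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n_total - 1))
    var_term = n_total * (n_total + 1) / 12 - tie_term
    mean_ranks = {name: ranks[labels == name].mean() for name in groups}
    sizes = {name: int((labels == name).sum()) for name in groups}
    rows = []
    for name in groups:
        if name == reference:
            continue
        z = (mean_ranks[name] - mean_ranks[reference]) / np.sqrt(
            var_term * (1 / sizes[name] + 1 / sizes[reference])
        )
        rows.append({"group": name, "z": float(z),
                     "p": float(2 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out


def loading_distribution_tests(
    loadings: pd.DataFrame,
    cell_map: pd.Series,
    reference: str = "unclassified",
    kurtosis_convention: str = "pearson",
) -> dict:
    """Per-component comparison of loading distributions across cell types.

    Genes absent from ``cell_map`` form the reference 'unclassified' group.
    Returns, per component: group descriptives (n, mean, SD, skewness g1 and
    kurtosis in the stated convention), the tie-corrected Kruskal-Wallis H
    and p, and Dunn z tests of each cell type against the reference with
    Holm adjustment.  ``kurtosis_convention`` is ``"pearson"`` (raw fourth
    moment, normal = 3) or ``"excess"`` (normal = 0).
    """
    if kurtosis_convention not in ("pearson", "excess"):
        raise InvalidParameterError("kurtosis_convention: 'pearson' or 'excess'")
    labels = pd.Series(
        [cell_map.get(g, reference) for g in loadings.index],
        index=loadings.index,
    ).fillna(reference)
    counts = labels.value_counts()
    keep = counts[counts >= 2].index
    dropped = counts[counts < 2]
    for name, cnt in dropped.items():
        logger.warning("group %s has %d member(s); dropped from test", name, cnt)
    if len(keep) < 2:
        raise InvalidParameterError("need >= 2 groups with >= 2 members")
    results = {}
    fisher = kurtosis_convention == "excess"
    for comp in loadings.columns:
        groups = {
            name: loadings.loc[labels == name, comp].to_numpy()
            for name in keep
        }
        h, p = stats.kruskal(*groups.values())
        desc = pd.DataFrame(
            {
                "group": list(groups),
                "n": [len(v) for v in groups.values()],
                "mean": [v.mean() for v in groups.values()],
                "sd": [v.std(ddof=1) for v in groups.values()],
                "skewness": [stats.skew(v) for v in groups.values()],
                "kurtosis": [stats.kurtosis(v, fisher=fisher)
                             for v in groups.values()],
            }
        )
        dunn = (
            _dunn_vs_reference(groups, reference)
            if reference in groups
            else pd.DataFrame()
        )
        results[comp] = {
            "H": float(h),
            "df": len(groups) - 1,
            "p": float(p),
            "descriptives": desc,
            "dunn": dunn,
            "kurtosis_convention": kurtosis_convention,
        }
    return results


def export_loading_threshold_sets(
    loadings: pd.DataFrame, threshold: float = 0.3
) -> dict:
    """Gene sets above/below +-threshold per component, for external GO tools."""
    sets = {}
    for comp in loadings.columns:
        col = loadings[comp]
        sets[f"{comp}_below_-{threshold}"] = list(col.index[col < -threshold])
        sets[f"{comp}_above_{threshold}"] = list(col.index[col > threshold])
    return sets
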