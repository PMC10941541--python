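"""End-to-end study runner: synthetic study generation and full analysis.

Wires the modules together in the order of the study design: donor QC ->
median expression -> two varimax components -> per-cohort latent g ->
regional morphometry associations -> random-effects meta-analysis ->
spatial component-map tests with spin nulls -> component-adjusted gene and
cell-type mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas, components, genes, latent, meta, morphometry, spatial
from . import synthetic

#: Cohort sizes shaped like the three study cohorts, scaled to keep an
#: end-to-end run fast; the largest cohort dominates the pooled weight.
DEFAULT_COHORT_SIZES = {"cohortA": 8000, "cohortB": 1000, "cohortC": 600}
DEFAULT_COHORT_TESTS = {"cohortA": 8, "cohortB": 7, "cohortC": 10}
DEFAULT_AGE_RANGES = {
    "cohortA": (44.0, 83.0),
    "cohortB": (26.0, 84.0),
    "cohortC": (70.0, 74.0),
}


@dataclass
class StudyData:
    """All synthetic inputs for one simulated study."""

    parcellation: pd.DataFrame
    donor_profiles: atlas.DonorProfiles
    median_expression: pd.DataFrame
    expression_truth: synthetic.ExpressionTruth
    beta_maps_true: pd.DataFrame
    cohorts: dict = field(default_factory=dict)  # name -> phenotype frame
    cohort_truths: dict = field(default_factory=dict)
    cell_map: pd.Series | None = None


@dataclass
class StudyResults:
    """Computed outputs of the full analysis on one study."""

    retained_genes: pd.Index
    component_model: components.ComponentModel
    g_models: dict
    g_scores: dict
    associations: pd.DataFrame  # stacked per-cohort regional betas
    meta_results: pd.DataFrame
    spatial_tests: pd.DataFrame
    gene_table: pd.DataFrame
    selected_genes: list
    selection_audit: dict
    celltype_table: pd.DataFrame


def simulate_study(
    seed: int = 0,
    n_regions: int = 68,
    n_genes: int = 2000,
    n_donors: int = 6,
    cohort_sizes: dict | None = None,
    cohort_tests: dict | None = None,
    expression_params: synthetic.ExpressionParams | None = None,
    n_planted_genes: int = 10,
    planted_effect: float = 0.4,
    background_frac: float = 0.25,
    missing_rate: float = 0.0,
    with_cell_map: bool = True,
) -> StudyData:
    """Generate a full synthetic study with shared ground truth."""
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    parc = synthetic.generate_sphere_parcellation(n_regions // 2, seed=sub())
    params = expression_params or synthetic.ExpressionParams(
        n_planted_genes=n_planted_genes,
        planted_effect=planted_effect,
        background_frac=background_frac,
    )
    profiles, median, truth = synthetic.generate_expression(
        n_regions=n_regions, n_genes=n_genes, n_donors=n_donors,
        params=params, seed=sub(),
    )
    beta_maps = synthetic.make_beta_maps(truth, seed=sub())

    cohort_sizes = cohort_sizes or DEFAULT_COHORT_SIZES
    cohort_tests = cohort_tests or DEFAULT_COHORT_TESTS
    cohorts, truths = {}, {}
    for name, n in cohort_sizes.items():
        cparams = synthetic.CohortParams(
            missing_rate=missing_rate,
            age_range=DEFAULT_AGE_RANGES.get(name, (44.0, 83.0)),
            with_lag=(name == "cohortC"),
        )
        frame, ctruth = synthetic.generate_cohort(
            n, cohort_tests.get(name, 8), beta_maps, params=cparams,
            planted_genes=truth.planted_genes,
            planted_effect=truth.planted_effect, seed=sub(), cohort=name,
        )
        cohorts[name] = frame
        truths[name] = ctruth

    cell_map = (
        synthetic.generate_cell_map(median.columns, seed=sub())
        if with_cell_map
        else None
    )
    return StudyData(
        parcellation=parc,
        donor_profiles=profiles,
        median_expression=median,
        expression_truth=truth,
        beta_maps_true=beta_maps,
        cohorts=cohorts,
        cohort_truths=truths,
        cell_map=cell_map,
    )


def run_study(
    study: StudyData,
    n_perm: int = 1000,
    seed: int = 0,
    k: int = 2,
    qc_threshold: float = atlas.DEFAULT_CONSISTENCY_THRESHOLD,
) -> StudyResults:
    """Run the full analysis pipeline on a (synthetic or real) study."""
    rng = np.random.default_rng(seed)

    # 1. donor-consistency QC on the left hemisphere, applied to both
    retained, _ = atlas.donor_consistency_filter(
        study.donor_profiles, study.median_expression, threshold=qc_threshold
    )
    expr = study.median_expression.loc[:, retained]

    # 2. two varimax components of the region x gene matrix
    model = components.fit_components(expr, k=k, rotate="varimax")

    # 3. per-cohort latent g and regional associations
    g_models, g_scores, assoc_frames = {}, {}, []
    region_ids = study.median_expression.index
    for name, frame in study.cohorts.items():
        test_cols = [c for c in frame.columns if c.startswith("test")]
        adjusted = latent.residualize_tests(
            frame[test_cols], frame["age"], frame["sex"]
        )
        gm = latent.fit_one_factor(adjusted, seed=int(rng.integers(2**31 - 1)))
        scores = latent.factor_scores(gm, adjusted)
        scores = latent.orient_g(scores, adjusted[test_cols[0]])
        g_models[name] = gm
        g_scores[name] = scores
        assoc = morphometry.cohort_regional_betas(
            frame,
            scores,
            region_ids,
            lag_column="lag" if "lag" in frame.columns else None,
            cohort=name,
        )
        assoc_frames.append(assoc)
    associations = pd.concat(assoc_frames, ignore_index=True)

    # 4. random-effects meta-analysis, one cell per region x measure
    meta_results = meta.run_meta_grid(associations)

    # 5. spin permutations shared by all spatial tests
    perms = spatial.spin_permutations(
        study.parcellation, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
    )
    parc_order = pd.Index(study.parcellation["region"])
    meta_maps = {
        measure: grp.set_index("region")["beta"].reindex(parc_order).to_numpy()
        for measure, grp in meta_results.groupby("measure")
    }
    scores_aligned = model.scores.reindex(parc_order)

    rows = []
    for measure, g_map in meta_maps.items():
        for comp in scores_aligned.columns:
            comp_map = scores_aligned[comp].to_numpy()
            for form in ("absolute", "quadratic"):
                res = spatial.spatial_correlation(comp_map, g_map, perms=perms,
                                                  form=form)
                rows.append(
                    {
                        "measure": measure,
                        "component": comp,
                        "form": form,
                        "statistic": res.statistic,
                        "p_parametric": res.p_parametric,
                        "p_spin": res.p_spin,
                        "n_perm": res.n_perm,
                    }
                )
    spatial_tests = pd.DataFrame(rows)

    # 6. component-adjusted gene mapping and candidate selection
    expr_aligned = expr.reindex(parc_order)
    s1 = scores_aligned.iloc[:, 0].to_numpy()
    s2 = scores_aligned.iloc[:, 1].to_numpy()
    gene_table = genes.gene_association_table(
        expr_aligned, meta_maps, s1, s2, perms=perms
    )
    selected, audit = genes.select_candidate_genes(gene_table)

    # 7. cell-type mean-profile associations
    celltype_table = pd.DataFrame()
    if study.cell_map is not None:
        celltype_table = genes.celltype_profile_association(
            expr_aligned, study.cell_map, meta_maps, s1, s2, perms=perms
        )

    return StudyResults(
        retained_genes=retained,
        component_model=model,
        g_models=g_models,
        g_scores=g_scores,
        associations=associations,
        meta_results=meta_results,
        spatial_tests=spatial_tests,
        gene_table=gene_table,
        selected_genes=selected,
        selection_audit=audit,
        celltype_table=celltype_table,
    )
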