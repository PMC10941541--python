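"""Benchmark experiments: recovery, calibration and structural checks.

Each function runs a self-contained simulation experiment at the study's
default conditions and returns summary numbers.  They back both the test
suite and the reproduction script, so the quantities are always recomputed
from scratch.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import atlas, components, genes, latent, meta, pipeline, spatial
from . import synthetic


def _spawn(seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def end_to_end_counts(seed: int = 0, n_genes: int = 2000,
                      n_perm: int = 1000) -> dict:
    """Full study run at the 68-region / 3-measure / 3-cohort shape.

    Returns the structural counts (meta-analyses emitted, partition-
    stability train/test evaluations) plus wall-clock time.
    """
    t0 = time.perf_counter()
    study = pipeline.simulate_study(seed=seed, n_genes=n_genes)
    results = pipeline.run_study(study, n_perm=n_perm, seed=seed + 1)
    stability = components.partition_stability(
        study.median_expression.loc[:, results.retained_genes],
        n_folds=5, n_reps=50, k=10, seed=seed + 2,
    )
    n_evaluations = len(
        stability.pairs[["rep", "fold"]].drop_duplicates()
    )
    elapsed = time.perf_counter() - t0
    model = results.component_model
    return {
        "meta_results_count": len(results.meta_results),
        "stability_evaluations": n_evaluations,
        "runtime_seconds": elapsed,
        "two_component_variance_pct": float(
            model.eigenvalue_shares[:2].sum()
        ),
        "unrotated_pc1_share_pct": float(model.eigenvalue_shares[0]),
        "unrotated_pc2_share_pct": float(model.eigenvalue_shares[1]),
        "rotated_shares_pct": [float(v) for v in model.variance_explained],
        "n_selected_genes": len(results.selected_genes),
        "results": results,
        "study": study,
    }


def component_recovery(seed: int = 0, n_seeds: int = 10,
                       n_genes: int = 1000) -> dict:
    """Recover planted loadings at variance fraction 0.5; min best-match |phi|."""
    mins = []
    for s in _spawn(seed, n_seeds):
        _, median, truth = synthetic.generate_expression(
            n_regions=68, n_genes=n_genes, n_donors=6, seed=s
        )
        model = components.fit_components(median, k=2, rotate="none")
        per_comp = []
        for j in range(2):
            per_comp.append(
                max(
                    abs(components.congruence(
                        model.loadings.iloc[:, j],
                        truth.true_loadings.iloc[:, i],
                    ))
                    for i in range(2)
                )
            )
        mins.append(min(per_comp))
    return {"min_congruence": float(np.min(mins)),
            "mean_congruence": float(np.mean(mins)), "n_seeds": n_seeds}


def cfa_recovery(seed: int = 0, n_seeds: int = 20, n: int = 1000,
                 loading: float = 0.7, n_tests: int = 10) -> dict:
    """One-factor FIML recovery of a planted loading across seeds."""
    means, devs, seed_means = [], [], []
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        g = rng.normal(size=n)
        lam = np.full(n_tests, loading)
        x = lam * g[:, None] + np.sqrt(1 - lam**2) * rng.normal(
            size=(n, n_tests)
        )
        data = pd.DataFrame(x, columns=[f"t{j}" for j in range(n_tests)])
        model = latent.fit_one_factor(data, seed=s)
        est = model.lambda_.to_numpy()
        means.append(est.mean())
        devs.extend(np.abs(est - loading))
        seed_means.append(abs(est.mean() - loading))
    return {
        "mean_loading": float(np.mean(means)),
        "mean_abs_error": float(np.mean(devs)),
        "max_seed_mean_deviation": float(np.max(seed_means)),
        "n_seeds": n_seeds,
    }


def dl_recovery(seed: int = 0, n_reps: int = 1000, k: int = 50,
                mu: float = 0.1, tau: float = 0.05) -> dict:
    """Monte-Carlo bias of the DerSimonian-Laird pooled estimate and tau^2."""
    rng = np.random.default_rng(seed)
    pooled, tau2s = [], []
    for _ in range(n_reps):
        se = rng.uniform(0.02, 0.08, k)
        b = rng.normal(mu, np.sqrt(se**2 + tau**2))
        res = meta.dersimonian_laird(b, se)
        pooled.append(res.beta)
        tau2s.append(res.tau2)
    return {
        "pooled_beta": float(np.mean(pooled)),
        "pooled_bias": float(np.mean(pooled) - mu),
        "tau2": float(np.mean(tau2s)),
        "n_reps": n_reps,
    }


def selection_experiment(seed: int = 0, n_reps: int = 50,
                         n_genes: int = 2000, n_perm: int = 1000) -> dict:
    """Three-stage candidate-gene selection on planted specific effects.

    Per repetition: generate expression with 10 candidate genes (nominal
    effect 0.4) plus the background population, build the true association
    maps, fit components, run the adjusted gene mapping with spin tests, and
    apply the FDR-intersection-spin selection rule.  Reports recall on the
    candidates, the empirical false-discovery fraction among selections
    (selected genes with no planted effect), and the mean candidate
    coefficient.
    """
    recalls, fdrs, cand_betas = [], [], []
    for i, s in enumerate(_spawn(seed, n_reps)):
        params = synthetic.ExpressionParams(n_planted_genes=10,
                                            background_frac=0.25)
        _, median, truth = synthetic.generate_expression(
            n_regions=68, n_genes=n_genes, n_donors=6, params=params, seed=s
        )
        maps = synthetic.make_beta_maps(truth, seed=s + 1)
        model = components.fit_components(median, k=2)
        parc = synthetic.generate_sphere_parcellation(34, seed=s + 2)
        perms = spatial.spin_permutations(parc, n_perm=n_perm, seed=s + 3)
        g_maps = {m: maps[m].to_numpy() for m in maps.columns}
        table = genes.gene_association_table(
            median, g_maps,
            model.scores.iloc[:, 0].to_numpy(),
            model.scores.iloc[:, 1].to_numpy(),
            perms=perms,
        )
        selected, _ = genes.select_candidate_genes(table)
        cand = set(truth.planted_genes)
        bg = set(truth.background_genes)
        sel = set(selected)
        recalls.append(len(sel & cand) / len(cand))
        fdrs.append(0.0 if not sel else len(sel - cand - bg) / len(sel))
        vol = table[(table.measure == "volume") & table.gene.isin(cand)]
        cand_betas.append(vol["beta"].mean())
    return {
        "recall": float(np.mean(recalls)),
        "empirical_fdr": float(np.mean(fdrs)),
        "candidate_mean_beta": float(np.mean(cand_betas)),
        "n_reps": n_reps,
    }


def spin_calibration(seed: int = 0, n_sims: int = 500,
                     n_perm: int = 500) -> dict:
    """Spin-test type-I error for spatially uncorrelated map pairs."""
    parc = synthetic.generate_sphere_parcellation(34, seed=seed)
    perms = spatial.spin_permutations(parc, n_perm=n_perm, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    rej = 0
    for _ in range(n_sims):
        a, b = rng.normal(size=(2, 68))
        res = spatial.spatial_correlation(a, b, perms=perms, form="linear")
        rej += res.p_spin < 0.05
    return {"type1_rate": rej / n_sims, "n_sims": n_sims}


def spin_conservativeness(seed: int = 0, n_sims: int = 300,
                          n_perm: int = 300, length_scale: float = 0.8) -> dict:
    """Spin vs parametric rejection under strong spatial autocorrelation.

    Independent smooth Gaussian random fields over the sphere parcels: the
    parametric Pearson p is anti-conservative; the spin null should reject
    no more often.
    """
    parc = synthetic.generate_sphere_parcellation(34, seed=seed)
    xyz = parc[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    K = np.exp(-((d / length_scale) ** 2))
    w, v = np.linalg.eigh(K)
    S = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    perms = spatial.spin_permutations(parc, n_perm=n_perm, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    rej_spin = rej_param = 0
    for _ in range(n_sims):
        a = S @ rng.normal(size=len(xyz))
        b = S @ rng.normal(size=len(xyz))
        res = spatial.spatial_correlation(a, b, perms=perms, form="linear")
        rej_spin += res.p_spin < 0.05
        rej_param += res.p_parametric < 0.05
    return {
        "spin_rejection_rate": rej_spin / n_sims,
        "parametric_rejection_rate": rej_param / n_sims,
        "n_sims": n_sims,
    }


def consistency_filter_retention(seed: int = 0, n_donors: int = 6,
                                 donor_noise_sd: float = 0.05,
                                 n_genes: int = 1000) -> dict:
    """Share of genes the donor-consistency QC retains at low donor noise."""
    params = synthetic.ExpressionParams(donor_noise_sd=donor_noise_sd)
    profiles, median, _ = synthetic.generate_expression(
        n_regions=68, n_genes=n_genes, n_donors=n_donors, params=params,
        seed=seed,
    )
    retained, _ = atlas.donor_consistency_filter(profiles, median)
    return {"retention_fraction": len(retained) / n_genes, "n_genes": n_genes}
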