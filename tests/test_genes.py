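import numpy as np
import pandas as pd
import pytest

from cogex import atlas, components, genes, spatial, synthetic
from cogex.errors import IncompleteInputError


@pytest.fixture(scope="module")
def planted_setup():
    """Expression with specific genes, fitted components and true maps."""
    params = synthetic.ExpressionParams(
        n_planted_genes=10, background_frac=0.25
    )
    _, median, truth = synthetic.generate_expression(
        n_regions=68, n_genes=1000, n_donors=6, params=params, seed=31
    )
    maps = synthetic.make_beta_maps(truth, seed=32)
    model = components.fit_components(median, k=2)
    parc = synthetic.generate_sphere_parcellation(34, seed=33)
    perms = spatial.spin_permutations(parc, n_perm=300, seed=34)
    return median, truth, maps, model, perms


class TestAdjustedGeneAssociation:
    def test_profile_equal_to_score_map_flagged(self, planted_setup, rng):
        median, truth, maps, model, _ = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        res = genes.adjusted_gene_association(
            s1, maps["volume"].to_numpy(), s1, s2, gene="fake"
        )
        assert res.collinear
        # signal fully absorbed by the covariate: no detectable unique effect
        assert abs(res.beta / res.se) < 0.1
        assert res.p > 0.9

    def test_planted_gene_recovered_near_nominal_effect(self, planted_setup):
        median, truth, maps, model, _ = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        betas = []
        for gene in truth.planted_genes:
            prof = atlas.scale_by_hemisphere(median[gene])
            res = genes.adjusted_gene_association(
                prof.to_numpy(), maps["volume"].to_numpy(), s1, s2, gene=gene
            )
            betas.append(res.beta)
        assert np.mean(betas) == pytest.approx(0.4, abs=0.1)

    def test_affine_rescaling_invariance(self, planted_setup):
        median, truth, maps, model, _ = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        gene = truth.planted_genes[0]
        raw = median[gene]
        a = genes.adjusted_gene_association(
            atlas.scale_by_hemisphere(raw).to_numpy(),
            maps["volume"].to_numpy(), s1, s2,
        )
        b = genes.adjusted_gene_association(
            atlas.scale_by_hemisphere(raw * 3.7 + 11.0).to_numpy(),
            maps["volume"].to_numpy(), s1, s2,
        )
        assert a.beta == pytest.approx(b.beta, abs=1e-10)

    def test_table_matches_single_gene_route(self, planted_setup):
        median, truth, maps, model, perms = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        g_maps = {m: maps[m].to_numpy() for m in maps.columns}
        table = genes.gene_association_table(median, g_maps, s1, s2)
        gene = truth.planted_genes[3]
        single = genes.adjusted_gene_association(
            atlas.scale_by_hemisphere(median[gene]).to_numpy(),
            g_maps["volume"], s1, s2,
        )
        row = table[(table.gene == gene) & (table.measure == "volume")]
        assert row["beta"].iloc[0] == pytest.approx(single.beta, abs=1e-8)
        assert row["se"].iloc[0] == pytest.approx(single.se, abs=1e-8)


class TestSelectCandidateGenes:
    def test_three_stage_selection_recovers_planted(self, planted_setup):
        median, truth, maps, model, perms = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        g_maps = {m: maps[m].to_numpy() for m in maps.columns}
        table = genes.gene_association_table(median, g_maps, s1, s2,
                                             perms=perms)
        selected, audit = genes.select_candidate_genes(table)
        sizes = [
            min(audit["per_measure_fdr"].values()),
            audit["intersection"],
            audit["selected"],
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]  # stages only shrink
        cand = set(truth.planted_genes)
        assert len(set(selected) & cand) / len(cand) >= 0.7
        false = set(selected) - cand - set(truth.background_genes)
        assert len(false) <= 0.1 * max(len(selected), 1)

    def test_empty_input_gives_empty_audit(self, rng):
        rows = []
        for m in ("volume", "surface_area", "thickness"):
            for g in ("g1", "g2"):
                rows.append({"gene": g, "measure": m, "beta": 0.0, "se": 1.0,
                             "p": 0.9, "fdr_q": 0.9, "p_spin": 0.9})
        selected, audit = genes.select_candidate_genes(pd.DataFrame(rows))
        assert selected == []
        assert audit["intersection"] == 0

    def test_missing_measure_rejected(self):
        table = pd.DataFrame(
            {"gene": ["g1"], "measure": ["volume"], "fdr_q": [0.01],
             "p_spin": [0.01]}
        )
        with pytest.raises(IncompleteInputError):
            genes.select_candidate_genes(table)


class TestCellTypes:
    def test_single_gene_cell_set_equals_that_gene(self, planted_setup):
        median, truth, maps, model, _ = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        gene = truth.planted_genes[0]
        cell_map = pd.Series({gene: "planted", f"{gene}_copy": "planted"})
        dup = median.copy()
        dup[f"{gene}_copy"] = dup[gene]
        g_maps = {"volume": maps["volume"].to_numpy()}
        out = genes.celltype_profile_association(dup, cell_map, g_maps, s1, s2)
        single = genes.adjusted_gene_association(
            atlas.scale_by_hemisphere(median[gene]).to_numpy(),
            g_maps["volume"], s1, s2,
        )
        assert out["beta"].iloc[0] == pytest.approx(single.beta, abs=1e-10)

    def test_small_cell_types_skipped(self, planted_setup):
        median, truth, maps, model, _ = planted_setup
        cell_map = pd.Series({median.columns[0]: "lonely"})
        out = genes.celltype_profile_association(
            median, cell_map, {"volume": maps["volume"].to_numpy()},
            model.scores.iloc[:, 0].to_numpy(),
            model.scores.iloc[:, 1].to_numpy(),
        )
        assert len(out) == 0

    def test_null_cell_sets_fdr_controlled(self, planted_setup, rng):
        median, truth, maps, model, _ = planted_setup
        s1 = model.scores.iloc[:, 0].to_numpy()
        s2 = model.scores.iloc[:, 1].to_numpy()
        bulk = [g for g in median.columns
                if g not in truth.planted_genes
                and g not in truth.background_genes]
        g_maps = {m: maps[m].to_numpy() for m in maps.columns}
        flagged = total = 0
        for rep in range(10):
            chosen = rng.choice(bulk, size=9 * 10, replace=False)
            cell_map = pd.Series(
                {g: f"ct{i // 10}" for i, g in enumerate(chosen)}
            )
            out = genes.celltype_profile_association(median, cell_map, g_maps,
                                                     s1, s2)
            flagged += (out["fdr_q"] < 0.05).sum()
            total += len(out)
        assert flagged / total <= 0.05 + 0.05


class TestLoadingDistributions:
    def test_toy_oracle_frozen(self):
        # groups [1,2,3], [4,5,6] vs unclassified [2,3,4,5]; H and Dunn z
        # frozen from direct rank arithmetic (tie-corrected formulas)
        loadings = pd.DataFrame(
            {"C1": [1.0, 2, 3, 4, 5, 6, 2, 3, 4, 5]},
            index=[f"g{i}" for i in range(10)],
        )
        cell_map = pd.Series(
            {"g0": "a", "g1": "a", "g2": "a", "g3": "b", "g4": "b", "g5": "b"}
        )
        out = genes.loading_distribution_tests(loadings, cell_map)
        res = out["C1"]
        assert res["H"] == pytest.approx(5.385093167701867, abs=1e-10)
        assert res["df"] == 2
        dunn = res["dunn"].set_index("group")
        assert dunn.loc["a", "z"] == pytest.approx(-1.2404023733913196,
                                                   abs=1e-10)
        assert dunn.loc["b", "z"] == pytest.approx(1.2404023733913196,
                                                   abs=1e-10)
        assert (dunn["p_holm"] >= dunn["p"] - 1e-12).all()

    def test_disjoint_supports_give_maximal_h(self):
        # two groups with disjoint supports: H equals the value of the rank
        # formula for the fully separated configuration
        vals = [1.0, 2, 3, 10, 11, 12]
        loadings = pd.DataFrame({"C1": vals},
                                index=[f"g{i}" for i in range(6)])
        cell_map = pd.Series({"g0": "lo", "g1": "lo", "g2": "lo"})
        out = genes.loading_distribution_tests(loadings, cell_map,
                                               reference="unclassified")
        n = 6
        r_lo, r_hi = 2.0, 5.0  # mean ranks of the separated groups
        h_max = 12 / (n * (n + 1)) * 3 * ((r_lo - 3.5) ** 2 + (r_hi - 3.5) ** 2)
        assert out["C1"]["H"] == pytest.approx(h_max, abs=1e-10)

    def test_null_groups_uniform_p(self, rng):
        ps = []
        for rep in range(100):
            vals = rng.normal(size=120)
            loadings = pd.DataFrame({"C1": vals},
                                    index=[f"g{i}" for i in range(120)])
            cell_map = pd.Series({f"g{i}": f"ct{i % 3}" for i in range(60)})
            out = genes.loading_distribution_tests(loadings, cell_map)
            ps.append(out["C1"]["p"])
        # p-values roughly uniform: mean near 0.5, ~5% below .05
        assert abs(np.mean(ps) - 0.5) < 0.1
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_kurtosis_conventions(self, rng):
        vals = rng.normal(size=500)
        loadings = pd.DataFrame({"C1": vals},
                                index=[f"g{i}" for i in range(500)])
        cell_map = pd.Series({f"g{i}": "ct1" for i in range(100)})
        pearson = genes.loading_distribution_tests(loadings, cell_map)
        excess = genes.loading_distribution_tests(
            loadings, cell_map, kurtosis_convention="excess"
        )
        kp = pearson["C1"]["descriptives"].set_index("group")
        ke = excess["C1"]["descriptives"].set_index("group")
        assert kp.loc["ct1", "kurtosis"] == pytest.approx(
            ke.loc["ct1", "kurtosis"] + 3, abs=1e-10
        )


def test_threshold_set_export():
    loadings = pd.DataFrame(
        {"C1": [-0.5, -0.1, 0.2, 0.6], "C2": [0.0, 0.4, -0.8, 0.1]},
        index=["g1", "g2", "g3", "g4"],
    )
    sets = genes.export_loading_threshold_sets(loadings, threshold=0.3)
    assert sets["C1_below_-0.3"] == ["g1"]
    assert sets["C1_above_0.3"] == ["g4"]
    assert sets["C2_below_-0.3"] == ["g3"]
    assert sets["C2_above_0.3"] == ["g2"]
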