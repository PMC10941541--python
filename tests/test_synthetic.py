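import numpy as np
import pandas as pd
import pytest

from cogex import atlas, components, synthetic
from cogex.errors import InvalidParameterError


class TestSphereParcellation:
    def test_unit_norm_and_counts(self):
        parc = synthetic.generate_sphere_parcellation(34, seed=1)
        assert len(parc) == 68
        norms = np.linalg.norm(parc[["x", "y", "z"]].to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_deterministic(self):
        a = synthetic.generate_sphere_parcellation(34, seed=1)
        b = synthetic.generate_sphere_parcellation(34, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_mirror_symmetry(self):
        parc = synthetic.generate_sphere_parcellation(3, seed=7)
        left = parc[parc.hemisphere == "lh"][["x", "y", "z"]].to_numpy()
        right = parc[parc.hemisphere == "rh"][["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(left * [-1, 1, 1], right, atol=1e-12)

    def test_too_few_regions(self):
        with pytest.raises(InvalidParameterError):
            synthetic.generate_sphere_parcellation(2, seed=0)


class TestGenerateExpression:
    def test_odd_region_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.generate_expression(n_regions=13)

    def test_zero_donor_noise_gives_identical_donors(self):
        params = synthetic.ExpressionParams(donor_noise_sd=0.0)
        profiles, median, _ = synthetic.generate_expression(
            n_regions=20, n_genes=50, n_donors=3, params=params, seed=2
        )
        mats = list(profiles.donors.values())
        for mat in mats[1:]:
            pd.testing.assert_frame_equal(mats[0], mat)
        pd.testing.assert_frame_equal(median, mats[0])

    def test_median_equals_elementwise_median(self):
        profiles, median, _ = synthetic.generate_expression(
            n_regions=12, n_genes=30, n_donors=5, seed=3
        )
        stack = np.stack([m.to_numpy() for m in profiles.donors.values()])
        np.testing.assert_allclose(median.to_numpy(),
                                   np.median(stack, axis=0))

    def test_bit_identical_for_fixed_seed(self):
        a = synthetic.generate_expression(n_regions=12, n_genes=30, seed=4)
        b = synthetic.generate_expression(n_regions=12, n_genes=30, seed=4)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_truth_invariants(self):
        _, _, truth = synthetic.generate_expression(
            n_regions=68, n_genes=200, n_donors=4, seed=5
        )
        T = truth.true_scores.to_numpy()
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8  # orthogonal columns
        half = 34
        for j in range(2):
            r = np.corrcoef(T[:half, j], T[half:, j])[0, 1]
            assert r > 0.7  # paired hemispheres correlate by construction
            for block in (T[:half, j], T[half:, j]):
                assert abs(block.mean()) < 1e-10
                assert block.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_planted_variance_fraction_controls_eigenvalues(self):
        sums = []
        for seed in range(3):
            _, median, _ = synthetic.generate_expression(
                n_regions=68, n_genes=2000, n_donors=6, seed=seed
            )
            model = components.fit_components(median, k=2, rotate="none")
            sums.append(model.eigenvalue_shares[:2].sum())
        assert np.mean(sums) == pytest.approx(50.0, abs=5.0)

    def test_hemisphere_offset_visible_in_raw_data(self):
        _, median, truth = synthetic.generate_expression(
            n_regions=68, n_genes=500, n_donors=6, seed=6
        )
        hemis = atlas.hemisphere_of(median.index)
        gap = (
            median.loc[hemis == "lh"].mean().mean()
            - median.loc[hemis == "rh"].mean().mean()
        )
        assert gap == pytest.approx(truth.hemisphere_offset, abs=0.02)

    def test_consistency_filter_retains_nearly_all_genes(self):
        params = synthetic.ExpressionParams(donor_noise_sd=0.05)
        profiles, median, _ = synthetic.generate_expression(
            n_regions=68, n_genes=500, n_donors=6, params=params, seed=7
        )
        retained, _ = atlas.donor_consistency_filter(profiles, median)
        assert len(retained) >= 0.99 * 500

    def test_filter_retention_monotone_in_donor_noise(self):
        # more donor noise never increases expected retention (seed grid)
        counts = {sd: 0 for sd in (0.1, 1.0, 4.0)}
        for seed in range(4):
            for sd in counts:
                params = synthetic.ExpressionParams(donor_noise_sd=sd)
                profiles, median, _ = synthetic.generate_expression(
                    n_regions=28, n_genes=120, n_donors=5, params=params,
                    seed=seed,
                )
                retained, _ = atlas.donor_consistency_filter(profiles, median)
                counts[sd] += len(retained)
        assert counts[0.1] >= counts[1.0] >= counts[4.0]

    def test_specific_genes_orthogonal_to_components(self):
        params = synthetic.ExpressionParams(n_planted_genes=5,
                                            background_frac=0.1)
        _, median, truth = synthetic.generate_expression(
            n_regions=68, n_genes=300, n_donors=4, params=params, seed=8
        )
        assert len(truth.planted_genes) == 5
        assert len(truth.background_genes) == 30
        T = truth.true_scores.to_numpy()
        core = truth.specific_core.to_numpy()
        for j in range(2):
            assert abs(np.corrcoef(core, T[:, j])[0, 1]) < 1e-6
        # planted loadings on the shared components are zero
        assert (
            truth.true_loadings.loc[truth.planted_genes].to_numpy() == 0
        ).all()


class TestBetaMaps:
    def test_exact_quadratic_without_genes_or_noise(self):
        _, _, truth = synthetic.generate_expression(
            n_regions=40, n_genes=50, n_donors=2, seed=9
        )
        maps = synthetic.make_beta_maps(truth, map_noise_var=0.0, seed=0)
        T = truth.true_scores.to_numpy()
        X = np.column_stack([np.ones(len(T)), (T**2).sum(axis=1)])
        for m in maps.columns:
            coef, *_ = np.linalg.lstsq(X, maps[m].to_numpy(), rcond=None)
            resid = maps[m].to_numpy() - X @ coef
            np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_beta_scale_mean_and_sd(self):
        _, _, truth = synthetic.generate_expression(
            n_regions=68, n_genes=50, n_donors=2, seed=10
        )
        maps = synthetic.make_beta_maps(truth, seed=1)
        assert maps["volume"].mean() == pytest.approx(0.103, abs=1e-10)
        assert maps["volume"].std(ddof=1) == pytest.approx(0.034, abs=1e-10)
        assert maps["thickness"].mean() == pytest.approx(0.031, abs=1e-10)


class TestGenerateCohort:
    def _maps(self, seed=11):
        _, _, truth = synthetic.generate_expression(
            n_regions=20, n_genes=50, n_donors=2, seed=seed
        )
        return synthetic.make_beta_maps(truth, seed=seed)

    def test_too_few_tests_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.generate_cohort(100, 2, self._maps())

    def test_null_loadings_give_uncorrelated_tests(self):
        params = synthetic.CohortParams(loading=0.0, domain_resid_sd=0.0,
                                        test_age_beta=0.0, test_sex_beta=0.0)
        frame, _ = synthetic.generate_cohort(5000, 6, self._maps(),
                                             params=params, seed=12)
        tests = frame[[c for c in frame.columns if c.startswith("test")]]
        corr = tests.corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_null_beta_map_gives_null_associations(self):
        maps = self._maps() * 0.0
        frame, truth = synthetic.generate_cohort(10000, 4, maps, seed=13)
        g = truth.g_true
        betas = []
        for region in maps.index:
            y = frame[f"volume__{region}"]
            betas.append(np.corrcoef(y, g)[0, 1])
        assert abs(np.mean(betas)) < 0.01

    def test_missingness_rate_honoured(self):
        params = synthetic.CohortParams(missing_rate=0.2)
        frame, _ = synthetic.generate_cohort(4000, 6, self._maps(),
                                             params=params, seed=14)
        tests = frame[[c for c in frame.columns if c.startswith("test")]]
        rate = tests.isna().to_numpy().mean()
        assert rate == pytest.approx(0.2, abs=0.02)

    def test_truth_loadings_in_open_interval(self):
        _, truth = synthetic.generate_cohort(100, 5, self._maps(), seed=15)
        lam = truth.test_loadings.to_numpy()
        assert np.all((lam > 0) & (lam < 1))


def test_cell_map_partition():
    gene_ids = [f"g{i}" for i in range(200)]
    cell_map = synthetic.generate_cell_map(gene_ids, seed=16)
    assert cell_map.index.is_unique
    assert len(cell_map) == 9 * 20
    assert cell_map.value_counts().eq(20).all()


def test_truth_json_roundtrips(tmp_path):
    _, _, truth = synthetic.generate_expression(n_regions=12, n_genes=30,
                                                seed=17)
    path = tmp_path / "truth.json"
    synthetic.write_truth_json(truth, path)
    import json

    payload = json.loads(path.read_text())
    assert payload["hemisphere_offset"] == truth.hemisphere_offset
    assert len(payload["true_scores"]["index"]) == 12
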