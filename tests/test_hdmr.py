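import numpy as np
import pytest

from svmhdmr import (
    ConfigurationError,
    DataError,
    KernelError,
    build_kernel_bank,
    center_kernel_matrix,
    component_grid,
    compute_scsa,
    fit_svr_hdmr,
    influence_patterns,
)

from .conftest import make_table


def _table(values, labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.where(np.arange(values.shape[0]) % 2 == 0, 1, -1)
    return make_table(values, labels)


class TestKernelCentering:
    def test_hand_computed_2x2(self):
        # rows means r=(1.5, 1.5), grand mean g=1.5 for [[2,1],[1,2]]
        k0, r, g = center_kernel_matrix(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(k0, [[0.5, -0.5], [-0.5, 0.5]])
        np.testing.assert_allclose(r, [1.5, 1.5])
        assert g == 1.5

    def test_rank_one_kernel_centers_to_zero(self, rng):
        gvals = np.abs(rng.random(10)) + 0.1
        raw = np.outer(gvals, gvals)
        k0, _, _ = center_kernel_matrix(raw)
        np.testing.assert_allclose(k0, 0.0, atol=1e-12)

    def test_row_means_vanish_identically(self, rng):
        t = _table(rng.standard_normal((500, 2)))
        bank = build_kernel_bank(t)
        for k in bank.kernels:
            assert np.max(np.abs(k.k0.mean(axis=1))) < 1e-12
            assert np.allclose(k.k0, k.k0.T)
            assert k.grand_mean > 0

    def test_out_of_sample_expectation_near_zero(self, rng):
        x = rng.standard_normal(500)
        t = _table(x[:, None])
        bank = build_kernel_bank(t)
        fresh = rng.standard_normal(10_000)
        cross = bank.kernels[0].centered_cross(fresh)
        # average over fresh draws ~ marginal expectation at each sample point
        assert np.max(np.abs(cross.mean(axis=0))) < 0.02

    def test_negative_grand_mean_rejected(self):
        with pytest.raises(KernelError):
            center_kernel_matrix(np.array([[1.0, -3.0], [-3.0, 1.0]]))

    def test_polynomial_family_centers_too(self, rng):
        t = _table(rng.random((60, 2)))
        bank = build_kernel_bank(t, family="polynomial", bandwidth=3)
        for k in bank.kernels:
            assert np.max(np.abs(k.k0.mean(axis=1))) < 1e-10

    def test_unknown_family(self, rng):
        t = _table(rng.standard_normal((10, 2)))
        with pytest.raises(ConfigurationError):
            build_kernel_bank(t, family="wavelet")

    def test_min_samples(self, rng):
        t = make_table(rng.standard_normal((4, 2)), [-1, 1, -1, 1])
        with pytest.raises(DataError):
            build_kernel_bank(t)


class TestSvrHdmrFit:
    def test_constant_scores(self, rng):
        t = _table(rng.standard_normal((50, 3)))
        bank = build_kernel_bank(t)
        model = fit_svr_hdmr(bank, np.full(50, 2.5), epsilon=0.01, r2_floor=0.0)
        assert np.max(np.abs(model.components)) < 1e-6
        assert abs(model.f0 - 2.5) < 0.05

    def test_additive_ground_truth_recovery(self, rng):
        n = 500
        x = rng.standard_normal((n, 2))
        g1 = x[:, 0] ** 2
        g2 = np.tanh(2 * x[:, 1])
        y = g1 + g2 + 0.05 * rng.standard_normal(n)
        t = _table(x)
        model = fit_svr_hdmr(build_kernel_bank(t), y)
        for i, g in enumerate([g1, g2]):
            r2 = np.corrcoef(model.components[:, i], g - g.mean())[0, 1] ** 2
            assert r2 >= 0.9

    def test_fitted_value_identity(self, rng):
        n = 120
        x = rng.standard_normal((n, 3))
        y = x[:, 0] + 0.2 * rng.standard_normal(n)
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
        recon = model.f0 + model.components.sum(axis=1)
        np.testing.assert_allclose(recon, model.fitted, atol=1e-8)

    def test_component_sample_means_are_zero(self, rng):
        n = 200
        x = rng.standard_normal((n, 3))
        y = x[:, 0] ** 2 + x[:, 1]
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
        assert np.max(np.abs(model.components.mean(axis=0))) < 1e-6

    def test_poor_fit_warns(self, rng):
        n = 100
        x = rng.standard_normal((n, 2))
        y = np.sign(np.sin(7 * x[:, 0]) * np.sin(7 * x[:, 1]))  # pure interaction
        with pytest.warns(UserWarning, match="first-order"):
            fit_svr_hdmr(build_kernel_bank(_table(x)), y, cost=0.01)

    def test_evaluator_matches_sample_components(self, rng):
        n = 150
        x = rng.standard_normal((n, 2))
        y = x[:, 0] + x[:, 1] ** 2
        t = _table(x)
        model = fit_svr_hdmr(build_kernel_bank(t), y)
        for i, name in enumerate(model.feature_names):
            at_samples = model.evaluate_component(name, x[:, i])
            np.testing.assert_allclose(at_samples, model.components[:, i], atol=1e-10)


class TestScsa:
    def _fit(self, x, y):
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
        return model, compute_scsa(model, y)

    def test_identities(self, rng):
        n = 300
        x = rng.standard_normal((n, 4))
        y = x[:, 0] + 0.5 * x[:, 1] ** 2 + 0.2 * x[:, 2]
        _, s = self._fit(x, y)
        np.testing.assert_allclose(np.diag(s.sb_matrix), s.sa, atol=1e-10)
        np.testing.assert_allclose(s.sb_matrix.sum(axis=1), s.s_total, atol=1e-10)
        np.testing.assert_allclose(s.s_total - s.sa, s.sb, atol=1e-10)
        np.testing.assert_allclose(s.sb_matrix, s.sb_matrix.T, atol=1e-10)
        assert np.all(s.sa >= 0)

    def test_independent_features_have_small_sb(self, rng):
        n = 1000
        x = rng.standard_normal((n, 3))
        y = x[:, 0] + x[:, 1] ** 2 + np.tanh(x[:, 2])
        _, s = self._fit(x, y)
        assert np.max(np.abs(s.sb)) < 0.05

    def test_bivariate_normal_closed_form(self, rng):
        rho, n = 0.5, 5000
        cov = np.array([[1.0, rho], [rho, 1.0]])
        x = rng.standard_normal((n, 2)) @ np.linalg.cholesky(cov).T
        y = x[:, 0] + x[:, 1]
        _, s = self._fit(x, y)
        assert abs(s.sb_matrix[0, 1] - rho / (2 + 2 * rho)) < 0.03

    def test_closure_tracks_r_squared(self):
        # additive data: whenever the expansion fits well, total indices sum
        # close to 1
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 250
            x = rng.standard_normal((n, 3))
            y = x[:, 0] + 0.7 * x[:, 1] + 0.4 * x[:, 2] + 0.05 * rng.standard_normal(n)
            model, s = self._fit(x, y)
            if model.r_squared >= 0.95:
                assert s.sum_total >= 0.9

    def test_permutation_invariance(self, rng):
        n = 300
        x = rng.standard_normal((n, 3))
        y = x[:, 0] ** 2 + x[:, 1]
        _, s1 = self._fit(x, y)
        perm = rng.permutation(n)
        _, s2 = self._fit(x[perm], y[perm])
        # feature identity preserved; only sample order permuted
        np.testing.assert_allclose(s1.sb_matrix, s2.sb_matrix, atol=1e-10)

    def test_structural_ordering_recovery(self):
        # planted relative variances 0.4, 0.3, 0.2, 0.1 on independent inputs
        weights = np.sqrt([0.4, 0.3, 0.2, 0.1])
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((500, 4))
            y = x @ weights
            model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
            s = compute_scsa(model, y)
            hits += np.array_equal(np.argsort(-s.sa), np.arange(4))
        assert hits >= 95

    def test_zero_variance_guard(self, rng):
        x = rng.standard_normal((50, 2))
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), np.full(50, 1.0),
                             epsilon=0.01, r2_floor=0.0)
        with pytest.raises(DataError):
            compute_scsa(model, np.full(50, 1.0))


class TestInfluencePatterns:
    def test_zero_component_non_monotone(self, rng):
        t = _table(rng.standard_normal((60, 2)))
        model = fit_svr_hdmr(build_kernel_bank(t), np.full(60, 1.0), epsilon=0.01,
                             r2_floor=0.0)
        pats = influence_patterns(model)
        for info in pats.values():
            assert info["trend"] == "non-monotone"
            assert info["rank_correlation"] == 0.0

    def test_linear_component_enhancing(self, rng):
        n = 200
        x = rng.standard_normal((n, 2))
        y = x[:, 0] - 0.8 * x[:, 1]
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
        pats = influence_patterns(model)
        assert pats["x1"]["trend"] == "enhancing"
        assert pats["x1"]["rank_correlation"] > 0.95
        assert pats["x2"]["trend"] == "inhibiting"

    def test_component_grid_export(self, rng):
        n = 100
        x = rng.standard_normal((n, 2))
        y = x[:, 0] + x[:, 1]
        model = fit_svr_hdmr(build_kernel_bank(_table(x)), y)
        grids = component_grid(model, n_points=50)
        assert set(grids) == {"x1", "x2"}
        for g in grids.values():
            assert g.shape == (50, 2)
            assert np.all(np.isfinite(g))
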