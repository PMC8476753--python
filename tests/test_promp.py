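"""ProMP fitting: basis construction, ridge weights, weight distribution,
noise estimation and the marginal trajectory distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tapromp as tp
from tapromp.core import PhaseGrid, StrokeSet
from tapromp.promp import _design


def random_strokeset(rng, n=20, T=50, scale=1.0, grid=None):
    grid = grid or PhaseGrid.uniform(T)
    return StrokeSet(scale * rng.normal(size=(n, grid.T, 6)), "inward", grid)


class TestBasis:
    def test_bandwidth_rule_at_twenty_bases(self, grid):
        basis, _ = tp.make_basis(20, grid)
        np.testing.assert_allclose(basis.bandwidths, 0.2 * (20 - 1) ** -2.0)

    @given(M=st.integers(2, 40), T=st.integers(2, 150))
    @settings(max_examples=40, deadline=None)
    def test_rows_normalized_and_positive(self, M, T):
        _, phi = tp.make_basis(M, PhaseGrid.uniform(T))
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-12)
        # positive wherever representable (distant bumps underflow to 0.0)
        assert np.all(phi >= 0)
        assert np.all(phi.max(axis=1) > 0)

    def test_three_bases_at_quarter_phase(self):
        # independent evaluation of the normalized bumps at z = 0.25:
        # centers (0, 1/2, 1), h = 0.2 * (1/2)^2 = 0.05
        _, phi = tp.make_basis(3, PhaseGrid.uniform(5))
        raw = np.exp(-np.array([0.0625, 0.0625, 0.5625]) / (2 * 0.05))
        np.testing.assert_allclose(phi[1], raw / raw.sum(), atol=1e-14)

    def test_single_basis_rejected(self, grid):
        with pytest.raises(ValueError, match="M >= 2"):
            tp.make_basis(1, grid)


class TestBlockFeature:
    def test_single_channel_is_phi_itself(self, grid):
        _, phi = tp.make_basis(10, grid)
        np.testing.assert_array_equal(tp.build_block_feature(phi, 1), phi)

    def test_shape_and_block_structure(self, grid):
        _, phi = tp.make_basis(20, grid)
        A = tp.build_block_feature(phi, 6)
        assert A.shape == (600, 120)
        assert np.count_nonzero(A) == 6 * np.count_nonzero(phi)

    def test_matches_per_channel_loop(self, grid):
        rng = np.random.default_rng(0)
        _, phi = tp.make_basis(8, grid)
        A = tp.build_block_feature(phi, 6)
        w = rng.normal(size=8 * 6)
        stacked = A @ w
        for d in range(6):
            np.testing.assert_allclose(
                stacked[d * grid.T : (d + 1) * grid.T],
                phi @ w[d * 8 : (d + 1) * 8],
                atol=1e-12,
            )


class TestFitWeights:
    def test_zero_strokes_give_zero_weights(self, grid):
        strokes = StrokeSet(np.zeros((3, grid.T, 6)), "inward", grid)
        _, phi = tp.make_basis(10, grid)
        A = tp.build_block_feature(phi, 6)
        for lam in (1e-6, 1.0):
            np.testing.assert_array_equal(tp.fit_weights(strokes, A, lam), 0.0)

    def test_exact_recovery_of_in_span_targets(self, grid):
        rng = np.random.default_rng(4)
        _, phi = tp.make_basis(12, grid)
        A = tp.build_block_feature(phi, 6)
        w_true = rng.normal(size=(12 * 6, 5))
        tau = A @ w_true
        W = tp.fit_weights(tau, A, lam=1e-12)
        np.testing.assert_allclose(W, w_true, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_augmented_least_squares_oracle(self, seed):
        # ridge == ordinary least squares on the sqrt(lambda)-augmented system
        rng = np.random.default_rng(seed)
        T, M, D, n = rng.integers(5, 20), rng.integers(2, 6), rng.integers(1, 3), 4
        _, phi = tp.make_basis(int(M), PhaseGrid.uniform(int(T)))
        A = tp.build_block_feature(phi, int(D))
        tau = rng.normal(size=(A.shape[0], n))
        lam = 10.0 ** rng.uniform(-8, -1)
        W = tp.fit_weights(tau, A, lam)
        A_aug = np.vstack([A, np.sqrt(lam) * np.eye(A.shape[1])])
        tau_aug = np.vstack([tau, np.zeros((A.shape[1], n))])
        W_oracle = np.linalg.lstsq(A_aug, tau_aug, rcond=None)[0]
        np.testing.assert_allclose(W, W_oracle, atol=1e-8)

    def test_rank_deficient_without_ridge_rejected(self):
        _, phi = tp.make_basis(5, PhaseGrid.uniform(3))  # 3 rows, 5 columns
        tau = np.zeros((3, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            tp.fit_weights(tau, phi, lam=0.0)


class TestWeightDistribution:
    def test_identical_demonstrations_give_pure_jitter(self):
        W = np.tile(np.arange(6.0)[:, None], (1, 5))
        mu, Sigma = tp.fit_weight_distribution(W, jitter=1e-4)
        np.testing.assert_array_equal(mu, np.arange(6.0))
        np.testing.assert_array_equal(Sigma, 1e-4 * np.eye(6))

    def test_mean_is_column_average(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(10, 7))
        mu, _ = tp.fit_weight_distribution(W)
        np.testing.assert_allclose(mu, W.mean(axis=1), atol=1e-14)

    def test_single_demonstration_rejected(self):
        with pytest.raises(ValueError, match="two demonstrations"):
            tp.fit_weight_distribution(np.zeros((4, 1)))

    def test_recovers_known_weight_gaussian(self):
        rng = np.random.default_rng(7)
        dim, n = 8, 500
        mu_true = rng.normal(size=dim)
        diag_true = rng.uniform(0.5, 2.0, size=dim)
        W = mu_true[:, None] + np.sqrt(diag_true)[:, None] * rng.normal(size=(dim, n))
        mu, Sigma = tp.fit_weight_distribution(W)
        se = np.sqrt(diag_true / n)
        # 4 standard errors per coordinate keeps the joint false-alarm rate low
        assert np.all(np.abs(mu - mu_true) < 4 * se)
        np.testing.assert_allclose(np.diag(Sigma), diag_true, rtol=0.2)


class TestEstimateNoise:
    def test_in_span_data_has_negligible_noise(self, grid):
        rng = np.random.default_rng(1)
        _, phi, A = _design(grid, 10, 6)
        W = rng.normal(size=(60, 5))
        sigma = tp.estimate_noise(A @ W, W, A)
        assert np.all(sigma <= 1e-6)

    def test_recovers_additive_noise_level(self, grid):
        rng = np.random.default_rng(3)
        _, phi, A = _design(grid, 10, 6)
        W = rng.normal(size=(60, 200))
        tau = A @ W + rng.normal(0.0, 0.1, size=(600, 200))
        W_fit = tp.fit_weights(tau, A, 1e-6)
        sigma = tp.estimate_noise(tau, W_fit, A)
        np.testing.assert_allclose(sigma, 0.1, rtol=0.1)

    def test_floor_applies_to_zero_residual(self, grid):
        _, phi, A = _design(grid, 5, 6)
        W = np.zeros((30, 3))
        sigma = tp.estimate_noise(np.zeros((600, 3)), W, A, eps=1e-8)
        np.testing.assert_array_equal(sigma, 1e-8)


class TestMarginal:
    def test_degenerate_covariance_reduces_to_basis_mean(self, grid):
        basis, phi, _ = _design(grid, 10, 6)
        mu = np.random.default_rng(0).normal(size=60)
        model = tp.ProMPModel(
            basis, grid, phi, mu, np.zeros((60, 60)), np.full(6, 1e-5), 1e-6, 2
        )
        dist = tp.marginal_distribution(model, std_floor=1e-9)
        np.testing.assert_allclose(dist.std, 1e-5, atol=1e-12)
        for d in range(6):
            np.testing.assert_allclose(
                dist.mean[:, d], phi @ mu[d * 10 : (d + 1) * 10], atol=1e-12
            )

    def test_non_psd_covariance_rejected(self, grid):
        basis, phi, _ = _design(grid, 5, 6)
        model = tp.ProMPModel(
            basis, grid, phi, np.zeros(30), -np.eye(30), np.full(6, 0.1), 1e-6, 2
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            tp.marginal_distribution(model)

    def test_variance_at_least_observation_noise(self, grid):
        rng = np.random.default_rng(5)
        strokes = random_strokeset(rng, n=10, grid=grid)
        model = tp.ProMPModel.fit(strokes, M=10)
        dist = model.marginal()
        assert np.all(dist.std >= model.noise_std[None, :] - 1e-12)

    def test_monte_carlo_sampling_oracle(self, grid):
        # empirical std of sampled trajectories matches the analytic marginal
        rng = np.random.default_rng(9)
        basis, phi, A = _design(grid, 8, 6)
        mu = rng.normal(size=48)
        L = rng.normal(size=(48, 48)) / np.sqrt(48)
        Sigma = L @ L.T + 0.1 * np.eye(48)
        sigma_y = np.full(6, 0.2)
        model = tp.ProMPModel(basis, grid, phi, mu, Sigma, sigma_y, 1e-6, 2)
        dist = model.marginal()
        W = mu[:, None] + np.linalg.cholesky(Sigma) @ rng.normal(size=(48, 10_000))
        tau = A @ W + rng.normal(0.0, 0.2, size=(600, 10_000))
        emp_std = tau.std(axis=1, ddof=1).reshape(6, grid.T).T
        np.testing.assert_allclose(emp_std, dist.std, rtol=0.03)

    def test_refit_on_own_samples_is_self_consistent(self, grid):
        rng = np.random.default_rng(11)
        basis, phi, A = _design(grid, 10, 6)
        mu = rng.normal(size=60)
        L = rng.normal(size=(60, 60)) * 0.2
        Sigma = L @ L.T / 60 + 0.02 * np.eye(60)
        model = tp.ProMPModel(basis, grid, phi, mu, Sigma, np.full(6, 0.05), 1e-6, 2)
        n = 200
        W = mu[:, None] + np.linalg.cholesky(Sigma) @ rng.normal(size=(60, n))
        tau = A @ W + rng.normal(0.0, 0.05, size=(600, n))
        data = tau.T.reshape(n, 6, grid.T).transpose(0, 2, 1)
        refit = tp.ProMPModel.fit(StrokeSet(data, "inward", grid), M=10)
        d = tp.trajectory_kls(model.marginal(), refit.marginal()).value
        assert d < 0.1


class TestEmpirical:
    def test_duplicate_strokes_hit_the_std_floor(self, grid):
        data = np.tile(np.random.default_rng(0).normal(size=(1, grid.T, 6)), (2, 1, 1))
        dist = tp.empirical_distribution(StrokeSet(data, "inward", grid))
        np.testing.assert_array_equal(dist.std, 1e-8)

    def test_mean_matches_loop_oracle(self, grid):
        rng = np.random.default_rng(6)
        strokes = random_strokeset(rng, n=7, grid=grid)
        dist = tp.empirical_distribution(strokes)
        for t in (0, grid.T // 2, grid.T - 1):
            for d in range(6):
                expected = sum(strokes.data[j, t, d] for j in range(7)) / 7
                assert abs(dist.mean[t, d] - expected) < 1e-12

    def test_large_sample_std_recovery(self, grid):
        rng = np.random.default_rng(8)
        true_std = 0.7
        strokes = random_strokeset(rng, n=4000, scale=true_std, grid=grid)
        dist = tp.empirical_distribution(strokes)
        np.testing.assert_allclose(dist.std, true_std, rtol=0.05)


def test_model_roundtrip_through_serialization(tmp_path, grid, fast_config):
    rng = np.random.default_rng(2)
    strokes = tp.sample_strokeset(fast_config(), 20, "inward", grid, rng)
    model = tp.ProMPModel.fit(strokes)
    from tapromp.io import load_model, save_model

    save_model(model, tmp_path / "m")
    loaded = load_model(tmp_path / "m")
    np.testing.assert_allclose(loaded.weight_mean, model.weight_mean, atol=1e-12)
    d = tp.trajectory_kls(model.marginal(), loaded.marginal()).value
    assert d < 1e-10
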