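"""Moment propagation: linearization vs sigma points vs Monte Carlo."""

import numpy as np
import pytest

import roed.propagation as prop
from roed.distributions import ParameterDistribution
from roed.propagation import (ResponseTransform, propagate_linearized,
                              propagate_monte_carlo, propagate_sigma_points)

from conftest import make_static_map


@pytest.fixture
def gauss3():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((3, 3)) * 0.3
    cov = a @ a.T + 0.05 * np.eye(3)
    return ParameterDistribution(mean=[0.5, -0.2, 1.0], cov=cov, scale="linear")


class TestLinearExactness:
    def test_linearization_exact_on_linear_map(self, linear_static, gauss3,
                                               static_grid, null_stimulus):
        model, a_mat, b_vec = linear_static
        mt = propagate_linearized(model, gauss3, null_stimulus, static_grid)
        assert np.allclose(mt.means[0], a_mat @ gauss3.mean + b_vec, atol=1e-9)
        assert np.allclose(mt.covs[0], a_mat @ gauss3.cov @ a_mat.T, atol=1e-9)

    def test_sigma_points_match_linearization_on_linear_map(
            self, linear_static, gauss3, static_grid, null_stimulus):
        model, _, _ = linear_static
        lin = propagate_linearized(model, gauss3, null_stimulus, static_grid)
        ut = propagate_sigma_points(model, gauss3, null_stimulus, static_grid)
        assert np.allclose(ut.means, lin.means, atol=1e-8)
        assert np.allclose(ut.covs, lin.covs, atol=1e-8)

    def test_monte_carlo_matches_closed_form_on_linear_map(
            self, linear_static, static_grid, null_stimulus):
        model, a_mat, b_vec = linear_static
        dist = ParameterDistribution(mean=[0.5, -0.2, 1.0],
                                     cov=0.04 * np.eye(3), scale="linear")
        n = 20_000
        mc = propagate_monte_carlo(model, dist, null_stimulus, static_grid,
                                   n_samples=n, seed=3)
        true_mean = a_mat @ dist.mean + b_vec
        true_cov = a_mat @ dist.cov @ a_mat.T
        se_mean = np.sqrt(np.diag(true_cov) / n)
        assert np.all(np.abs(mc.means[0] - true_mean) < 5 * se_mean)
        se_var = np.sqrt(2.0 / (n - 1)) * np.diag(true_cov)
        assert np.all(np.abs(np.diag(mc.covs[0]) - np.diag(true_cov)) < 5 * se_var)


class TestQuadraticPathology:
    """y = theta^2: linearization is blind at the zero-gradient point."""

    def test_linearization_zero_variance_at_zero_gradient(
            self, quadratic_static, static_grid, null_stimulus):
        dist = ParameterDistribution(mean=[0.0], cov=[[1.0]], scale="linear")
        lin = propagate_linearized(quadratic_static, dist, null_stimulus,
                                   static_grid)
        assert lin.means[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert lin.covs[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_sigma_points_recover_chi_square_moments(
            self, quadratic_static, static_grid, null_stimulus):
        # chi^2_1 has mean 1 and variance 2; classic UT (n + lambda = 3,
        # beta = 0) reproduces both exactly
        dist = ParameterDistribution(mean=[0.0], cov=[[1.0]], scale="linear")
        ut = propagate_sigma_points(quadratic_static, dist, null_stimulus,
                                    static_grid, alpha=1.0, beta=0.0, kappa=2.0)
        assert ut.means[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert ut.covs[0, 0, 0] == pytest.approx(2.0, abs=1e-10)

    def test_linearization_first_order_moments_away_from_origin(
            self, quadratic_static, static_grid, null_stimulus):
        # theta ~ N(1, 0.01): truth mean 1.01, var 0.0402; linearization
        # gives mean 1, var 0.04
        dist = ParameterDistribution(mean=[1.0], cov=[[0.01]], scale="linear")
        lin = propagate_linearized(quadratic_static, dist, null_stimulus,
                                   static_grid)
        assert lin.means[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert lin.covs[0, 0, 0] == pytest.approx(0.04, rel=1e-6)

    def test_ut_beats_linearization_on_quartic(self, static_grid, null_stimulus):
        # y = theta^4, theta ~ N(0,1): E[y] = 3; linearization predicts 0
        model = make_static_map(lambda th: [th[0] ** 4], 1, 1)
        dist = ParameterDistribution(mean=[0.0], cov=[[1.0]], scale="linear")
        lin = propagate_linearized(model, dist, null_stimulus, static_grid)
        ut = propagate_sigma_points(model, dist, null_stimulus, static_grid,
                                    alpha=1.0, beta=0.0, kappa=2.0)
        lin_err = abs(lin.means[0, 0] - 3.0)
        ut_err = abs(ut.means[0, 0] - 3.0)
        assert np.isfinite(ut_err)
        assert ut_err < lin_err


class TestMonteCarloContract:
    def test_point_mass_gives_noise_only_covariance(
            self, linear_static, static_grid, null_stimulus):
        model, a_mat, b_vec = linear_static
        dist = ParameterDistribution(mean=[0.5, -0.2, 1.0],
                                     cov=np.zeros((3, 3)), scale="linear")
        tr = ResponseTransform("identity", noise_sd=0.3)
        mc = propagate_monte_carlo(model, dist, null_stimulus, static_grid,
                                   tr, n_samples=200, seed=0)
        assert np.allclose(mc.means[0], a_mat @ dist.mean + b_vec)
        assert np.allclose(mc.covs[0], 0.09 * np.eye(2), atol=1e-12)

    def test_seed_reproducibility(self, linear_static, static_grid,
                                  null_stimulus):
        model, _, _ = linear_static
        dist = ParameterDistribution(mean=[0.5, -0.2, 1.0],
                                     cov=0.04 * np.eye(3), scale="linear")
        a = propagate_monte_carlo(model, dist, null_stimulus, static_grid,
                                  n_samples=500, seed=11)
        b = propagate_monte_carlo(model, dist, null_stimulus, static_grid,
                                  n_samples=500, seed=11)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covs, b.covs)


def test_solver_call_counts(monkeypatch, exp_decay, null_stimulus):
    """Cost contract: 1 augmented solve (lin), 2n+1 (UT), n_samples (MC)."""
    grid = np.array([0.5, 1.0])
    dist = ParameterDistribution(mean=[0.5], cov=[[0.01]], scale="linear")
    calls = {"sim": 0, "aug": 0}
    real_sim, real_aug = prop.simulate, prop.simulate_with_sensitivities

    def count_sim(*a, **k):
        calls["sim"] += 1
        return real_sim(*a, **k)

    def count_aug(*a, **k):
        calls["aug"] += 1
        return real_aug(*a, **k)

    monkeypatch.setattr(prop, "simulate", count_sim)
    monkeypatch.setattr(prop, "simulate_with_sensitivities", count_aug)

    propagate_linearized(exp_decay, dist, null_stimulus, grid)
    assert calls == {"sim": 0, "aug": 1}
    calls.update(sim=0, aug=0)
    propagate_sigma_points(exp_decay, dist, null_stimulus, grid)
    assert calls == {"sim": 3, "aug": 0}
    calls.update(sim=0, aug=0)
    propagate_monte_carlo(exp_decay, dist, null_stimulus, grid,
                          n_samples=17, seed=0)
    assert calls == {"sim": 17, "aug": 0}


def test_log_transform_chain_rule(exp_decay):
    """Log-transformed linearization scales sensitivities by 1/y."""
    from roed.stimulus import constant_stimulus

    stim = constant_stimulus(0.0, 2.0)
    grid = np.array([1.0, 2.0])
    dist = ParameterDistribution(mean=[0.5], cov=[[0.01]], scale="linear")
    lin_log = propagate_linearized(exp_decay, dist, stim, grid,
                                   ResponseTransform("log"))
    # y = exp(-theta t) so log y = -theta t: exactly linear in theta,
    # d log y / d theta = -t
    assert np.allclose(lin_log.means[:, 0], -0.5 * grid, atol=1e-8)
    assert np.allclose(lin_log.covs[:, 0, 0], 0.01 * grid**2, rtol=1e-6)


def test_covariances_always_symmetric_psd(linear_static, gauss3, static_grid,
                                          null_stimulus):
    model, _, _ = linear_static
    for fn in (propagate_linearized, propagate_sigma_points):
        mt = fn(model, gauss3, null_stimulus, static_grid)
        for c in mt.covs:
            assert np.allclose(c, c.T)
            assert np.linalg.eigvalsh(c).min() >= -1e-10
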