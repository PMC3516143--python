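"""Stimulus parameterization and hybrid design optimization."""

import numpy as np
import pytest

from roed.design import DesignProblem, objective, optimize_design
from roed.distributions import ParameterDistribution
from roed.propagation import ResponseTransform
from roed.stimulus import (DesignSpace, StimulusDesign, apply_dwell_constraint,
                           constant_stimulus, decode_design, encode_design)


class TestEncoding:
    def test_mapk_design_space_vector_length(self):
        space = DesignSpace(u_max=2.5, horizon=100.0, n_segments=20)
        assert space.n_design_vars == 39  # 20 amplitudes + 19 durations

    def test_round_trip_in_bounds(self):
        space = DesignSpace(u_max=2.0, horizon=10.0, n_segments=3)
        v = np.array([0.5, 1.5, 0.2, 3.0, 4.0])
        design, clip = decode_design(v, space)
        assert clip.total == 0.0
        assert np.allclose(encode_design(design), v)

    def test_out_of_bounds_clipped_with_distance(self):
        space = DesignSpace(u_max=1.0, horizon=10.0, n_segments=2)
        design, clip = decode_design(np.array([2.0, -0.5, 3.0]), space)
        assert np.allclose(design.amplitudes, [1.0, 0.0])
        assert clip.amplitude_clip == pytest.approx(np.hypot(1.0, 0.5))

    def test_zero_amplitudes_null_stimulus(self):
        design = StimulusDesign(np.zeros(4), np.ones(3), 10.0)
        assert np.all(np.asarray(design.value_at(np.linspace(0, 10, 20))) == 0)

    def test_wrong_length_rejected(self):
        space = DesignSpace(u_max=1.0, horizon=10.0, n_segments=2)
        with pytest.raises(ValueError, match="length"):
            decode_design(np.zeros(4), space)

    def test_final_amplitude_extends_to_horizon(self):
        design = StimulusDesign(np.array([1.0, 2.0]), np.array([3.0]), 10.0)
        assert design.value_at(9.9) == 2.0
        assert design.value_at(2.9) == 1.0
        assert design.value_at(3.0) == 2.0  # right-continuous


class TestDwellConstraint:
    def test_zero_tau_unchanged(self):
        space = DesignSpace(u_max=1.0, horizon=10.0, n_segments=4, dt_min=0.5)
        assert apply_dwell_constraint(space, 0.0) == space

    def test_infeasible_tau_rejected(self):
        space = DesignSpace(u_max=1.0, horizon=10.0, n_segments=6)
        with pytest.raises(ValueError, match="infeasible"):
            apply_dwell_constraint(space, 2.4)  # 5 * 2.4 = 12 > 10

    def test_violating_durations_penalized(self, toy_pair):
        problem = _toy_problem(toy_pair, dt_min=1.0)
        v = np.array([0.5, 0.5, 0.2])  # duration below dwell minimum
        design, clip = decode_design(v, problem.design_space)
        assert clip.duration_clip > 0
        assert problem.penalty(design, clip) > 0


def _toy_problem(toy_pair, estimator="linearization", dt_min=0.0, u_max=1.0):
    model_a, model_b = toy_pair
    dist = ParameterDistribution(mean=[1.0], cov=[[0.0]], scale="linear")
    space = DesignSpace(u_max=u_max, horizon=2.0, n_segments=2, dt_min=dt_min)
    return DesignProblem(
        model_a=model_a, model_b=model_b, dist_a=dist, dist_b=dist,
        design_space=space, measurement_times=np.linspace(0.25, 2.0, 8),
        transform=ResponseTransform("identity", noise_sd=0.05),
        estimator=estimator, rtol=1e-8, atol=1e-10,
    )


class TestObjective:
    def test_identical_models_give_self_overlap(self, toy_pair):
        model_a, _ = toy_pair
        dist = ParameterDistribution(mean=[1.0], cov=[[0.01]], scale="linear")
        space = DesignSpace(u_max=1.0, horizon=2.0, n_segments=2)
        problem = DesignProblem(
            model_a=model_a, model_b=model_a, dist_a=dist, dist_b=dist,
            design_space=space, measurement_times=np.linspace(0.25, 2.0, 8),
            transform=ResponseTransform("identity", noise_sd=0.05),
            estimator="linearization",
        )
        design = constant_stimulus(0.7, 2.0)
        res = problem.overlap(StimulusDesign(np.array([0.7, 0.7]),
                                             np.array([1.0]), 2.0))
        # self-overlap equals the kernel of a distribution with itself
        from roed.overlap import gaussian_product_kernel

        ma, _ = problem.moments(StimulusDesign(np.array([0.7, 0.7]),
                                               np.array([1.0]), 2.0))
        expected = np.mean([gaussian_product_kernel(ma.means[k], ma.covs[k],
                                                    ma.means[k], ma.covs[k])
                            for k in range(len(ma.time_grid))])
        assert res.mean_overlap == pytest.approx(expected, rel=1e-12)

    def test_horizon_overshoot_penalty_formula(self, toy_pair):
        problem = _toy_problem(toy_pair)
        # durations sum to 1.5 * T -> penalty c * (0.5 T)^2
        design = StimulusDesign(np.array([0.5, 0.5]), np.array([3.0]), 2.0)
        assert problem.penalty(design) == pytest.approx(
            problem.penalty_weight * 1.0**2)

    def test_brute_force_grid_oracle(self, toy_pair):
        """u vs u^2 differ most at u = 0.5 and coincide at u in {0, 1}."""
        problem = _toy_problem(toy_pair)
        grid_vals = {}
        for a1 in (0.0, 0.5, 1.0):
            for a2 in (0.0, 0.5, 1.0):
                grid_vals[(a1, a2)] = objective(
                    problem, np.array([a1, a2, 1.0]))
        best_cell = min(grid_vals, key=grid_vals.get)
        assert best_cell == (0.5, 0.5)
        res = optimize_design(problem, seed=0, n_restarts=2, budget=120)
        # the continuous optimizer must do at least as well as the grid
        assert res.best_objective <= grid_vals[best_cell] + 1e-6
        assert np.all(np.abs(res.best_design.amplitudes - 0.5) < 0.2)


class TestOptimizer:
    def test_seed_determinism(self, toy_pair):
        problem = _toy_problem(toy_pair)
        a = optimize_design(problem, seed=5, n_restarts=2, budget=60)
        b = optimize_design(problem, seed=5, n_restarts=2, budget=60)
        assert a.best_objective == b.best_objective
        assert np.array_equal(a.best_design.amplitudes,
                              b.best_design.amplitudes)
        assert np.array_equal(a.history, b.history)

    def test_history_non_increasing(self, toy_pair):
        problem = _toy_problem(toy_pair)
        res = optimize_design(problem, seed=3, n_restarts=2, budget=60)
        assert np.all(np.diff(res.history) <= 0)

    def test_best_objective_matches_reevaluation(self, toy_pair):
        problem = _toy_problem(toy_pair)
        res = optimize_design(problem, seed=1, n_restarts=1, budget=60)
        assert objective(problem, res.best_design) == \
            pytest.approx(res.best_objective, abs=1e-10)

    def test_larger_budget_never_worse(self, toy_pair):
        problem = _toy_problem(toy_pair)
        small = optimize_design(problem, seed=7, n_restarts=1, budget=60,
                                polish=False)
        large = optimize_design(problem, seed=7, n_restarts=1, budget=120,
                                polish=False)
        assert large.best_objective <= small.best_objective + 1e-12


def test_linear_pair_estimators_agree(static_grid, null_stimulus):
    """On a fully linear model pair the UT and linearized objectives match."""
    from conftest import make_static_map

    a_mat = np.array([[1.0, 0.5]])
    b_mat = np.array([[0.8, -0.4]])
    model_a = make_static_map(lambda th: a_mat @ th, 2, 1)
    model_b = make_static_map(lambda th: b_mat @ th, 2, 1)
    dist = ParameterDistribution(mean=[1.0, 2.0], cov=0.02 * np.eye(2),
                                 scale="linear")
    space = DesignSpace(u_max=1.0, horizon=1.0, n_segments=1)
    kwargs = dict(model_a=model_a, model_b=model_b, dist_a=dist, dist_b=dist,
                  design_space=space, measurement_times=static_grid,
                  transform=ResponseTransform("identity", noise_sd=0.1))
    p_lin = DesignProblem(estimator="linearization", **kwargs)
    p_ut = DesignProblem(estimator="sigma-point", **kwargs)
    design = constant_stimulus(0.5, 1.0)
    assert p_lin.overlap(design).mean_overlap == \
        pytest.approx(p_ut.overlap(design).mean_overlap, abs=1e-8)
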