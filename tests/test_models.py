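"""ODE simulation and forward-sensitivity correctness."""

import numpy as np
import pytest

from roed.benchmarks.mapk import NOMINAL as MAPK_NOMINAL
from roed.benchmarks.schlogl import NOMINAL as SCHLOGL_NOMINAL
from roed.models import (OdeModel, SolverFailure, simulate,
                         simulate_with_sensitivities)
from roed.models import get_model
from roed.stimulus import StimulusDesign, constant_stimulus


def test_zero_dynamics_states_constant(null_stimulus):
    model = OdeModel(
        name="frozen", n_states=2, n_params=1, n_readouts=2,
        rhs=lambda x, u, th, t: np.zeros(2),
        readout=lambda x, th, t: x,
        init=lambda th: np.array([1.0, 2.0]),
    )
    traj = simulate(model, [0.3], null_stimulus, np.linspace(0.0, 1.0, 5))
    assert np.allclose(traj.states, [1.0, 2.0])
    assert np.allclose(traj.readouts, [1.0, 2.0])


def test_exponential_decay_closed_form(exp_decay, null_stimulus):
    stim = constant_stimulus(0.0, 2.0)
    traj = simulate(exp_decay, [0.5], stim, np.array([2.0]))
    assert traj.states[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-6)


def test_logistic_reaches_stable_fixed_point():
    model = OdeModel(
        name="logistic", n_states=1, n_params=1, n_readouts=1,
        rhs=lambda x, u, th, t: np.array([x[0] * (1 - x[0])]),
        readout=lambda x, th, t: x,
        init=lambda th: np.array([0.5]),
    )
    traj = simulate(model, [1.0], constant_stimulus(0.0, 20.0), np.array([20.0]))
    assert traj.states[0, 0] == pytest.approx(1.0, abs=1e-6)


def test_piecewise_stimulus_integrated_exactly():
    # dx/dt = u with u = 2 on [0,1), u = -1 on [1,3): x(t) piecewise linear
    model = OdeModel(
        name="integrator", n_states=1, n_params=1, n_readouts=1,
        rhs=lambda x, u, th, t: np.array([u]),
        readout=lambda x, th, t: x,
        init=lambda th: np.array([0.0]),
    )
    stim = StimulusDesign(np.array([2.0, -1.0]), np.array([1.0]), 3.0)
    traj = simulate(model, [0.0], stim, np.array([0.5, 1.0, 2.0, 3.0]))
    assert np.allclose(traj.states[:, 0], [1.0, 2.0, 1.0, 0.0], atol=1e-9)


def test_sensitivities_zero_without_parameter_dependence(null_stimulus):
    model = OdeModel(
        name="theta_free", n_states=1, n_params=2, n_readouts=1,
        rhs=lambda x, u, th, t: np.array([-x[0]]),
        readout=lambda x, th, t: x,
        init=lambda th: np.array([1.0]),
    )
    _, sens = simulate_with_sensitivities(model, [0.4, 0.7], null_stimulus,
                                          np.linspace(0.0, 1.0, 4))
    assert np.allclose(sens.state_sens, 0.0, atol=1e-10)


def test_exponential_decay_sensitivity_closed_form(exp_decay):
    # d x / d theta = -t exp(-theta t)
    stim = constant_stimulus(0.0, 2.0)
    _, sens = simulate_with_sensitivities(exp_decay, [0.5], stim, np.array([2.0]))
    assert sens.state_sens[0, 0, 0] == pytest.approx(-2.0 * np.exp(-1.0), rel=1e-5)
    assert sens.readout_sens[0, 0, 0] == pytest.approx(-0.735759, abs=1e-5)


@pytest.mark.parametrize("name,theta,stim_level,t_end", [
    # stimulus levels keep the nominal trajectory away from the saddle-node
    # threshold, where sensitivities diverge and finite differences are
    # ill-conditioned
    ("schlogl_A", SCHLOGL_NOMINAL, 10.0, 5.0),
    ("schlogl_B", SCHLOGL_NOMINAL, 10.0, 5.0),
    ("mapk_A", MAPK_NOMINAL, 2.0, 40.0),
    ("mapk_B", MAPK_NOMINAL, 2.0, 40.0),
])
def test_sensitivities_match_finite_differences(name, theta, stim_level, t_end):
    """Augmented-system sensitivities agree with central differences of
    simulate on every bundled model (rel. 1e-4)."""
    model = get_model(name)
    stim = constant_stimulus(stim_level, t_end)
    grid = np.linspace(t_end / 4, t_end, 4)
    _, sens = simulate_with_sensitivities(model, theta, stim, grid)
    fd = np.empty_like(sens.readout_sens)
    for j in range(model.n_params):
        step = 1e-6 * max(abs(theta[j]), 1.0)
        tp, tm = np.array(theta, float), np.array(theta, float)
        tp[j] += step
        tm[j] -= step
        yp = simulate(model, tp, stim, grid).readouts
        ym = simulate(model, tm, stim, grid).readouts
        fd[:, :, j] = (yp - ym) / (2 * step)
    # floor the denominator so exponentially-dead directions (both methods
    # agree the sensitivity is ~0, FD returns pure roundoff) do not compare
    # noise against noise
    scale = np.maximum(np.abs(fd), 1e-3 * np.abs(fd).max())
    assert np.max(np.abs(sens.readout_sens - fd) / scale) < 1e-4


def test_halved_tolerances_leave_solution_stable(exp_decay):
    stim = constant_stimulus(0.0, 2.0)
    a = simulate(exp_decay, [0.5], stim, np.array([2.0]), rtol=1e-8, atol=1e-10)
    b = simulate(exp_decay, [0.5], stim, np.array([2.0]), rtol=5e-9, atol=5e-11)
    assert abs(a.states[0, 0] - b.states[0, 0]) < 10 * 1e-8


def test_simulation_deterministic(exp_decay):
    stim = constant_stimulus(0.0, 2.0)
    grid = np.linspace(0.1, 2.0, 7)
    a = simulate(exp_decay, [0.5], stim, grid)
    b = simulate(exp_decay, [0.5], stim, grid)
    assert np.array_equal(a.states, b.states)


def test_finite_difference_jacobians_match_analytic():
    """FD fallbacks agree with the analytic Jacobians the Schlögl model ships."""
    model = get_model("schlogl_A")
    bare = OdeModel(name="bare", n_states=1, n_params=7, n_readouts=1,
                    rhs=model.rhs, readout=model.readout, init=model.init)
    x = np.array([2.5])
    th = SCHLOGL_NOMINAL
    assert np.allclose(bare.jac_x(x, 10.0, th, 0.0),
                       model.jac_x(x, 10.0, th, 0.0), rtol=1e-5)
    assert np.allclose(bare.jac_theta(x, 10.0, th, 0.0),
                       model.jac_theta(x, 10.0, th, 0.0), rtol=1e-5, atol=1e-8)


def test_blowup_raises_solver_failure(null_stimulus):
    model = OdeModel(
        name="finite_time_blowup", n_states=1, n_params=1, n_readouts=1,
        rhs=lambda x, u, th, t: np.array([x[0] ** 2]),
        readout=lambda x, th, t: x,
        init=lambda th: np.array([1.0]),
    )
    stim = constant_stimulus(0.0, 2.0)
    with pytest.raises(SolverFailure) as err:
        simulate(model, [1.0], stim, np.array([2.0]))
    assert np.isfinite(err.value.time)


def test_input_contract_errors(exp_decay):
    stim = constant_stimulus(0.0, 2.0)
    with pytest.raises(ValueError, match="n_params"):
        simulate(exp_decay, [0.5, 0.1], stim, np.array([1.0]))
    with pytest.raises(ValueError, match="horizon"):
        simulate(exp_decay, [0.5], stim, np.array([3.0]))
    with pytest.raises(ValueError, match="increasing"):
        simulate(exp_decay, [0.5], stim, np.array([1.0, 0.5]))
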