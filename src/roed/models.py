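"""Parameterized ODE models with inputs, readouts and forward sensitivities.

A model is the initial value problem

    dx/dt = f(x, u(t), theta, t),   x(t0) = x0(theta),
    y(t)  = g(x(t), theta, t),

where ``theta`` merges dynamic parameters, readout parameters and (possibly)
initial conditions into one parameter vector.  Stimuli are piecewise
constant; integration restarts at every segment breakpoint so the
discontinuity is never smoothed by the step controller.

Forward sensitivities d x/d theta are obtained by integrating the augmented
system

    dS/dt = (df/dx) S + df/dtheta,   S(t0) = d x0/d theta,

and readout sensitivities follow from the chain rule
d y/d theta = (dg/dx) S + dg/dtheta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import odeint

from .stimulus import StimulusDesign

__all__ = [
    "OdeModel",
    "Trajectory",
    "SensitivityTrajectory",
    "SolverFailure",
    "simulate",
    "simulate_with_sensitivities",
    "register_model",
    "get_model",
    "available_models",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: finite-difference step scale for missing Jacobians
FD_STEP = 1e-6


class SolverFailure(RuntimeError):
    """ODE integration failed (stiff blow-up or non-finite state).

    Attributes
    ----------
    time : the time at which the failure was detected.
    """

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass
class OdeModel:
    """A parameterized ODE model with a stimulus input and readout map."""

    name: str
    n_states: int
    n_params: int
    n_readouts: int
    rhs: Callable[[np.ndarray, float, np.ndarray, float], np.ndarray]
    readout: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    init: Callable[[np.ndarray], np.ndarray]
    n_inputs: int = 1
    rhs_jac_x: Optional[Callable] = None
    rhs_jac_theta: Optional[Callable] = None
    readout_jac_x: Optional[Callable] = None
    readout_jac_theta: Optional[Callable] = None
    init_jac_theta: Optional[Callable] = None

    # --- finite-difference fallbacks -------------------------------------
    def _fd_step(self, v: np.ndarray) -> np.ndarray:
        return FD_STEP * np.maximum(np.abs(v), 1.0)

    def jac_x(self, x, u, theta, t) -> np.ndarray:
        if self.rhs_jac_x is not None:
            return np.asarray(self.rhs_jac_x(x, u, theta, t), float)
        return _central_jac(lambda xx: self.rhs(xx, u, theta, t), x, self._fd_step(x),
                            self.n_states)

    def jac_theta(self, x, u, theta, t) -> np.ndarray:
        if self.rhs_jac_theta is not None:
            return np.asarray(self.rhs_jac_theta(x, u, theta, t), float)
        return _central_jac(lambda th: self.rhs(x, u, th, t), theta,
                            self._fd_step(theta), self.n_states)

    def g_jac_x(self, x, theta, t) -> np.ndarray:
        if self.readout_jac_x is not None:
            return np.asarray(self.readout_jac_x(x, theta, t), float)
        return _central_jac(lambda xx: self.readout(xx, theta, t), x,
                            self._fd_step(x), self.n_readouts)

    def g_jac_theta(self, x, theta, t) -> np.ndarray:
        if self.readout_jac_theta is not None:
            return np.asarray(self.readout_jac_theta(x, theta, t), float)
        return _central_jac(lambda th: self.readout(x, th, t), theta,
                            self._fd_step(theta), self.n_readouts)

    def x0_jac_theta(self, theta) -> np.ndarray:
        if self.init_jac_theta is not None:
            return np.asarray(self.init_jac_theta(theta), float)
        return _central_jac(lambda th: self.init(th), theta,
                            self._fd_step(theta), self.n_states)


def _central_jac(fun, v, steps, n_out) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``v`` (columns = inputs)."""
    v = np.asarray(v, float)
    jac = np.empty((n_out, v.size))
    for j in range(v.size):
        vp, vm = v.copy(), v.copy()
        vp[j] += steps[j]
        vm[j] -= steps[j]
        jac[:, j] = (np.atleast_1d(fun(vp)) - np.atleast_1d(fun(vm))) / (2 * steps[j])
    return jac


@dataclass(frozen=True)
class Trajectory:
    """Solution of one simulation on a measurement grid."""

    time_grid: np.ndarray
    states: np.ndarray      # [time, n_states]
    readouts: np.ndarray    # [time, n_readouts]

    def __post_init__(self):
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.states.shape[0] != self.time_grid.size or \
           self.readouts.shape[0] != self.time_grid.size:
            raise ValueError("row counts must equal grid length")

    def to_frame(self):
        """Export as a pandas DataFrame (columns time, x_1.., y_1..)."""
        import pandas as pd

        data = {"time": self.time_grid}
        for i in range(self.states.shape[1]):
            data[f"x_{i + 1}"] = self.states[:, i]
        for i in range(self.readouts.shape[1]):
            data[f"y_{i + 1}"] = self.readouts[:, i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class SensitivityTrajectory:
    """Forward sensitivities on a measurement grid."""

    time_grid: np.ndarray
    state_sens: np.ndarray    # [time, n_states, n_params]
    readout_sens: np.ndarray  # [time, n_readouts, n_params]


def _check_inputs(model: OdeModel, theta: np.ndarray, stimulus: StimulusDesign,
                  time_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, float)
    if theta.size != model.n_params:
        raise ValueError(f"theta length {theta.size} != n_params {model.n_params}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    time_grid = np.asarray(time_grid, float)
    if time_grid.ndim != 1 or time_grid.size < 1:
        raise ValueError("time_grid must be a 1-D array with >= 1 points")
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if time_grid[0] < 0 or time_grid[-1] > stimulus.horizon + 1e-12:
        raise ValueError("time_grid must lie within [0, stimulus horizon]")
    return theta, time_grid


def _integrate_segments(deriv, x0, stimulus: StimulusDesign, time_grid,
                        rtol, atol):
    """Integrate segment-by-segment, restarting at each stimulus breakpoint.

    ``deriv(x, u, t)`` is the full derivative of the (possibly augmented)
    state.  Returns the solution at the requested grid times.
    """
    edges = stimulus.segment_edges()
    amps = stimulus.segment_amplitudes()
    out = np.empty((time_grid.size, x0.size))
    x = np.asarray(x0, float)
    t_cur = 0.0
    k = 0  # next grid index to fill
    # grid points exactly at t = 0
    while k < time_grid.size and time_grid[k] <= t_cur + 1e-14:
        out[k] = x
        k += 1
    for e1, u in zip(edges[1:], amps):
        if e1 <= t_cur + 1e-14:
            continue
        seg_end = min(e1, stimulus.horizon)
        # grid times inside (t_cur, seg_end]
        idx_hi = k
        while idx_hi < time_grid.size and time_grid[idx_hi] <= seg_end + 1e-12:
            idx_hi += 1
        ts = np.concatenate(([t_cur], time_grid[k:idx_hi], [seg_end]))
        ts = np.unique(ts)
        sol, info = odeint(deriv, x, ts, args=(float(u),), tfirst=True,
                           rtol=rtol, atol=atol, mxstep=10_000,
                           full_output=True)
        if info["message"] != "Integration successful." or \
                not np.all(np.isfinite(sol)):
            t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) \
                else float(ts[0])
            raise SolverFailure(
                f"integration failed near t = {t_fail:g}: {info['message']}",
                t_fail)
        # map solution rows back to requested grid times
        for t_req in time_grid[k:idx_hi]:
            row = np.searchsorted(ts, t_req)
            out[k] = sol[row]
            k += 1
        x = sol[-1]
        t_cur = seg_end
        if t_cur >= time_grid[-1] - 1e-12 and k >= time_grid.size:
            break
    if k < time_grid.size:  # pragma: no cover - guarded by _check_inputs
        raise SolverFailure("grid extends past stimulus horizon", float(time_grid[k]))
    return out


def simulate(model: OdeModel, theta, stimulus: StimulusDesign, time_grid,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> Trajectory:
    """Solve the model IVP under a piecewise-constant stimulus.

    Readouts are evaluated on the requested grid.  Raises
    :class:`SolverFailure` if the integrator produces non-finite states.
    """
    theta, time_grid = _check_inputs(model, theta, stimulus, time_grid)
    x0 = np.atleast_1d(np.asarray(model.init(theta), float))
    if x0.size != model.n_states:
        raise ValueError("init map returned wrong number of states")

    def deriv(t, x, u):
        return np.atleast_1d(model.rhs(x, u, theta, t))

    states = _integrate_segments(deriv, x0, stimulus, time_grid, rtol, atol)
    readouts = np.empty((time_grid.size, model.n_readouts))
    for i, t in enumerate(time_grid):
        readouts[i] = np.atleast_1d(model.readout(states[i], theta, t))
    return Trajectory(time_grid, states, readouts)


def simulate_with_sensitivities(
    model: OdeModel, theta, stimulus: StimulusDesign, time_grid,
    rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
) -> tuple[Trajectory, SensitivityTrajectory]:
    """Jointly integrate states and forward sensitivities.

    The augmented system has ``n_states * (1 + n_params)`` equations; the
    sensitivity block evolves as dS/dt = J_x S + J_theta with
    S(0) = d x0 / d theta.
    """
    theta, time_grid = _check_inputs(model, theta, stimulus, time_grid)
    nx, np_ = model.n_states, model.n_params
    x0 = np.atleast_1d(np.asarray(model.init(theta), float))
    s0 = model.x0_jac_theta(theta)
    z0 = np.concatenate([x0, s0.ravel()])

    def deriv(t, z, u):
        x = z[:nx]
        s = z[nx:].reshape(nx, np_)
        dx = np.atleast_1d(model.rhs(x, u, theta, t))
        jx = model.jac_x(x, u, theta, t)
        jt = model.jac_theta(x, u, theta, t)
        ds = jx @ s + jt
        return np.concatenate([dx, ds.ravel()])

    sol = _integrate_segments(deriv, z0, stimulus, time_grid, rtol, atol)
    states = sol[:, :nx]
    state_sens = sol[:, nx:].reshape(-1, nx, np_)
    readouts = np.empty((time_grid.size, model.n_readouts))
    readout_sens = np.empty((time_grid.size, model.n_readouts, np_))
    for i, t in enumerate(time_grid):
        x = states[i]
        readouts[i] = np.atleast_1d(model.readout(x, theta, t))
        readout_sens[i] = model.g_jac_x(x, theta, t) @ state_sens[i] + \
            model.g_jac_theta(x, theta, t)
    return (Trajectory(time_grid, states, readouts),
            SensitivityTrajectory(time_grid, state_sens, readout_sens))


# --- model registry -------------------------------------------------------

_REGISTRY: dict[str, Callable[[], OdeModel]] = {}


def register_model(name: str, factory: Callable[[], OdeModel]) -> None:
    """Register a model factory under a name (overwrites silently)."""
    _REGISTRY[name] = factory


def get_model(name: str) -> OdeModel:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(_REGISTRY)}") from None
    return factory()


def available_models() -> list[str]:
    return sorted(_REGISTRY)
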