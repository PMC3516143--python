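"""Propagate parameter uncertainty to response mean/covariance trajectories.

Three estimators share one contract: given a model, a parameter
distribution, a stimulus and a measurement grid, return the per-time-point
mean vector and covariance matrix of the (optionally log-transformed)
response, with additive measurement noise variance sigma^2 on the
transformed scale.

* linearization — first-order (delta-method) propagation through forward
  sensitivities; one augmented ODE solve; exact for linear maps, local
  otherwise (coexisting stable branches are invisible to it).
* sigma points — 2n+1 deterministic samples of the parameter distribution,
  each simulated independently; captures curvature without derivatives.
* Monte Carlo — seeded random sampling; the reference the others are
  judged against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .distributions import ParameterDistribution, build_sigma_points, sample_parameters
from .models import OdeModel, SolverFailure, simulate, simulate_with_sensitivities
from .stimulus import StimulusDesign

log = logging.getLogger(__name__)

__all__ = [
    "MomentTrajectory",
    "ResponseTransform",
    "propagate_linearized",
    "propagate_sigma_points",
    "propagate_monte_carlo",
    "propagate",
]


@dataclass(frozen=True)
class ResponseTransform:
    """Transform applied to readouts before moment estimation.

    ``kind='log'`` takes elementwise ln (responses floored at ``floor_eps``
    first); ``noise_sd`` is the measurement-noise standard deviation added
    as sigma^2 I on the transformed scale.
    """

    kind: Literal["identity", "log"] = "identity"
    noise_sd: float = 0.0
    floor_eps: float = 1e-12

    def __post_init__(self):
        if self.kind not in ("identity", "log"):
            raise ValueError("kind must be 'identity' or 'log'")
        if self.floor_eps <= 0:
            raise ValueError("floor_eps must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.kind == "identity":
            return y
        if np.any(y < self.floor_eps):
            log.warning("log transform floored %d nonpositive responses",
                        int(np.sum(y < self.floor_eps)))
        return np.log(np.maximum(y, self.floor_eps))

    def chain_scale(self, y: np.ndarray) -> np.ndarray:
        """d(transform)/dy evaluated at y (for sensitivity chain rule)."""
        if self.kind == "identity":
            return np.ones_like(y)
        return 1.0 / np.maximum(y, self.floor_eps)


@dataclass(frozen=True)
class MomentTrajectory:
    """Per-time-point response mean and covariance for one model."""

    time_grid: np.ndarray
    means: np.ndarray  # [NT, n_readouts]
    covs: np.ndarray   # [NT, n_readouts, n_readouts]
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.means.shape[0] != self.time_grid.size or \
           self.covs.shape[0] != self.time_grid.size:
            raise ValueError("means/covs rows must match time grid")
        if self.covs.shape[1] != self.covs.shape[2] or \
           self.covs.shape[1] != self.means.shape[1]:
            raise ValueError("covs must be [NT, d, d] matching means [NT, d]")

    @property
    def n_readouts(self) -> int:
        return self.means.shape[1]

    def to_frame(self):
        """Long-format DataFrame: time, i, j, mean_i, cov_ij."""
        import pandas as pd

        rows = []
        d = self.n_readouts
        for k, t in enumerate(self.time_grid):
            for i in range(d):
                for j in range(d):
                    rows.append((t, i + 1, j + 1, self.means[k, i], self.covs[k, i, j]))
        return pd.DataFrame(rows, columns=["time", "readout_i", "readout_j",
                                           "mean_i", "cov_ij"])


def _psd_clip(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() < 0:
        if w.min() < -1e-10 * max(np.trace(cov), 1.0):
            log.warning("response covariance clipped: min eigenvalue %g", w.min())
        cov = (v * np.maximum(w, 0.0)) @ v.T
        cov = 0.5 * (cov + cov.T)
    return cov


def propagate_linearized(
    model: OdeModel,
    dist: ParameterDistribution,
    stimulus: StimulusDesign,
    time_grid,
    transform: ResponseTransform = ResponseTransform(),
    rtol: float = 1e-8, atol: float = 1e-10,
) -> MomentTrajectory:
    """First-order moment estimates via forward sensitivities.

    mean(t) = transformed readout at theta = E[theta];
    cov(t) = S(t) Sigma_theta S(t)^T + sigma^2 I, with S the
    transformed-response sensitivity (log transform row-scales by 1/y).
    """
    time_grid = np.asarray(time_grid, float)
    traj, sens = simulate_with_sensitivities(model, dist.mean, stimulus, time_grid,
                                             rtol=rtol, atol=atol)
    nt, d = traj.readouts.shape
    means = transform.apply(traj.readouts)
    covs = np.empty((nt, d, d))
    noise = transform.noise_sd**2 * np.eye(d)
    for k in range(nt):
        s = transform.chain_scale(traj.readouts[k])[:, None] * sens.readout_sens[k]
        covs[k] = _psd_clip(s @ dist.cov @ s.T) + noise
    return MomentTrajectory(time_grid, means, covs, "linearization",
                            {"rtol": rtol, "atol": atol})


def propagate_sigma_points(
    model: OdeModel,
    dist: ParameterDistribution,
    stimulus: StimulusDesign,
    time_grid,
    transform: ResponseTransform = ResponseTransform(),
    alpha: float | None = None, beta: float | None = None, kappa: float | None = None,
    rtol: float = 1e-8, atol: float = 1e-10,
) -> MomentTrajectory:
    """Unscented (sigma-point) moment estimates: 2n+1 independent simulations."""
    from .distributions import UT_ALPHA, UT_BETA

    time_grid = np.asarray(time_grid, float)
    sp = build_sigma_points(dist,
                            alpha=UT_ALPHA if alpha is None else alpha,
                            beta=UT_BETA if beta is None else beta,
                            kappa=kappa)
    responses = np.empty((sp.n_points, time_grid.size, model.n_readouts))
    for i, theta in enumerate(sp.points):
        try:
            traj = simulate(model, theta, stimulus, time_grid, rtol=rtol, atol=atol)
        except SolverFailure as exc:
            raise SolverFailure(
                f"sigma point {i} failed for model {model.name!r}: {exc}",
                exc.time) from exc
        responses[i] = transform.apply(traj.readouts)
    nt, d = time_grid.size, model.n_readouts
    means = np.empty((nt, d))
    covs = np.empty((nt, d, d))
    noise = transform.noise_sd**2 * np.eye(d)
    for k in range(nt):
        m, c = sp.estimate_moments(responses[:, k, :])
        means[k], covs[k] = m, c + noise
    return MomentTrajectory(time_grid, means, covs, "sigma-point",
                            {"ut_params": sp.ut_params})


def propagate_monte_carlo(
    model: OdeModel,
    dist: ParameterDistribution,
    stimulus: StimulusDesign,
    time_grid,
    transform: ResponseTransform = ResponseTransform(),
    n_samples: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    rtol: float = 1e-8, atol: float = 1e-10,
    max_fail_frac: float = 0.01,
) -> MomentTrajectory:
    """Monte Carlo moment estimates (unbiased n-1 covariance).

    Failed sample simulations are dropped with a logged count; more than
    ``max_fail_frac`` failures raise :class:`SolverFailure`.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    time_grid = np.asarray(time_grid, float)
    thetas = sample_parameters(dist, n_samples, seed)
    nt, d = time_grid.size, model.n_readouts
    responses = np.empty((n_samples, nt, d))
    ok = np.ones(n_samples, dtype=bool)
    for i in range(n_samples):
        try:
            traj = simulate(model, thetas[i], stimulus, time_grid, rtol=rtol, atol=atol)
            responses[i] = transform.apply(traj.readouts)
        except SolverFailure:
            ok[i] = False
    n_fail = int(np.sum(~ok))
    if n_fail:
        log.warning("Monte Carlo dropped %d/%d failed simulations", n_fail, n_samples)
        if n_fail > max_fail_frac * n_samples:
            raise SolverFailure(
                f"{n_fail}/{n_samples} Monte Carlo simulations failed", float("nan"))
    resp = responses[ok]
    means = resp.mean(axis=0)
    covs = np.empty((nt, d, d))
    noise = transform.noise_sd**2 * np.eye(d)
    for k in range(nt):
        dev = resp[:, k, :] - means[k]
        covs[k] = dev.T @ dev / (resp.shape[0] - 1) + noise
    return MomentTrajectory(time_grid, means, covs, "monte-carlo",
                            {"n_samples": n_samples, "n_failed": n_fail,
                             "seed": _seed_repr(seed)})


def _seed_repr(seed):
    return seed.entropy if isinstance(seed, np.random.SeedSequence) else seed


def propagate(method: str, model, dist, stimulus, time_grid,
              transform: ResponseTransform = ResponseTransform(), **kwargs) -> MomentTrajectory:
    """Dispatch by estimator name ('linearization' | 'sigma-point' | 'monte-carlo')."""
    table = {
        "linearization": propagate_linearized,
        "sigma-point": propagate_sigma_points,
        "monte-carlo": propagate_monte_carlo,
    }
    try:
        fn = table[method]
    except KeyError:
        raise ValueError(f"unknown estimator {method!r}; choose from {sorted(table)}") from None
    return fn(model, dist, stimulus, time_grid, transform, **kwargs)
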