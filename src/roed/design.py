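"""Stimulus design optimization for model discrimination.

The design variables are the flat control-vector parameterization of a
piecewise-constant stimulus (Nw amplitudes + Nw-1 durations).  The
objective is the time-averaged Gaussian overlap of the two models'
propagated response distributions, plus quadratic penalties for horizon
overshoot and bound violations; lower is better.  The search is a hybrid:
a seeded CMA-ES global phase followed by a derivative-free Nelder-Mead
polish, repeated from multiple random starting designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .cmaes import cma_es
from .distributions import ParameterDistribution
from .models import OdeModel, SolverFailure
from .overlap import OverlapResult, mean_overlap
from .propagation import MomentTrajectory, ResponseTransform, propagate
from .stimulus import (ClipReport, DesignSpace, StimulusDesign, decode_design,
                       encode_design)

log = logging.getLogger(__name__)

__all__ = ["DesignProblem", "OptimizationResult", "objective", "optimize_design"]

#: sentinel objective for failed estimator evaluations (keeps stochastic
#: search alive instead of aborting the run)
FAILURE_SENTINEL = 1e6

DEFAULT_PENALTY_WEIGHT = 1e3


@dataclass
class DesignProblem:
    """Two rival models plus everything needed to score a stimulus design."""

    model_a: OdeModel
    model_b: OdeModel
    dist_a: ParameterDistribution
    dist_b: ParameterDistribution
    design_space: DesignSpace
    measurement_times: np.ndarray
    transform: ResponseTransform = field(default_factory=ResponseTransform)
    estimator: Literal["linearization", "sigma-point", "monte-carlo"] = "sigma-point"
    kernel_power: float = 1.0
    penalty_weight: float = DEFAULT_PENALTY_WEIGHT
    ut_params: dict = field(default_factory=dict)
    mc_params: dict = field(default_factory=dict)
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self):
        self.measurement_times = np.asarray(self.measurement_times, float)
        if self.measurement_times[-1] > self.design_space.horizon + 1e-12:
            raise ValueError("measurement times must lie within the design horizon")
        if self.model_a.n_inputs != self.model_b.n_inputs or \
           self.model_a.n_readouts != self.model_b.n_readouts:
            raise ValueError("models must share input and readout dimensions")

    def _estimator_kwargs(self) -> dict:
        if self.estimator == "sigma-point":
            return dict(self.ut_params)
        if self.estimator == "monte-carlo":
            return dict(self.mc_params)
        return {}

    def moments(self, design: StimulusDesign) -> tuple[MomentTrajectory, MomentTrajectory]:
        """Propagate both models under ``design`` with the configured estimator."""
        kwargs = self._estimator_kwargs()
        kwargs.update(rtol=self.rtol, atol=self.atol)
        ma = propagate(self.estimator, self.model_a, self.dist_a, design,
                       self.measurement_times, self.transform, **kwargs)
        mb = propagate(self.estimator, self.model_b, self.dist_b, design,
                       self.measurement_times, self.transform, **kwargs)
        return ma, mb

    def overlap(self, design: StimulusDesign,
                clip: ClipReport | None = None) -> OverlapResult:
        """Mean overlap of the two response distributions plus penalties."""
        ma, mb = self.moments(design)
        penalty = self.penalty(design, clip)
        return mean_overlap(ma, mb, self.kernel_power, penalty=penalty)

    def penalty(self, design: StimulusDesign, clip: ClipReport | None = None) -> float:
        """Quadratic horizon-overshoot and bound-clip penalties."""
        overshoot = max(0.0, float(np.sum(design.durations)) - self.design_space.horizon)
        pen = self.penalty_weight * overshoot**2
        if clip is not None:
            pen += self.penalty_weight * clip.total**2
        return pen


def objective(problem: DesignProblem, design: StimulusDesign | np.ndarray) -> float:
    """Penalized mean overlap of a design (lower = more discriminative).

    Accepts either a :class:`StimulusDesign` or a flat design vector (which
    is decoded with bound clipping; the clip distance feeds the penalty).
    Estimator failures return a large finite sentinel so stochastic search
    can continue.
    """
    clip = None
    if not isinstance(design, StimulusDesign):
        design, clip = decode_design(np.asarray(design, float), problem.design_space)
    try:
        return float(objective_result(problem, design, clip).penalized)
    except (SolverFailure, np.linalg.LinAlgError) as exc:
        log.warning("objective evaluation failed (%s); returning sentinel", exc)
        return FAILURE_SENTINEL


def objective_result(problem: DesignProblem, design: StimulusDesign,
                     clip: ClipReport | None = None) -> OverlapResult:
    return problem.overlap(design, clip)


@dataclass
class OptimizationResult:
    """Best design across restarts, with reproducibility metadata."""

    best_design: StimulusDesign
    best_objective: float
    history: np.ndarray           # best-so-far objective per CMA-ES generation
    seed: int
    n_restarts: int
    estimator: str
    restart_objectives: list[float] = field(default_factory=list)
    n_evals: int = 0

    def to_dict(self) -> dict:
        return {
            "best_objective": self.best_objective,
            "amplitudes": self.best_design.amplitudes.tolist(),
            "durations": self.best_design.durations.tolist(),
            "horizon": self.best_design.horizon,
            "history": np.asarray(self.history).tolist(),
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "estimator": self.estimator,
            "restart_objectives": self.restart_objectives,
            "n_evals": self.n_evals,
        }


def _random_design_vector(space: DesignSpace, rng: np.random.Generator) -> np.ndarray:
    amps = rng.uniform(0.0, space.u_max, size=space.n_segments)
    # durations drawn so the cumulative sum stays within the horizon
    if space.n_segments > 1:
        free = max(space.horizon - space.dt_min * (space.n_segments - 1), 0.0)
        raw = rng.dirichlet(np.ones(space.n_segments))[:-1] * free
        durs = space.dt_min + raw
    else:
        durs = np.empty(0)
    return np.concatenate([amps, durs])


def optimize_design(
    problem: DesignProblem,
    seed: int = 0,
    n_restarts: int = 1,
    budget: int = 300,
    popsize: int | None = None,
    sigma0_frac: float = 0.25,
    polish: bool = True,
    polish_maxiter: int = 60,
) -> OptimizationResult:
    """Hybrid multistart optimization of the discrimination objective.

    Each restart runs a seeded CMA-ES from a random in-bounds design
    (``budget`` objective evaluations for the global phase), then a
    Nelder-Mead polish from the CMA-ES incumbent.  The best design across
    restarts is returned; identical seeds give identical results.
    """
    space = problem.design_space
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_restarts)

    # search in a normalized space (amplitudes / u_max, durations / horizon)
    # so one CMA-ES step size fits all coordinates
    scale = np.concatenate([
        np.full(space.n_segments, space.u_max if space.u_max > 0 else 1.0),
        np.full(space.n_segments - 1, space.horizon),
    ])
    fun = lambda v: objective(problem, v * scale)

    best_vec = None
    best_f = np.inf
    history: list[float] = []
    restart_objectives: list[float] = []
    total_evals = 0
    failures = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        x0 = _random_design_vector(space, rng) / scale
        try:
            res = cma_es(fun, x0, sigma0=sigma0_frac,
                         seed=child.spawn(1)[0], max_evals=budget, popsize=popsize)
            total_evals += res.n_evals
            x_loc, f_loc = res.x_best, res.f_best
            if polish:
                loc = minimize(fun, x_loc, method="Nelder-Mead",
                               options={"maxiter": polish_maxiter,
                                        "xatol": 1e-7, "fatol": 1e-12})
                total_evals += loc.nfev
                if loc.fun < f_loc:
                    x_loc, f_loc = loc.x, float(loc.fun)
            restart_objectives.append(f_loc)
            # best-so-far across restarts, concatenated per generation
            running = min(best_f, np.inf)
            for h in res.history:
                running = min(running, h)
                history.append(running)
            if f_loc < best_f:
                best_f = f_loc
                best_vec = x_loc
            history.append(best_f)
        except Exception as exc:  # noqa: BLE001 - per-restart diagnostics
            log.warning("restart %d failed: %s", r, exc)
            failures.append((r, repr(exc)))
            restart_objectives.append(float("nan"))
    if best_vec is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")
    best_design, clip = decode_design(best_vec * scale, space)
    # re-evaluate the decoded (clipped) design so the reported objective
    # matches a fresh evaluation exactly
    best_f = float(objective_result(problem, best_design, clip).penalized)
    return OptimizationResult(
        best_design=best_design,
        best_objective=best_f,
        history=np.minimum.accumulate(np.asarray(history)) if history else np.empty(0),
        seed=seed,
        n_restarts=n_restarts,
        estimator=problem.estimator,
        restart_objectives=restart_objectives,
        n_evals=total_evals,
    )
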