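"""Monte Carlo verification of optimized designs and relative-MSE scoring.

An estimator (linearization or sigma points) proposes moment trajectories;
the Monte Carlo reference re-propagates the parameter distribution by
seeded random sampling.  The report compares the overlap computed from each
and scores the estimator's moments by a componentwise relative MSE,
averaged over time points and components:

    rel_mse = mean_k,i [ (est_k,i - ref_k,i)^2 / ref_k,i^2 ]

split into mean, variance (diagonal covariance entries) and covariance
(strict off-diagonal) classes; the denominator is floored at 1e-24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignProblem
from .overlap import mean_overlap
from .propagation import MomentTrajectory, propagate_monte_carlo
from .stimulus import StimulusDesign

__all__ = ["VerificationReport", "relative_mse", "verify_design"]

_REF_FLOOR = 1e-24


@dataclass(frozen=True)
class ModelVerification:
    """Per-model comparison of estimator moments to the MC reference."""

    rel_mse_mean: float
    rel_mse_var: float
    rel_mse_cov: float
    cov_class_empty: bool = False


@dataclass(frozen=True)
class VerificationReport:
    """Design verification: MC overlap vs estimator overlap plus rel-MSEs."""

    mc_overlap: float
    est_overlap: float
    per_model: dict = field(default_factory=dict)     # name -> ModelVerification
    rel_mse_mean: float = 0.0   # aggregated (mean over models)
    rel_mse_var: float = 0.0
    rel_mse_cov: float = 0.0
    n_samples: int = 0
    seed: int | None = None
    estimator: str = ""
    mc_moments: tuple[MomentTrajectory, MomentTrajectory] | None = None
    est_moments: tuple[MomentTrajectory, MomentTrajectory] | None = None

    def to_dict(self) -> dict:
        return {
            "mc_overlap": self.mc_overlap,
            "est_overlap": self.est_overlap,
            "estimator": self.estimator,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "rel_mse_mean": self.rel_mse_mean,
            "rel_mse_var": self.rel_mse_var,
            "rel_mse_cov": self.rel_mse_cov,
            "per_model": {
                name: {
                    "rel_mse_mean": mv.rel_mse_mean,
                    "rel_mse_var": mv.rel_mse_var,
                    "rel_mse_cov": mv.rel_mse_cov,
                    "cov_class_empty": mv.cov_class_empty,
                } for name, mv in self.per_model.items()
            },
        }


def relative_mse(est: MomentTrajectory, ref: MomentTrajectory
                 ) -> tuple[float, float, float]:
    """Componentwise relative squared error of moment estimates vs a reference.

    Returns ``(rel_mse_mean, rel_mse_var, rel_mse_cov)``.  For 1-D readouts
    the covariance class is empty and reported as 0.
    """
    if est.time_grid.size != ref.time_grid.size or \
       not np.allclose(est.time_grid, ref.time_grid):
        raise ValueError("moment trajectories must share the time grid")
    if est.n_readouts != ref.n_readouts:
        raise ValueError("moment trajectories must share the readout dimension")

    def _rel(e: np.ndarray, r: np.ndarray) -> float:
        if e.size == 0:
            return 0.0
        return float(np.mean((e - r) ** 2 / np.maximum(r**2, _REF_FLOOR)))

    d = est.n_readouts
    diag = np.arange(d)
    off = ~np.eye(d, dtype=bool)
    mse_mean = _rel(est.means, ref.means)
    mse_var = _rel(est.covs[:, diag, diag], ref.covs[:, diag, diag])
    mse_cov = _rel(est.covs[:, off], ref.covs[:, off])
    return mse_mean, mse_var, mse_cov


def verify_design(
    problem: DesignProblem,
    design: StimulusDesign,
    n_samples: int = 10_000,
    seed: int = 0,
) -> VerificationReport:
    """Monte Carlo verification of one design against the problem's estimator.

    Draws ``n_samples`` parameter sets per model (independent sub-seeds
    fanned out from ``seed``), rebuilds the MC moment trajectories, computes
    the MC-verified overlap, and scores the estimator's moments with
    :func:`relative_mse` per model and aggregated (mean over the two models).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100 for a meaningful reference")
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = ss.spawn(2)
    mc_a = propagate_monte_carlo(problem.model_a, problem.dist_a, design,
                                 problem.measurement_times, problem.transform,
                                 n_samples=n_samples, seed=seed_a,
                                 rtol=problem.rtol, atol=problem.atol)
    mc_b = propagate_monte_carlo(problem.model_b, problem.dist_b, design,
                                 problem.measurement_times, problem.transform,
                                 n_samples=n_samples, seed=seed_b,
                                 rtol=problem.rtol, atol=problem.atol)
    if problem.estimator == "monte-carlo" and "seed" not in problem.mc_params:
        # self-comparison convention: an MC "estimator" without its own seed
        # reuses the reference draws (same seeds/sample count)
        n_est = problem.mc_params.get("n_samples", n_samples)
        est_a = propagate_monte_carlo(problem.model_a, problem.dist_a, design,
                                      problem.measurement_times, problem.transform,
                                      n_samples=n_est, seed=seed_a,
                                      rtol=problem.rtol, atol=problem.atol)
        est_b = propagate_monte_carlo(problem.model_b, problem.dist_b, design,
                                      problem.measurement_times, problem.transform,
                                      n_samples=n_est, seed=seed_b,
                                      rtol=problem.rtol, atol=problem.atol)
    else:
        est_a, est_b = problem.moments(design)
    mc_ov = mean_overlap(mc_a, mc_b, problem.kernel_power).mean_overlap
    est_ov = mean_overlap(est_a, est_b, problem.kernel_power).mean_overlap

    per_model = {}
    aggregates = np.zeros(3)
    for name, est, ref in ((problem.model_a.name, est_a, mc_a),
                           (problem.model_b.name, est_b, mc_b)):
        m, v, c = relative_mse(est, ref)
        per_model[name] = ModelVerification(m, v, c,
                                            cov_class_empty=est.n_readouts < 2)
        aggregates += (m, v, c)
    aggregates /= 2.0
    return VerificationReport(
        mc_overlap=mc_ov,
        est_overlap=est_ov,
        per_model=per_model,
        rel_mse_mean=float(aggregates[0]),
        rel_mse_var=float(aggregates[1]),
        rel_mse_cov=float(aggregates[2]),
        n_samples=n_samples,
        seed=seed,
        estimator=problem.estimator,
        mc_moments=(mc_a, mc_b),
        est_moments=(est_a, est_b),
    )
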