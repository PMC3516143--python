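"""Scaled benchmark protocols with headline comparison quantities.

These drive the two bundled systems end to end — multistart hybrid
optimization with each estimator, Monte Carlo verification of the winning
designs — and distil the comparison into the quantities the benchmark is
about:

* how much better (in MC-verified overlap) the sigma-point design is than
  the linearization design,
* by what factor the linearization estimate understates its own design's
  true overlap,
* the relative MSEs of each estimator's moment predictions, and
* where model B's population ends up (branch occupancy) under the winning
  sigma-point design on the bistable system.

Problem sizes default to desk-scale settings (tens of restarts, 10^3-10^4
MC samples) chosen so a full protocol completes in minutes on one core;
they are arguments, not constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..design import optimize_design
from ..distributions import sample_parameters
from ..models import simulate
from ..verification import verify_design
from .runner import build_problem

log = logging.getLogger(__name__)

__all__ = ["schlogl_protocol", "mapk_protocol", "branch_occupancy"]


def branch_occupancy(problem, design, n_samples: int = 1000, seed: int = 0,
                     model: str = "b") -> dict:
    """Monte Carlo terminal-state branch split for one model under a design.

    Returns the fraction of parameter draws whose terminal response lies
    above the nominal separatrix (upper branch) and below it.
    """
    from .schlogl import schlogl_steady_states

    roots, _ = schlogl_steady_states()
    separatrix = roots[1]
    mdl = problem.model_b if model == "b" else problem.model_a
    dist = problem.dist_b if model == "b" else problem.dist_a
    thetas = sample_parameters(dist, n_samples, seed)
    t_end = np.array([problem.measurement_times[-1]])
    terminal = np.empty(n_samples)
    for i, th in enumerate(thetas):
        terminal[i] = simulate(mdl, th, design, t_end,
                               rtol=problem.rtol, atol=problem.atol).readouts[0, 0]
    return {
        "upper_fraction": float(np.mean(terminal > separatrix)),
        "lower_fraction": float(np.mean(terminal < separatrix)),
        "separatrix": float(separatrix),
    }


@dataclass
class ProtocolCell:
    """One (estimator, eta) protocol outcome."""

    estimator: str
    eta: float
    est_overlap: float
    mc_overlap: float
    rel_mse_mean: float
    rel_mse_var: float
    rel_mse_cov: float
    design: object
    n_evals: int


def _run_cell(system: str, eta: float, estimator: str, seed: int,
              n_restarts: int, budget: int, polish_maxiter: int,
              n_mc: int, **overrides) -> ProtocolCell:
    problem = build_problem(system, eta, estimator, **overrides)
    result = optimize_design(problem, seed=seed, n_restarts=n_restarts,
                             budget=budget, polish_maxiter=polish_maxiter)
    report = verify_design(problem, result.best_design, n_samples=n_mc,
                           seed=seed + 10_000)
    return ProtocolCell(
        estimator=estimator, eta=eta,
        est_overlap=report.est_overlap, mc_overlap=report.mc_overlap,
        rel_mse_mean=report.rel_mse_mean, rel_mse_var=report.rel_mse_var,
        rel_mse_cov=report.rel_mse_cov,
        design=result.best_design, n_evals=result.n_evals,
    )


def schlogl_protocol(seed: int = 1, n_restarts: int = 50, budget: int = 120,
                     polish_maxiter: int = 30, n_mc: int = 10_000,
                     eta: float | None = None,
                     n_occupancy: int = 1000) -> dict:
    """Optimize + verify the Schlögl pair with both estimators.

    Returns the per-estimator cells plus the headline comparison ratios and
    the branch occupancy of model B under the sigma-point design.
    """
    from .schlogl import SCHLOGL_DEFAULTS

    eta_val = eta if eta is not None else SCHLOGL_DEFAULTS["eta"]
    cells = {}
    for i, estimator in enumerate(("linearization", "sigma-point")):
        cells[estimator] = _run_cell("schlogl", eta_val, estimator,
                                     seed + 100 * i, n_restarts, budget,
                                     polish_maxiter, n_mc)
    lin, sp = cells["linearization"], cells["sigma-point"]
    problem = build_problem("schlogl", eta_val, "sigma-point")
    occupancy = branch_occupancy(problem, sp.design, n_samples=n_occupancy,
                                 seed=seed + 777)
    return {
        "cells": cells,
        "mc_overlap_ratio_lin_over_sp": lin.mc_overlap / sp.mc_overlap,
        "lin_underestimation_factor": lin.mc_overlap / max(lin.est_overlap,
                                                           1e-300),
        "sp_estimate_ratio_mc_over_est": sp.mc_overlap / max(sp.est_overlap,
                                                             1e-300),
        "rel_mse_var_ratio_lin_over_sp": lin.rel_mse_var / max(sp.rel_mse_var,
                                                               1e-300),
        "model_b_occupancy": occupancy,
    }


def mapk_protocol(seed: int = 1, etas=(0.01, 0.4), n_repeats: int = 5,
                  budget: int = 120, polish_maxiter: int = 30,
                  n_mc: int = 1000, n_segments: int = 6) -> dict:
    """Optimize + verify the MAPK pair with both estimators per eta level.

    The scaled protocol uses a coarser stimulus parameterization
    (``n_segments`` instead of the full 20) so each optimization stays
    desk-scale; the design space override is part of the scaled protocol,
    not of the bundled defaults.
    """
    results = {}
    for j, eta in enumerate(etas):
        cells = {}
        for i, estimator in enumerate(("linearization", "sigma-point")):
            cells[estimator] = _run_cell(
                "mapk", eta, estimator, seed + 100 * i + 1000 * j,
                n_repeats, budget, polish_maxiter, n_mc,
                n_segments=n_segments)
        lin, sp = cells["linearization"], cells["sigma-point"]
        results[eta] = {
            "cells": cells,
            "mc_overlap_ratio_lin_over_sp": lin.mc_overlap / sp.mc_overlap,
            "rel_mse_var_lin": lin.rel_mse_var,
            "rel_mse_var_sp": sp.rel_mse_var,
            "rel_mse_cov_lin": lin.rel_mse_cov,
            "rel_mse_cov_sp": sp.rel_mse_cov,
        }
    return results
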