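"""A compact (mu/mu_w, lambda) Covariance Matrix Adaptation Evolution Strategy.

Standard CMA-ES with rank-one and rank-mu covariance updates and cumulative
step-size adaptation, sufficient for the low-dimensional (10-40 variables)
control-vector-parameterization problems this package solves.  Fully
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["cma_es", "CmaResult"]


@dataclass
class CmaResult:
    x_best: np.ndarray
    f_best: float
    history: list[float] = field(default_factory=list)  # best-so-far per generation
    n_evals: int = 0


def cma_es(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    seed: int | np.random.SeedSequence,
    max_evals: int = 1000,
    popsize: int | None = None,
    ftol: float = 1e-12,
) -> CmaResult:
    """Minimize ``objective`` starting from ``x0`` with initial step ``sigma0``.

    Stops on the evaluation budget, step-size collapse, or stagnation of the
    population spread below ``ftol``.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, float)
    n = x0.size
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = x0.copy()
    sigma = float(sigma0)
    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    inv_sqrt_c = np.eye(n)
    eigen_stale = 0

    res = CmaResult(x_best=x0.copy(), f_best=np.inf)
    gen = 0
    while res.n_evals + lam <= max_evals:
        gen += 1
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T          # y_i = B D z_i
        xs = mean + sigma * y
        fs = np.array([objective(x) for x in xs])
        res.n_evals += lam
        order = np.argsort(fs)
        if fs[order[0]] < res.f_best:
            res.f_best = float(fs[order[0]])
            res.x_best = xs[order[0]].copy()
        res.history.append(res.f_best)

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (inv_sqrt_c @ y_w)
        h_sig = (np.linalg.norm(ps)
                 / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_n) < 1.4 + 2 / (n + 1)
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not h_sig) * cc * (2 - cc) * C)
             + cmu * rank_mu)
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        eigen_stale += lam
        if eigen_stale > lam * max(1, int(1 / (10 * n * (c1 + cmu)))):
            eigen_stale = 0
            C = 0.5 * (C + C.T)
            d2, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(d2, 1e-20))
            inv_sqrt_c = (B / D) @ B.T

        if sigma * D.max() < 1e-12:
            break
        if fs[order[min(mu, lam - 1)]] - fs[order[0]] < ftol and gen > 10:
            break
    return res
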