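"""Model overlap: the probability product kernel between Gaussian responses.

For two response distributions approximated as Gaussians N(mu_a, Sigma_a)
and N(mu_b, Sigma_b), the probability product kernel

    k_p = integral N_a(y)^p N_b(y)^p dy

has a closed form.  At p = 1 it is the expected likelihood of one model
under the other ("model overlap"), equal to the Gaussian convolution
identity N(mu_a - mu_b; 0, Sigma_a + Sigma_b); at p = 1/2 it is the
Bhattacharyya coefficient, equal to 1 iff the distributions coincide.  The
design criterion is the arithmetic mean of k_p over the measurement grid —
a discrimination design *minimizes* it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve

from .propagation import MomentTrajectory

__all__ = ["OverlapResult", "gaussian_product_kernel", "mean_overlap"]

_JITTER = 1e-12


@dataclass(frozen=True)
class OverlapResult:
    """Per-time-point kernel values and their time average."""

    per_time: np.ndarray
    mean_overlap: float
    p: float
    penalty: float = 0.0

    @property
    def penalized(self) -> float:
        return self.mean_overlap + self.penalty


def _regularize(cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, float))
    tr = max(np.trace(cov), 1.0)
    return 0.5 * (cov + cov.T) + _JITTER * tr * np.eye(cov.shape[0])


def _logdet(cov: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite after regularization")
    return ld


def gaussian_product_kernel(mu_a, cov_a, mu_b, cov_b, p: float = 1.0) -> float:
    """Closed-form probability product kernel of two Gaussians.

    General p follows the standard Gaussian product-kernel formula

        k_p = (2 pi)^{(1-2p) d / 2} p^{-d/2} |S|^{1/2}
              |Sigma_a|^{-p/2} |Sigma_b|^{-p/2}
              exp(-p/2 (mu_a' Sa^-1 mu_a + mu_b' Sb^-1 mu_b - m' S m)),

    with S = (Sa^-1 + Sb^-1)^-1 and m = Sa^-1 mu_a + Sb^-1 mu_b.  For p = 1
    this reduces to the density of N(0, Sigma_a + Sigma_b) at mu_a - mu_b.
    Near-singular covariances get an additive jitter of 1e-12 * trace.
    """
    if p <= 0:
        raise ValueError("kernel power p must be > 0")
    mu_a = np.atleast_1d(np.asarray(mu_a, float))
    mu_b = np.atleast_1d(np.asarray(mu_b, float))
    cov_a = _regularize(cov_a)
    cov_b = _regularize(cov_b)
    d = mu_a.size
    if mu_b.size != d or cov_a.shape != (d, d) or cov_b.shape != (d, d):
        raise ValueError("dimension mismatch between means and covariances")

    if p == 1.0:
        # convolution identity: N(mu_a - mu_b; 0, Sigma_a + Sigma_b)
        s = cov_a + cov_b
        diff = mu_a - mu_b
        quad = diff @ solve(s, diff, assume_a="pos")
        return float(np.exp(-0.5 * (d * np.log(2 * np.pi) + _logdet(s) + quad)))

    ia = np.linalg.inv(cov_a)
    ib = np.linalg.inv(cov_b)
    s = np.linalg.inv(ia + ib)
    m = ia @ mu_a + ib @ mu_b
    quad = mu_a @ ia @ mu_a + mu_b @ ib @ mu_b - m @ s @ m
    log_k = (
        0.5 * (1 - 2 * p) * d * np.log(2 * np.pi)
        - 0.5 * d * np.log(p)
        + 0.5 * _logdet(s)
        - 0.5 * p * _logdet(cov_a)
        - 0.5 * p * _logdet(cov_b)
        - 0.5 * p * quad
    )
    return float(np.exp(log_k))


def mean_overlap(traj_a: MomentTrajectory, traj_b: MomentTrajectory,
                 p: float = 1.0, penalty: float = 0.0) -> OverlapResult:
    """Average the product kernel over the shared measurement grid.

    Both trajectories must be on identical grids with the same readout
    dimension.  ``penalty`` (constraint violations, recorded by the design
    objective) is carried through unchanged.
    """
    if traj_a.time_grid.size != traj_b.time_grid.size or \
       not np.allclose(traj_a.time_grid, traj_b.time_grid):
        raise ValueError("moment trajectories must share the measurement grid")
    if traj_a.n_readouts != traj_b.n_readouts:
        raise ValueError("moment trajectories must share the readout dimension")
    per_time = np.array([
        gaussian_product_kernel(traj_a.means[k], traj_a.covs[k],
                                traj_b.means[k], traj_b.covs[k], p)
        for k in range(traj_a.time_grid.size)
    ])
    return OverlapResult(per_time, float(per_time.mean()), p, float(penalty))
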