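"""Parameter uncertainty: normal / log-normal distributions and sigma points.

Parameter spread is usually stated as a coefficient of variation ``eta``
(standard deviation = eta * mean), i.e. covariance diag(eta * E[theta])^2.
Log-normally distributed parameters are handled by converting the natural
(mean, covariance) pair to the moments of the underlying normal, doing all
Gaussian constructions (sigma points, sampling) there, and exponentiating
back, which keeps sigma points and samples strictly positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ParameterDistribution",
    "SigmaPointSet",
    "lognormal_to_normal_moments",
    "normal_to_lognormal_moments",
    "build_sigma_points",
    "sample_parameters",
    "UT_ALPHA", "UT_BETA",
]

#: scaled unscented-transform defaults: alpha = 1, beta = 2 (Gaussian
#: prior), kappa = 3 - n (Julier's fourth-moment heuristic, n + lambda = 3).
#: Note kappa = 3 - n makes the centre mean weight (3-n)/3 negative for
#: n > 3, which is fine for smooth unimodal responses but corrupts moment
#: estimates when sigma points straddle coexisting stable branches; for
#: such systems pass kappa = 0, which keeps every mean weight nonnegative
#: at the price of a wider sqrt(n) point spread (the bundled bistable
#: benchmark does exactly this).  All three constants are config-exposed.
UT_ALPHA = 1.0
UT_BETA = 2.0


def default_kappa(n: int) -> float:
    return 3.0 - n


def _check_psd(cov: np.ndarray, what: str = "cov") -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, float))
    if cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(cov, cov.T, atol=1e-10 * (1 + np.abs(cov).max())):
        raise ValueError(f"{what} must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-12 * max(np.trace(cov), 1.0):
        raise ValueError(f"{what} must be positive semidefinite (min eig {w.min():g})")
    return cov


@dataclass(frozen=True)
class ParameterDistribution:
    """Mean/covariance of the model parameter vector, on a declared scale.

    ``scale='linear'`` means theta ~ N(mean, cov); ``scale='lognormal'``
    means theta is log-normal with the *given* natural-scale mean and
    covariance (the underlying normal moments are derived on demand).
    ``cv_eta``, if given, builds ``cov = diag(eta * mean)^2``.
    """

    mean: np.ndarray
    cov: np.ndarray = None  # type: ignore[assignment]
    scale: Literal["linear", "lognormal"] = "linear"
    cv_eta: float | None = None

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, float))
        object.__setattr__(self, "mean", mean)
        if self.cv_eta is not None:
            if self.cv_eta < 0:
                raise ValueError("cv_eta must be >= 0")
            cov = np.diag((self.cv_eta * mean) ** 2)
        elif self.cov is None:
            raise ValueError("either cov or cv_eta must be given")
        else:
            cov = self.cov
        cov = _check_psd(cov)
        if cov.shape[0] != mean.size:
            raise ValueError("cov dimension must match mean length")
        object.__setattr__(self, "cov", cov)
        if self.scale not in ("linear", "lognormal"):
            raise ValueError("scale must be 'linear' or 'lognormal'")
        if self.scale == "lognormal" and np.any(mean <= 0):
            raise ValueError("log-normal scale requires strictly positive mean")

    @property
    def n_params(self) -> int:
        return self.mean.size

    def normal_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Moments of the Gaussian used for point constructions.

        Identity for linear scale; the underlying-normal moments for
        log-normal scale.
        """
        if self.scale == "linear":
            return self.mean.copy(), self.cov.copy()
        return lognormal_to_normal_moments(self.mean, self.cov)


def lognormal_to_normal_moments(mean, cov) -> tuple[np.ndarray, np.ndarray]:
    """Moments of the normal whose exponential has the given mean and covariance.

    With natural mean m and covariance C:

        Sigma_N[i,j] = ln(1 + C_ij / (m_i m_j)),
        mu_N[i]      = ln m_i - Sigma_N[i,i] / 2.

    Raises for non-positive means.  If the implied normal covariance is not
    PSD (possible for extreme correlation structures) its negative
    eigenvalues are clipped at zero with a warning.
    """
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    if np.any(mean <= 0):
        raise ValueError("log-normal mean must be strictly positive")
    ratio = cov / np.outer(mean, mean)
    if np.any(ratio <= -1):
        raise ValueError("covariance incompatible with a log-normal (1 + C_ij/(m_i m_j) <= 0)")
    cov_n = np.log1p(ratio)
    w, v = np.linalg.eigh(cov_n)
    if w.min() < -1e-12 * max(np.trace(cov_n), 1.0):
        warnings.warn("implied normal covariance not PSD; clipping negative eigenvalues")
        cov_n = (v * np.maximum(w, 0.0)) @ v.T
        cov_n = 0.5 * (cov_n + cov_n.T)
    mu_n = np.log(mean) - 0.5 * np.diag(cov_n)
    return mu_n, cov_n


def normal_to_lognormal_moments(mu_n, cov_n) -> tuple[np.ndarray, np.ndarray]:
    """Natural-scale mean and covariance of exp(N(mu_n, cov_n))."""
    mu_n = np.atleast_1d(np.asarray(mu_n, float))
    cov_n = np.atleast_2d(np.asarray(cov_n, float))
    s2 = np.diag(cov_n)
    mean = np.exp(mu_n + 0.5 * s2)
    cov = np.outer(mean, mean) * np.expm1(cov_n)
    return mean, cov


@dataclass(frozen=True)
class SigmaPointSet:
    """The 2n+1 scaled-UT points with mean and covariance weights.

    Points live in the *natural* parameter space (exponentiated for
    log-normal distributions); weights are shared between scales.
    """

    points: np.ndarray        # [(2n+1), n]
    mean_weights: np.ndarray
    cov_weights: np.ndarray
    ut_params: tuple[float, float, float, float]  # (alpha, beta, kappa, lambda)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def estimate_moments(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Weighted mean and covariance of per-point transformed values.

        ``values`` has shape [(2n+1), d].  The covariance is symmetrized and
        eigenvalue-clipped at zero (negative W0 can produce slightly
        indefinite estimates); clipping is logged.
        """
        values = np.atleast_2d(np.asarray(values, float))
        mean = self.mean_weights @ values
        dev = values - mean
        cov = (dev * self.cov_weights[:, None]).T @ dev
        cov = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(cov)
        if w.min() < 0:
            if w.min() < -1e-10 * max(np.trace(cov), 1.0):
                log.warning("UT covariance clipped: min eigenvalue %g", w.min())
            cov = (v * np.maximum(w, 0.0)) @ v.T
            cov = 0.5 * (cov + cov.T)
        return mean, cov


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor, with one jitter retry on failure."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(np.trace(cov), 1.0)
        log.warning("Cholesky failed; retrying with jitter %g", jitter)
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))


def build_sigma_points(
    dist: ParameterDistribution,
    alpha: float = UT_ALPHA,
    beta: float = UT_BETA,
    kappa: float | None = None,
) -> SigmaPointSet:
    """Construct the 2n+1 scaled unscented-transform sigma points.

    lambda = alpha^2 (n + kappa) - n; points are mu and
    mu +/- sqrt(n + lambda) * (chol Sigma)_i in the Gaussian space, with
    W0^m = lambda/(n+lambda), W0^c = W0^m + 1 - alpha^2 + beta and
    Wi = 1 / (2 (n + lambda)).  For log-normal distributions the
    construction happens in the underlying normal space and the points are
    exponentiated back; the weights are unchanged.
    """
    n = dist.n_params
    if kappa is None:
        kappa = default_kappa(n)
    lam = alpha**2 * (n + kappa) - n
    if n + lam <= 0:
        raise ValueError(f"invalid UT parameters: n + lambda = {n + lam:g} <= 0")
    mu, cov = dist.normal_moments()
    root = _sqrt_psd(cov)
    scale = np.sqrt(n + lam)
    pts = np.empty((2 * n + 1, n))
    pts[0] = mu
    for i in range(n):
        pts[1 + i] = mu + scale * root[:, i]
        pts[1 + n + i] = mu - scale * root[:, i]
    if dist.scale == "lognormal":
        pts = np.exp(pts)
    wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = wm[0] + 1.0 - alpha**2 + beta
    return SigmaPointSet(pts, wm, wc, (alpha, beta, float(kappa), float(lam)))


def sample_parameters(dist: ParameterDistribution, n_samples: int,
                      seed: int | np.random.SeedSequence) -> np.ndarray:
    """Draw reproducible parameter samples on the natural scale.

    Log-normal samples are exponentials of correlated normal draws using the
    converted moments, so their natural-scale mean/covariance converge to
    the distribution's as n grows.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    mu, cov = dist.normal_moments()
    draws = rng.multivariate_normal(mu, cov, size=n_samples, method="cholesky" if
                                    _is_cholesky_safe(cov) else "eigh")
    if dist.scale == "lognormal":
        draws = np.exp(draws)
    return draws


def _is_cholesky_safe(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False
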