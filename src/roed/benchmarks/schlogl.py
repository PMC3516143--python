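"""The Schlögl reaction: a bistable autocatalytic benchmark pair.

The Schlögl model is the canonical trimolecular autocatalytic reaction

    A + 2X <-> 3X   (k1 forward, k2 backward)
    B <-> X         (k3 forward, k4 backward)

whose deterministic rate equation for the concentration x of species X is

    dx/dt = k1 * a * x^2 - k2 * x^3 + k3 * b - k4 * x,

with a, b the (reservoir-buffered) concentrations of A and B.  For suitable
rates the cubic right-hand side has three positive roots — two stable
steady states separated by an unstable one — which is what makes the model
a stress test for local (linearized) uncertainty propagation: a parameter
distribution straddling the separatrix yields a bimodal response that a
single Gaussian centred on the nominal branch badly mis-describes.

The two rival models differ only in the input layer through which the
stimulus u(t) feeds the reservoir of species A:

    model A:  a_eff = a + u               (linear reservoir feed)
    model B:  a_eff = a + u / (1 + u/gamma)   (saturating feed)

At u = 0 the models coincide, so an unstimulated experiment cannot
discriminate them.

The packaged nominal rate set is a normalization chosen so the
unstimulated cubic factors as -(x-1)(x-3)(x-9) (stable steady states at 1
and 9, separatrix at 3) with a wide bistable window; every constant here
is config-overridable.
"""

from __future__ import annotations

import numpy as np

from ..distributions import ParameterDistribution
from ..models import OdeModel, register_model
from ..propagation import ResponseTransform
from ..stimulus import DesignSpace, apply_dwell_constraint, constant_stimulus

__all__ = ["build_schlogl_pair", "schlogl_steady_states", "SCHLOGL_DEFAULTS"]

#: parameter order: (k1, k2, k3, k4, a, b, x0) — four kinetic constants,
#: two reservoir concentrations, and the initial condition, all distributed.
PARAM_NAMES = ("k1", "k2", "k3", "k4", "a", "b", "x0")

#: nominal values (normalized units); k1*a = 13, k3*b = 27, k4 = 39
#: make the unstimulated cubic -(x-1)(x-3)(x-9): stable states at 1 and 9,
#: unstable separatrix at 3, with a wide bistable window (the autocatalytic
#: gain k1*a_eff can move -11%..+21% before a branch disappears)
NOMINAL = np.array([0.13, 1.0, 0.27, 39.0, 100.0, 100.0, 1.0])

#: saturation scale of model B's input layer
GAMMA_B = 40.0

SCHLOGL_DEFAULTS = {
    "eta": 0.1,              # coefficient of variation of the parameter spread
    "noise_sd": 0.1,         # additive measurement noise SD on x
    "u_max": 100.0,          # stimulus bound (reservoir-feed units)
    "horizon": 10.0,         # experiment length (normalized time)
    "n_segments": 5,         # piecewise-constant stimulus segments
    "tau_min": 1.0,          # dwell-time constraint between stimulations
    "measurement_times": np.linspace(1.0, 10.0, 10),
    "initial_stimulus": 0.0,  # the suboptimal starting experiment
    "scale": "lognormal",
    # kappa = 0 keeps all UT mean weights nonnegative; with the default
    # kappa = 3 - n the centre weight is -4/3 at n = 7, which badly corrupts
    # the estimated moments when sigma points land on both stable branches
    "ut_params": {"alpha": 1.0, "beta": 2.0, "kappa": 0.0},
}


def _make_model(name: str, input_layer) -> OdeModel:
    """Scalar Schlögl model with a pluggable input layer a_eff = h(a, u)."""

    def rhs(x, u, th, t):
        k1, k2, k3, k4, a, b, _ = th
        a_eff = input_layer(a, u)
        xx = x[0]
        return np.array([k1 * a_eff * xx**2 - k2 * xx**3 + k3 * b - k4 * xx])

    def rhs_jac_x(x, u, th, t):
        k1, k2, _, k4, a, _, _ = th
        a_eff = input_layer(a, u)
        xx = x[0]
        return np.array([[2 * k1 * a_eff * xx - 3 * k2 * xx**2 - k4]])

    def rhs_jac_theta(x, u, th, t):
        k1, k2, k3, k4, a, b, _ = th
        a_eff = input_layer(a, u)
        xx = x[0]
        # d a_eff / d a = 1 for both packaged layers (u enters additively)
        return np.array([[a_eff * xx**2, -xx**3, b, -xx, k1 * xx**2, k3, 0.0]])

    return OdeModel(
        name=name,
        n_states=1,
        n_params=7,
        n_readouts=1,
        rhs=rhs,
        readout=lambda x, th, t: np.array([x[0]]),
        init=lambda th: np.array([th[6]]),
        rhs_jac_x=rhs_jac_x,
        rhs_jac_theta=rhs_jac_theta,
        readout_jac_x=lambda x, th, t: np.array([[1.0]]),
        readout_jac_theta=lambda x, th, t: np.zeros((1, 7)),
        init_jac_theta=lambda th: np.array([[0.0] * 6 + [1.0]]),
    )


def input_layer_a(a: float, u: float) -> float:
    """Model A: linear reservoir feed."""
    return a + u


def input_layer_b(a: float, u: float, gamma: float = GAMMA_B) -> float:
    """Model B: saturating reservoir feed (same small-u slope as model A)."""
    return a + u / (1.0 + u / gamma)


def build_schlogl_pair(eta: float | None = None, **overrides):
    """Return (model A, model B, defaults dict) for the Schlögl benchmark.

    ``defaults`` carries the parameter distribution (log-normal, CV = eta on
    every parameter including the initial condition), the response
    transform, the dwell-constrained design space, the measurement grid and
    the packaged initial (suboptimal) stimulus.
    """
    cfg = dict(SCHLOGL_DEFAULTS)
    cfg.update(overrides)
    if eta is not None:
        cfg["eta"] = eta
    model_a = _make_model("schlogl_A", input_layer_a)
    model_b = _make_model("schlogl_B", input_layer_b)
    dist = ParameterDistribution(mean=NOMINAL.copy(), cv_eta=cfg["eta"],
                                 scale=cfg["scale"])
    space = apply_dwell_constraint(
        DesignSpace(u_max=cfg["u_max"], horizon=cfg["horizon"],
                    n_segments=cfg["n_segments"]),
        cfg["tau_min"],
    )
    defaults = {
        "dist": dist,
        "transform": ResponseTransform("identity", noise_sd=cfg["noise_sd"]),
        "design_space": space,
        "measurement_times": np.asarray(cfg["measurement_times"], float),
        "initial_stimulus": constant_stimulus(cfg["initial_stimulus"], cfg["horizon"]),
        "param_names": PARAM_NAMES,
        "eta": cfg["eta"],
        "ut_params": dict(cfg["ut_params"]),
    }
    return model_a, model_b, defaults


def schlogl_steady_states(theta: np.ndarray | None = None, u: float = 0.0,
                          input_layer=input_layer_a) -> tuple[np.ndarray, np.ndarray]:
    """Real nonnegative steady states of the cubic and their stability.

    Returns ``(roots, stable)`` with roots sorted ascending and ``stable``
    the boolean sign test f'(root) < 0.
    """
    th = NOMINAL if theta is None else np.asarray(theta, float)
    k1, k2, k3, k4, a, b = th[:6]
    a_eff = input_layer(a, u)
    # -k2 x^3 + k1 a_eff x^2 - k4 x + k3 b
    coeffs = [-k2, k1 * a_eff, -k4, k3 * b]
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    real = real[real >= 0]
    dfdx = -3 * k2 * real**2 + 2 * k1 * a_eff * real - k4
    return real, dfdx < 0


register_model("schlogl_A", lambda: _make_model("schlogl_A", input_layer_a))
register_model("schlogl_B", lambda: _make_model("schlogl_B", input_layer_b))
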