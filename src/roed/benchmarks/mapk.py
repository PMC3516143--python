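"""MAPK signaling-cascade benchmark pair with rival negative feedbacks.

A three-level mitogen-activated protein kinase cascade (kinase MKKK, then
MKK with two phosphorylation sites, then MAPK with two sites), following
the classic Kholodenko ultrasensitivity/feedback cascade model.  Only the
phosphorylated forms are integrated; the unphosphorylated pools follow
from conservation with the total concentration of each species as a model
parameter.

The doubly phosphorylated output MAPK-PP feeds back on the first
activation step.  The two rival hypotheses differ in the functional form
of that negative feedback:

    model A:  v1 is inhibited by 1 + (MAPKPP / KI)        (hyperbolic)
    model B:  v1 is inhibited by 1 + (MAPKPP / KI_B)^2    (cooperative)

The stimulus u(t) is the maximal rate of the first activation step
(growth-factor strength).  Model B's inhibition constant KI_B is a
calibrated packaged constant: it was fitted once (nominal parameters,
least squares on the two log-responses) so that both models produce
matching readouts under the packaged initial constant stimulus — the
starting point at which the models cannot be told apart and a
discrimination design is called for.

Kinetic constants are the classic published cascade values; concentrations
in nM, time in minutes.  Benchmark-protocol settings (noise level,
measurement grid, stimulus bound) are package defaults, all
config-overridable.
"""

from __future__ import annotations

import numpy as np

from ..distributions import ParameterDistribution
from ..models import OdeModel, register_model
from ..propagation import ResponseTransform
from ..stimulus import DesignSpace, constant_stimulus

__all__ = ["build_mapk_pair", "MAPK_DEFAULTS", "KI_B_CALIBRATED"]

#: distributed parameters (log-normal, CV = eta): the catalytic constants of
#: the nine (de)phosphorylation steps plus the feedback inhibition constant
PARAM_NAMES = ("V2", "k3", "k4", "V5", "V6", "k7", "k8", "V9", "V10", "KI")

#: nominal values of the distributed parameters (nM, 1/min units)
NOMINAL = np.array([0.25, 0.025, 0.025, 0.75, 0.75, 0.025, 0.025, 0.5, 0.5, 9.0])

#: fixed Michaelis constants of steps 1..10 (nM)
K_M = {"K1": 10.0, "K2": 8.0, "K3": 15.0, "K4": 15.0, "K5": 15.0,
       "K6": 15.0, "K7": 15.0, "K8": 15.0, "K9": 15.0, "K10": 15.0}

#: total concentrations of the three species (nM); conservation closes the
#: unphosphorylated pools
TOTALS = {"MKKK": 100.0, "MKK": 300.0, "MAPK": 300.0}

#: initial phosphorylated concentrations (MKKK-P, MKK-P, MKK-PP, MAPK-P, MAPK-PP)
X0 = np.array([10.0, 10.0, 10.0, 10.0, 10.0])

#: model B inhibition constant — calibrated so models A and B match under
#: the packaged initial stimulus (see calibrate_ki_b below)
KI_B_CALIBRATED = 8.6490

MAPK_DEFAULTS = {
    "eta": 0.1,
    "noise_sd": 0.1,          # log-scale measurement noise SD
    "u_max": 2.5,             # stimulus bound = nominal maximal activation rate
    "horizon": 100.0,         # minutes
    "n_segments": 20,         # bundled design space: 20 amplitudes, 19 durations
    "tau_min": 0.0,
    "measurement_times": np.linspace(10.0, 100.0, 10),
    "initial_stimulus_level": 2.5,
    "scale": "lognormal",
}


def _make_mapk_model(name: str, feedback_exponent: int) -> OdeModel:
    k1m = K_M["K1"]; k2m = K_M["K2"]; k3m = K_M["K3"]; k4m = K_M["K4"]
    k5m = K_M["K5"]; k6m = K_M["K6"]; k7m = K_M["K7"]; k8m = K_M["K8"]
    k9m = K_M["K9"]; k10m = K_M["K10"]
    tot1, tot2, tot3 = TOTALS["MKKK"], TOTALS["MKK"], TOTALS["MAPK"]
    h = feedback_exponent

    def rhs(x, u, th, t):
        x1p, x2p, x2pp, x3p, x3pp = x
        v2c, k3c, k4c, v5c, v6c, k7c, k8c, v9c, v10c, ki = th
        x1 = tot1 - x1p
        x2 = tot2 - x2p - x2pp
        x3 = tot3 - x3p - x3pp
        fb = 1.0 + (x3pp / ki) ** h
        v1 = u * x1 / (fb * (k1m + x1))
        v2 = v2c * x1p / (k2m + x1p)
        v3 = k3c * x1p * x2 / (k3m + x2)
        v4 = k4c * x1p * x2p / (k4m + x2p)
        v5 = v5c * x2pp / (k5m + x2pp)
        v6 = v6c * x2p / (k6m + x2p)
        v7 = k7c * x2pp * x3 / (k7m + x3)
        v8 = k8c * x2pp * x3p / (k8m + x3p)
        v9 = v9c * x3pp / (k9m + x3pp)
        v10 = v10c * x3p / (k10m + x3p)
        return np.array([
            v1 - v2,
            v3 + v5 - v4 - v6,
            v4 - v5,
            v7 + v9 - v8 - v10,
            v8 - v9,
        ])

    def rhs_jac_x(x, u, th, t):
        x1p, x2p, x2pp, x3p, x3pp = x
        v2c, k3c, k4c, v5c, v6c, k7c, k8c, v9c, v10c, ki = th
        x1 = tot1 - x1p
        x2 = tot2 - x2p - x2pp
        x3 = tot3 - x3p - x3pp
        r = x3pp / ki
        fb = 1.0 + r**h
        v1 = u * x1 / (fb * (k1m + x1))
        dfb_dx3pp = h * r ** (h - 1) / ki
        j = np.zeros((5, 5))
        dv1_dx1p = -u * k1m / (fb * (k1m + x1) ** 2)
        dv1_dx3pp = -v1 * dfb_dx3pp / fb
        dv2_dx1p = v2c * k2m / (k2m + x1p) ** 2
        dv3_dx1p = k3c * x2 / (k3m + x2)
        dv3_dx2 = k3c * x1p * k3m / (k3m + x2) ** 2
        dv4_dx1p = k4c * x2p / (k4m + x2p)
        dv4_dx2p = k4c * x1p * k4m / (k4m + x2p) ** 2
        dv5_dx2pp = v5c * k5m / (k5m + x2pp) ** 2
        dv6_dx2p = v6c * k6m / (k6m + x2p) ** 2
        dv7_dx2pp = k7c * x3 / (k7m + x3)
        dv7_dx3 = k7c * x2pp * k7m / (k7m + x3) ** 2
        dv8_dx2pp = k8c * x3p / (k8m + x3p)
        dv8_dx3p = k8c * x2pp * k8m / (k8m + x3p) ** 2
        dv9_dx3pp = v9c * k9m / (k9m + x3pp) ** 2
        dv10_dx3p = v10c * k10m / (k10m + x3p) ** 2
        # f1 = v1 - v2
        j[0, 0] = dv1_dx1p - dv2_dx1p
        j[0, 4] = dv1_dx3pp
        # f2 = v3 + v5 - v4 - v6 ; x2 depends on x2p, x2pp
        j[1, 0] = dv3_dx1p - dv4_dx1p
        j[1, 1] = -dv3_dx2 - dv4_dx2p - dv6_dx2p
        j[1, 2] = -dv3_dx2 + dv5_dx2pp
        # f3 = v4 - v5
        j[2, 0] = dv4_dx1p
        j[2, 1] = dv4_dx2p
        j[2, 2] = -dv5_dx2pp
        # f4 = v7 + v9 - v8 - v10 ; x3 depends on x3p, x3pp
        j[3, 2] = dv7_dx2pp - dv8_dx2pp
        j[3, 3] = -dv7_dx3 - dv8_dx3p - dv10_dx3p
        j[3, 4] = -dv7_dx3 + dv9_dx3pp
        # f5 = v8 - v9
        j[4, 2] = dv8_dx2pp
        j[4, 3] = dv8_dx3p
        j[4, 4] = -dv9_dx3pp
        return j

    def rhs_jac_theta(x, u, th, t):
        x1p, x2p, x2pp, x3p, x3pp = x
        v2c, k3c, k4c, v5c, v6c, k7c, k8c, v9c, v10c, ki = th
        x1 = tot1 - x1p
        x2 = tot2 - x2p - x2pp
        x3 = tot3 - x3p - x3pp
        r = x3pp / ki
        fb = 1.0 + r**h
        v1 = u * x1 / (fb * (k1m + x1))
        dv1_dki = v1 * h * r**h / (ki * fb)
        g2 = x1p / (k2m + x1p)
        g3 = x1p * x2 / (k3m + x2)
        g4 = x1p * x2p / (k4m + x2p)
        g5 = x2pp / (k5m + x2pp)
        g6 = x2p / (k6m + x2p)
        g7 = x2pp * x3 / (k7m + x3)
        g8 = x2pp * x3p / (k8m + x3p)
        g9 = x3pp / (k9m + x3pp)
        g10 = x3p / (k10m + x3p)
        j = np.zeros((5, 10))
        j[0, 0] = -g2
        j[0, 9] = dv1_dki
        j[1, 1] = g3
        j[1, 2] = -g4
        j[1, 3] = g5
        j[1, 4] = -g6
        j[2, 2] = g4
        j[2, 3] = -g5
        j[3, 5] = g7
        j[3, 6] = -g8
        j[3, 7] = g9
        j[3, 8] = -g10
        j[4, 6] = g8
        j[4, 7] = -g9
        return j

    # readouts: the doubly phosphorylated forms of the two lower levels
    def readout(x, th, t):
        return np.array([x[4], x[2]])

    def readout_jac_x(x, th, t):
        j = np.zeros((2, 5))
        j[0, 4] = 1.0
        j[1, 2] = 1.0
        return j

    return OdeModel(
        name=name,
        n_states=5,
        n_params=10,
        n_readouts=2,
        rhs=rhs,
        readout=readout,
        init=lambda th: X0.copy(),
        rhs_jac_x=rhs_jac_x,
        rhs_jac_theta=rhs_jac_theta,
        readout_jac_x=readout_jac_x,
        readout_jac_theta=lambda x, th, t: np.zeros((2, 10)),
        init_jac_theta=lambda th: np.zeros((5, 10)),
    )


def build_mapk_pair(eta: float | None = None, **overrides):
    """Return (model A, model B, defaults dict) for the MAPK benchmark.

    Model B's nominal KI entry is the calibrated ``KI_B_CALIBRATED`` so the
    pair is indistinguishable under the packaged initial design.
    """
    cfg = dict(MAPK_DEFAULTS)
    cfg.update(overrides)
    if eta is not None:
        cfg["eta"] = eta
    model_a = _make_mapk_model("mapk_A", feedback_exponent=1)
    model_b = _make_mapk_model("mapk_B", feedback_exponent=2)
    nominal_b = NOMINAL.copy()
    nominal_b[9] = cfg.get("ki_b", KI_B_CALIBRATED)
    dist_a = ParameterDistribution(mean=NOMINAL.copy(), cv_eta=cfg["eta"],
                                   scale=cfg["scale"])
    dist_b = ParameterDistribution(mean=nominal_b, cv_eta=cfg["eta"],
                                   scale=cfg["scale"])
    space = DesignSpace(u_max=cfg["u_max"], horizon=cfg["horizon"],
                        n_segments=cfg["n_segments"], dt_min=cfg["tau_min"])
    defaults = {
        "dist_a": dist_a,
        "dist_b": dist_b,
        "transform": ResponseTransform("log", noise_sd=cfg["noise_sd"]),
        "design_space": space,
        "measurement_times": np.asarray(cfg["measurement_times"], float),
        "initial_stimulus": constant_stimulus(cfg["initial_stimulus_level"],
                                              cfg["horizon"]),
        "param_names": PARAM_NAMES,
        "eta": cfg["eta"],
    }
    return model_a, model_b, defaults


def calibrate_ki_b(initial_level: float | None = None,
                   horizon: float | None = None) -> float:
    """Refit model B's inhibition constant to match model A's nominal readouts.

    Minimizes the summed squared difference of the two models'
    log-responses on a dense grid under the initial constant stimulus.
    Used once to produce ``KI_B_CALIBRATED``; exposed for reproducibility.
    """
    from scipy.optimize import minimize_scalar

    from ..models import simulate

    cfg = MAPK_DEFAULTS
    level = cfg["initial_stimulus_level"] if initial_level is None else initial_level
    t_end = cfg["horizon"] if horizon is None else horizon
    grid = np.linspace(1.0, t_end, 40)
    stim = constant_stimulus(level, t_end)
    model_a = _make_mapk_model("mapk_A", 1)
    model_b = _make_mapk_model("mapk_B", 2)
    ya = np.log(simulate(model_a, NOMINAL, stim, grid).readouts)

    def loss(ki_b):
        th = NOMINAL.copy()
        th[9] = ki_b
        yb = np.log(np.maximum(simulate(model_b, th, stim, grid).readouts, 1e-12))
        return float(np.sum((ya - yb) ** 2))

    res = minimize_scalar(loss, bounds=(1.0, 300.0), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


register_model("mapk_A", lambda: _make_mapk_model("mapk_A", 1))
register_model("mapk_B", lambda: _make_mapk_model("mapk_B", 2))
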