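"""Shared toy models and fixtures.

Static parameter->response maps are built as models with zero dynamics and
a parameter-dependent readout evaluated on the single-point grid [0.0], so
no ODE integration is involved and closed-form moments are available.
"""

import numpy as np
import pytest

from roed.models import OdeModel
from roed.stimulus import DesignSpace, StimulusDesign, constant_stimulus


@pytest.fixture
def exp_decay():
    """dx/dt = -theta * x, x0 = 1: x(t) = exp(-theta t)."""
    return OdeModel(
        name="exp_decay", n_states=1, n_params=1, n_readouts=1,
        rhs=lambda x, u, th, t: np.array([-th[0] * x[0]]),
        readout=lambda x, th, t: np.array([x[0]]),
        init=lambda th: np.array([1.0]),
    )


def make_static_map(fun, n_params, n_readouts=1):
    """Model whose readout is fun(theta), with frozen (zero) dynamics."""
    return OdeModel(
        name="static", n_states=1, n_params=n_params, n_readouts=n_readouts,
        rhs=lambda x, u, th, t: np.array([0.0]),
        readout=lambda x, th, t: np.atleast_1d(np.asarray(fun(th), float)),
        init=lambda th: np.array([0.0]),
    )


@pytest.fixture
def static_grid():
    """Measurement grid for static maps: the single point t = 0."""
    return np.array([0.0])


@pytest.fixture
def null_stimulus():
    return constant_stimulus(0.0, 1.0)


@pytest.fixture
def linear_static():
    """y = A theta + b with a 2-readout, 3-parameter map."""
    a_mat = np.array([[1.0, -2.0, 0.5], [0.3, 1.1, -0.7]])
    b_vec = np.array([0.2, -1.0])
    model = make_static_map(lambda th: a_mat @ th + b_vec, 3, 2)
    return model, a_mat, b_vec


@pytest.fixture
def quadratic_static():
    """Scalar y = theta^2."""
    return make_static_map(lambda th: [th[0] ** 2], 1, 1)


@pytest.fixture
def toy_pair():
    """dx/dt = -x + u versus dx/dt = -x + u^2 (parameter-free dynamics)."""

    def make(input_power):
        return OdeModel(
            name=f"toy_u{input_power}", n_states=1, n_params=1, n_readouts=1,
            rhs=lambda x, u, th, t: np.array([-x[0] + u ** input_power]),
            readout=lambda x, th, t: np.array([x[0]]),
            init=lambda th: np.array([0.0]),
        )

    return make(1), make(2)
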