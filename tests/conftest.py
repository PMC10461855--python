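"""Shared fixtures: published parameter sets and tiny closed-form models."""

from dataclasses import dataclass

import numpy as np
import pytest

from homeostat import protocols as P
from homeostat.models import ModelDefinition, _ParamBase


@dataclass(frozen=True)
class LinearParams(_ParamBase):
    """dA/dt = rate - decay*A : closed-form test system."""

    rate: float
    decay: float


def _rhs_linear(t, y, p):
    return np.array([p[0] - p[1] * y[0]])


@dataclass(frozen=True)
class OscParams(_ParamBase):
    """Harmonic oscillator shifted so both components stay positive."""

    omega: float
    offset: float
    voffset: float


def _rhs_harmonic(t, y, p):
    # x oscillates around offset, "velocity" state around voffset
    return np.array([y[1] - p[2], -p[0] ** 2 * (y[0] - p[1])])


@pytest.fixture(scope="session")
def linear_model():
    return ModelDefinition(
        name="linear", species=("A",), param_cls=LinearParams,
        rhs=_rhs_linear, perturbation_param="rate",
        background_param="decay", oscillatory=False,
    )


@pytest.fixture(scope="session")
def harmonic_model():
    return ModelDefinition(
        name="harmonic", species=("x", "v"), param_cls=OscParams,
        rhs=_rhs_harmonic, perturbation_param="omega",
        background_param="offset", oscillatory=True,
    )


@pytest.fixture(scope="session")
def fig5_params():
    return dict(P.FIG5_PARAMS)


@pytest.fixture(scope="session")
def fig9_params():
    return dict(P.FIG9_PARAMS)


@pytest.fixture(scope="session")
def fig11_params():
    return dict(P.FIG11_PARAMS)


@pytest.fixture(scope="session")
def fig14_params():
    return dict(P.FIG14_PARAMS)


@pytest.fixture(scope="session")
def fig16_params():
    return dict(P.FIG16_PARAMS)
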