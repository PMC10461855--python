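"""Retinal intensity-response algebra (Naka-Rushton light adaptation).

The graded response amplitude ``V`` of a retinal cell to a light intensity
``I`` follows the Hill relation

    V = V_max * I**alpha / (I**alpha + sigma**alpha)

with cooperativity ``alpha = 1`` for photoreceptors (rods and cones), where
it reduces to the Michaelis-Menten / Naka-Rushton form.  For a single-pigment
system adapted to a constant background ``I0``, the incremental response to a
further perturbation ``I_pert`` obeys the same hyperbolic law with shifted
parameters:

    sigma_1  = sigma + I0
    V_max,1  = V_max * sigma / (sigma + I0)

an exact algebraic identity of the alpha = 1 equation.  On a logarithmic
intensity axis this family of curves consists of horizontal translates of a
single shape — which is why parallel intensity-response lines at different
backgrounds do *not* by themselves demonstrate any background-compensation
mechanism.

Light intensities are kept in their own namespace (``I0``, ``I_pert``) to
avoid collision with the controller species I1/I2 of the homeostat models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "HillParams",
    "EffectiveParams",
    "hill_response",
    "background_response",
    "incremental_response",
    "effective_params",
    "intensity_response_family",
]


@dataclass(frozen=True)
class HillParams:
    """Intensity-response parameters: amplitude scale, half-saturation, cooperativity."""

    V_max: float
    sigma: float
    alpha: float = 1.0

    def __post_init__(self):
        if not (self.V_max > 0 and self.sigma > 0 and self.alpha > 0):
            raise InvalidParameterError(
                f"V_max, sigma and alpha must be > 0, got "
                f"({self.V_max}, {self.sigma}, {self.alpha})"
            )


@dataclass(frozen=True)
class EffectiveParams:
    """Background-shifted response parameters of the alpha=1 system."""

    V_max_1: float
    sigma_1: float
    I0: float


def _check_intensity(I, name="I"):
    arr = np.asarray(I, dtype=np.float64)
    if np.any(arr < 0):
        raise InvalidParameterError(f"{name} must be >= 0")
    return arr


def _require_alpha1(params: HillParams):
    if params.alpha != 1.0:
        raise InvalidParameterError(
            "the background-shift identity holds for the single-pigment "
            f"alpha=1 case only (got alpha={params.alpha})"
        )


def hill_response(params: HillParams, I):
    """Response amplitude ``V_max * I^alpha / (I^alpha + sigma^alpha)``."""
    I = _check_intensity(I)
    Ia = I ** params.alpha
    return params.V_max * Ia / (Ia + params.sigma ** params.alpha)


def background_response(params: HillParams, I0):
    """Steady response ``V0`` to the background alone (alpha = 1)."""
    _require_alpha1(params)
    I0 = _check_intensity(I0, "I0")
    return params.V_max * I0 / (I0 + params.sigma)


def incremental_response(params: HillParams, I0, I_pert):
    """Incremental response ``V1`` to ``I_pert`` on top of background ``I0``.

    Computed in the factored (shifted-parameter) form

        V1 = V_max * [sigma/(I0+sigma)] * [I_pert/(I0+I_pert+sigma)]

    which equals ``hill_response(I0+I_pert) - background_response(I0)``
    identically.
    """
    _require_alpha1(params)
    I0 = _check_intensity(I0, "I0")
    Ip = _check_intensity(I_pert, "I_pert")
    return (params.V_max * params.sigma / (I0 + params.sigma)
            * Ip / (I0 + Ip + params.sigma))


def effective_params(params: HillParams, I0) -> EffectiveParams:
    """Background-shifted parameters ``(V_max,1, sigma_1)`` for background ``I0``."""
    _require_alpha1(params)
    I0 = float(_check_intensity(I0, "I0"))
    return EffectiveParams(
        V_max_1=params.V_max * params.sigma / (params.sigma + I0),
        sigma_1=params.sigma + I0,
        I0=I0,
    )


def intensity_response_family(V_max: float, sigmas, I_grid=None) -> pd.DataFrame:
    """Tidy table of alpha=1 intensity-response curves, one per sigma.

    Default grid: 400 logarithmic points over [1e-6, 1e2].  Columns
    ``sigma, I, V`` suit linear or logarithmic plotting of either axis.
    """
    if I_grid is None:
        I_grid = np.logspace(-6, 2, 400)
    I_grid = _check_intensity(I_grid)
    frames = []
    for s in sigmas:
        p = HillParams(V_max=V_max, sigma=float(s), alpha=1.0)
        frames.append(pd.DataFrame({
            "sigma": float(s), "I": I_grid, "V": hill_response(p, I_grid),
        }))
    return pd.concat(frames, ignore_index=True)
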