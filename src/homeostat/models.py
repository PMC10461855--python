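"""Reaction networks of the coherent/incoherent-feedback homeostats.

Five mass-action networks are defined, each a negative-feedback homeostat in
which a controlled species ``A`` is held at a set-point by a controller ``E``
(or ``E1``/``E2``), while two further integral controllers ``I1`` (outflow) and
``I2`` (inflow) hold the time average of the controller itself at a set-point.
Integral control is implemented kinetically by zero-order removal of each
controller species (Michaelis constants far below the working concentrations).

The networks differ in how the outer controllers wire back into the ``A``-``E``
signalling axis:

* ``m2_coherent_osc``   — derepression (motif-2) limit-cycle oscillator;
  ``I1``/``I2`` act directly on ``A`` ("coherent" feedback).
* ``m8_coherent_osc``   — motif-8 outflow-control oscillator, also coherent.
* ``m2_firstorder``     — the motif-2 network with all ``A``-removing reactions
  made first-order in ``A``; non-oscillatory.
* ``dual_e``            — two inflow controllers ``E1``/``E2``; only ``E2`` is
  under coherent ``I1``/``I2`` control.
* ``m2_incoherent_osc`` — ``E``, ``I1``, ``I2`` feed back to a precursor ``a``
  of ``A`` instead of ``A`` itself ("incoherent"); frequency homeostasis
  survives but background compensation is lost.

Each network designates one *perturbation* parameter (stepped during an
experiment) and one *background* parameter (held at a constant level alongside
the step).  Rate parameters are in arbitrary units (au) throughout.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, fields
from typing import Callable, Mapping

import numpy as np
from numba import njit

from .errors import InvalidParameterError, InvalidStateError, WindupWarning

__all__ = [
    "M2CoherentParams",
    "M8CoherentParams",
    "M2FirstOrderParams",
    "DualEParams",
    "M2IncoherentParams",
    "ModelDefinition",
    "MODEL_REGISTRY",
    "get_model",
    "rhs_m2_coherent",
    "rhs_m8_coherent",
    "rhs_m2_firstorder",
    "rhs_dual_e",
    "rhs_m2_incoherent",
    "setpoints_m2",
    "setpoints_m8",
    "setpoints_dual_e",
    "setpoints_m2_incoherent",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

class _ParamBase:
    """Shared validation / conversion helpers for the per-model dataclasses."""

    #: names of Michaelis-like constants that must be strictly positive
    _strictly_positive: tuple[str, ...] = ()

    def __post_init__(self):
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{f.name} is not finite: {v!r}")
            if v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        for name in self._strictly_positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(
                    f"Michaelis-like constant {name} must be > 0, got {getattr(self, name)}"
                )
        self._check_setpoint_ordering()

    def _check_setpoint_ordering(self):  # pragma: no cover - overridden
        pass

    def to_vector(self) -> np.ndarray:
        """Parameter vector in declared field order (the RHS kernel layout)."""
        return np.array(dataclasses.astuple(self), dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "_ParamBase":
        return dataclasses.replace(self, **changes)

    @classmethod
    def param_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "_ParamBase":
        unknown = set(d) - set(cls.param_names())
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s) for {cls.__name__}: {sorted(unknown)}"
            )
        return cls(**d)


@dataclass(frozen=True)
class M2CoherentParams(_ParamBase):
    """Rate constants of the motif-2 coherent-feedback oscillator.

    ``k2`` is the perturbation (zero-order removal of A), ``k10`` the constant
    background removal.  ``k7, k8, k13, k16, k17`` are Michaelis constants;
    values far below the species concentrations make the corresponding
    removals zero-order, which implements integral control.
    """

    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    k17: float
    kg: float
    kg3: float

    _strictly_positive = ("k5", "k7", "k8", "k13", "k16", "k17")

    def _check_setpoint_ordering(self):
        # the I2 inflow set-point must lie below the I1 outflow set-point,
        # otherwise the two controllers fight and wind up
        if self.k11 > 0 and self.k15 > 0:
            if self.k14 / self.k15 >= self.k12 / self.k11:
                warnings.warn(
                    "E set-point ordering violated: k14/k15 >= k12/k11 "
                    "(inflow set-point above outflow set-point) — "
                    "I1 and I2 will wind up",
                    WindupWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class M8CoherentParams(_ParamBase):
    """Rate constants of the motif-8 coherent-feedback oscillator.

    ``k1`` is the perturbation (inflow to A), ``k3`` the constant background
    inflow.  ``k10`` is the inhibition constant with which A suppresses the
    production of ``e``.
    """

    k1: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    k17: float
    k18: float
    kg1: float
    kg2: float

    _strictly_positive = ("k5", "k8", "k9", "k10", "k14", "k17", "k18")


@dataclass(frozen=True)
class M2FirstOrderParams(_ParamBase):
    """Motif-2 parameters with every A-removing reaction first-order in A.

    Adds a constant basal inflow ``k1`` (default 0; with the published
    constants the printed steady states balance exactly at ``k1 = 0``).
    The Michaelis constants ``k8`` and ``k17`` of the oscillatory scheme drop
    out of the first-order rate law; they are retained in the schema (with
    their customary 1e-6 defaults) but unused by the kernel.
    """

    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    kg: float
    kg3: float
    k8: float = 1e-6
    k17: float = 1e-6
    k1: float = 0.0

    _strictly_positive = ("k5", "k7", "k13", "k16")

    _check_setpoint_ordering = M2CoherentParams._check_setpoint_ordering


@dataclass(frozen=True)
class DualEParams(_ParamBase):
    """Rate constants of the dual-inflow-controller (E1/E2) scheme.

    ``k2`` is the perturbation, ``k10`` the background (both first-order
    removals of A).  E1 and E2 define set-points ``k6/k4`` and ``k12/k13``
    for A; the E2 set-point must be the lower one so that E2 (the controller
    wired to I1/I2) takes over.
    """

    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    k17: float
    k18: float
    k19: float
    k20: float
    kg: float
    kg3: float

    _strictly_positive = ("k5", "k7", "k14", "k17", "k20")

    def _check_setpoint_ordering(self):
        if self.k4 > 0 and self.k13 > 0:
            if self.k12 / self.k13 >= self.k6 / self.k4:
                warnings.warn(
                    "A set-point ordering violated: k12/k13 >= k6/k4 — "
                    "E2 cannot take over control from E1",
                    WindupWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class M2IncoherentParams(_ParamBase):
    """Rate constants of the incoherent-feedback motif-2 oscillator.

    ``E``, ``I1`` and ``I2`` feed back to the precursor ``a`` rather than to
    ``A``; ``k2`` is the perturbation and ``k10`` the background (first-order
    removals of A).
    """

    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    kg: float
    kg3: float

    _strictly_positive = ("k5", "k7", "k13", "k16")

    _check_setpoint_ordering = M2CoherentParams._check_setpoint_ordering


# --------------------------------------------------------------------------
# right-hand-side kernels (numba-compiled; p follows the dataclass order)
# --------------------------------------------------------------------------

@njit(cache=True)
def _rhs_m2_coherent(t, y, p):
    # p: k2 k3 k4 k5 k6 k7 k8 k9 k10 k11 k12 k13 k14 k15 k16 k17 kg kg3
    A, e, E, I1, I2 = y[0], y[1], y[2], y[3], y[4]
    out = np.empty(5)
    out[0] = (p[17] * I2 + p[1] * p[3] / (p[3] + E)
              - p[16] * A * I1 / (p[15] + A)
              - p[0] * A / (p[6] + A)
              - p[8] * A / (p[6] + A))
    out[1] = p[2] * A - p[7] * e
    out[2] = p[7] * e - p[4] * E / (p[5] + E)
    out[3] = p[9] * E - p[10] * I1 / (p[11] + I1)
    out[4] = p[12] - (p[13] * I2 / (p[14] + I2)) * E
    return out


@njit(cache=True)
def _rhs_m8_coherent(t, y, p):
    # p: k1 k3 k4 k5 k6 k7 k8 k9 k10 k11 k12 k13 k14 k15 k16 k17 k18 kg1 kg2
    A, e, E, I1, I2 = y[0], y[1], y[2], y[3], y[4]
    out = np.empty(5)
    out[0] = (p[0] + p[1]
              - (p[18] * A / (p[16] + A)) * I2
              + p[17] * I1
              - (p[2] * A / (p[3] + A)) * (p[7] / (p[7] + E)))
    out[1] = p[4] * p[8] / (p[8] + A) - p[9] * e
    out[2] = p[9] * e - p[5] * E / (p[6] + E)
    out[3] = p[10] * E - p[11] * I1 / (p[12] + I1)
    out[4] = p[13] - (p[14] * I2 / (p[15] + I2)) * E
    return out


@njit(cache=True)
def _rhs_m2_firstorder(t, y, p):
    # p: k2 k3 k4 k5 k6 k7 k9 k10 k11 k12 k13 k14 k15 k16 kg kg3 k8 k17 k1
    A, e, E, I1, I2 = y[0], y[1], y[2], y[3], y[4]
    out = np.empty(5)
    out[0] = (p[18] + p[15] * I2 + p[1] * p[3] / (p[3] + E)
              - p[14] * A * I1 - p[0] * A - p[7] * A)
    out[1] = p[2] * A - p[6] * e
    out[2] = p[6] * e - p[4] * E / (p[5] + E)
    out[3] = p[8] * E - p[9] * I1 / (p[10] + I1)
    out[4] = p[11] - (p[12] * I2 / (p[13] + I2)) * E
    return out


@njit(cache=True)
def _rhs_dual_e(t, y, p):
    # p: k2 k3 k4 k5 k6 k7 k9 k10 k11 k12 k13 k14 k15 k16 k17 k18 k19 k20 kg kg3
    A, a, E1, E2, I1, I2 = y[0], y[1], y[2], y[3], y[4], y[5]
    out = np.empty(6)
    out[0] = (p[18] * I2 - p[19] * A * I1 - p[0] * A - p[7] * A
              + p[6] * a + p[8] * E2)
    out[1] = p[1] * p[3] / (p[3] + E1) - p[6] * a
    out[2] = p[2] * A - p[4] * E1 / (p[5] + E1)
    out[3] = p[9] - A * (p[10] * E2 / (p[11] + E2))
    out[4] = p[12] - (p[13] * I1 / (p[14] + I1)) * E2
    out[5] = p[15] * E2 - p[16] * I2 / (p[17] + I2)
    return out


@njit(cache=True)
def _rhs_m2_incoherent(t, y, p):
    # p: k2 k3 k4 k5 k6 k7 k9 k10 k11 k12 k13 k14 k15 k16 kg kg3
    A, a, E, I1, I2 = y[0], y[1], y[2], y[3], y[4]
    out = np.empty(5)
    out[0] = p[6] * a - p[0] * A - p[7] * A
    out[1] = (p[15] * I2 + p[1] / (p[3] + E)) * p[3] - p[14] * a * I1 - p[6] * a
    out[2] = p[2] * A - p[4] * E / (p[5] + E)
    out[3] = p[8] * E - p[9] * I1 / (p[10] + I1)
    out[4] = p[11] - (p[12] * I2 / (p[13] + I2)) * E
    return out


# --------------------------------------------------------------------------
# public RHS operations (validated wrappers over the kernels)
# --------------------------------------------------------------------------

def _eval_rhs(kernel, state, params, n):
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (n,):
        raise InvalidStateError(f"state must have shape ({n},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidStateError(f"state contains non-finite values: {y}")
    return kernel(0.0, y, params.to_vector())


def rhs_m2_coherent(state, params: M2CoherentParams) -> np.ndarray:
    """Time derivatives (Ȧ, ė, Ė, İ1, İ2) of the motif-2 coherent oscillator."""
    return _eval_rhs(_rhs_m2_coherent, state, params, 5)


def rhs_m8_coherent(state, params: M8CoherentParams) -> np.ndarray:
    """Time derivatives (Ȧ, ė, Ė, İ1, İ2) of the motif-8 coherent oscillator."""
    return _eval_rhs(_rhs_m8_coherent, state, params, 5)


def rhs_m2_firstorder(state, params: M2FirstOrderParams) -> np.ndarray:
    """Time derivatives of the non-oscillatory first-order motif-2 variant."""
    return _eval_rhs(_rhs_m2_firstorder, state, params, 5)


def rhs_dual_e(state, params: DualEParams) -> np.ndarray:
    """Time derivatives (Ȧ, ȧ, Ė1, Ė2, İ1, İ2) of the dual-inflow-controller scheme."""
    return _eval_rhs(_rhs_dual_e, state, params, 6)


def rhs_m2_incoherent(state, params: M2IncoherentParams) -> np.ndarray:
    """Time derivatives (Ȧ, ȧ, Ė, İ1, İ2) of the incoherent-feedback oscillator."""
    return _eval_rhs(_rhs_m2_incoherent, state, params, 5)


# --------------------------------------------------------------------------
# analytic set-points (zero-order limits of the steady-state conditions)
# --------------------------------------------------------------------------

def _ratio(num, den, what):
    if den == 0:
        raise InvalidParameterError(f"zero denominator in set-point {what}")
    return num / den


def setpoints_m2(params: M2CoherentParams | M2FirstOrderParams) -> dict[str, float]:
    """Set-points of the motif-2 schemes.

    ``A_set = k6/k4`` (enforced on <A> by E), ``E_set_I1 = k12/k11`` (outflow
    controller I1) and ``E_set_I2 = k14/k15`` (inflow controller I2).  For
    cooperating controllers ``E_set_I2 < E_set_I1`` must hold; a violation
    raises :class:`~homeostat.errors.WindupWarning`.
    """
    a_set = _ratio(params.k6, params.k4, "A_set = k6/k4")
    e1 = _ratio(params.k12, params.k11, "E_set_I1 = k12/k11")
    e2 = _ratio(params.k14, params.k15, "E_set_I2 = k14/k15")
    if e2 >= e1:
        warnings.warn(
            f"E_set_I2 ({e2}) >= E_set_I1 ({e1}): controllers will wind up",
            WindupWarning,
            stacklevel=2,
        )
    return {"A_set": a_set, "E_set_I1": e1, "E_set_I2": e2}


def setpoints_m8(params: M8CoherentParams) -> dict[str, float]:
    """Set-points of the motif-8 scheme.

    Only the E set-points are analytic: ``E_set_I1 = k13/k12`` and
    ``E_set_I2 = k15/k16``.  The oscillatory set-point of A itself has no
    closed form (``A_set`` is reported as NaN); the closest analytic statement
    is the long-time harmonic-average limit
    ``<1/(k10+A)> → k7/(k6*k10)``, returned as
    ``inverse_shifted_A_average_prediction``.
    """
    e1 = _ratio(params.k13, params.k12, "E_set_I1 = k13/k12")
    e2 = _ratio(params.k15, params.k16, "E_set_I2 = k15/k16")
    pred = _ratio(params.k7, params.k6 * params.k10, "k7/(k6*k10)")
    return {
        "A_set": math.nan,  # no closed form for the oscillatory average of A
        "E_set_I1": e1,
        "E_set_I2": e2,
        "inverse_shifted_A_average_prediction": pred,
    }


def setpoints_dual_e(params: DualEParams) -> dict[str, float]:
    """Set-points of the dual-inflow-controller scheme.

    ``A_set_E1 = k6/k4`` and ``A_set_E2 = k12/k13`` (E2 must have the lower
    set-point to take over control); the E2 set-points of the outer
    controllers are ``E2_set_I1 = k15/k16`` and ``E2_set_I2 = k19/k18``.
    """
    a1 = _ratio(params.k6, params.k4, "A_set_E1 = k6/k4")
    a2 = _ratio(params.k12, params.k13, "A_set_E2 = k12/k13")
    e_i1 = _ratio(params.k15, params.k16, "E2_set_I1 = k15/k16")
    e_i2 = _ratio(params.k19, params.k18, "E2_set_I2 = k19/k18")
    if a2 >= a1:
        warnings.warn(
            f"A_set_E2 ({a2}) >= A_set_E1 ({a1}): E2 cannot take over control",
            WindupWarning,
            stacklevel=2,
        )
    return {
        "A_set_E1": a1,
        "A_set_E2": a2,
        "E2_set_I1": e_i1,
        "E2_set_I2": e_i2,
    }


def setpoints_m2_incoherent(params: M2IncoherentParams) -> dict[str, float]:
    """Set-points of the incoherent oscillator (same ratios as motif-2)."""
    a_set = _ratio(params.k6, params.k4, "A_set = k6/k4")
    e1 = _ratio(params.k12, params.k11, "E_set_I1 = k12/k11")
    e2 = _ratio(params.k14, params.k15, "E_set_I2 = k14/k15")
    return {"A_set": a_set, "E_set_I1": e1, "E_set_I2": e2}


# --------------------------------------------------------------------------
# model registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDefinition:
    """A named ODE system: state layout, parameter schema and RHS kernel."""

    name: str
    species: tuple[str, ...]
    param_cls: type
    rhs: Callable  # kernel signature (t, y, pvec) -> dy
    perturbation_param: str
    background_param: str
    oscillatory: bool
    setpoints: Callable | None = None

    def __post_init__(self):
        names = self.param_cls.param_names()
        if self.perturbation_param not in names:
            raise InvalidParameterError(
                f"perturbation parameter {self.perturbation_param!r} not in schema"
            )
        if self.background_param not in names:
            raise InvalidParameterError(
                f"background parameter {self.background_param!r} not in schema"
            )
        if self.perturbation_param == self.background_param:
            raise InvalidParameterError(
                "perturbation and background parameters must differ"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def make_params(self, params) -> _ParamBase:
        if isinstance(params, self.param_cls):
            return params
        if isinstance(params, Mapping):
            return self.param_cls.from_dict(params)
        raise InvalidParameterError(
            f"cannot build {self.param_cls.__name__} from {type(params).__name__}"
        )

    def pack(self, params) -> np.ndarray:
        return self.make_params(params).to_vector()

    def validate_state(self, state) -> np.ndarray:
        y = np.asarray(state, dtype=np.float64)
        if y.shape != (self.n_species,):
            raise InvalidStateError(
                f"{self.name}: state must have shape ({self.n_species},), got {y.shape}"
            )
        if not np.all(np.isfinite(y)):
            raise InvalidStateError(f"{self.name}: non-finite state {y}")
        if np.any(y < 0):
            raise InvalidStateError(f"{self.name}: negative concentrations {y}")
        return y


MODEL_REGISTRY: dict[str, ModelDefinition] = {
    m.name: m
    for m in (
        ModelDefinition(
            name="m2_coherent_osc",
            species=("A", "e", "E", "I1", "I2"),
            param_cls=M2CoherentParams,
            rhs=_rhs_m2_coherent,
            perturbation_param="k2",
            background_param="k10",
            oscillatory=True,
            setpoints=setpoints_m2,
        ),
        ModelDefinition(
            name="m8_coherent_osc",
            species=("A", "e", "E", "I1", "I2"),
            param_cls=M8CoherentParams,
            rhs=_rhs_m8_coherent,
            perturbation_param="k1",
            background_param="k3",
            oscillatory=True,
            setpoints=setpoints_m8,
        ),
        ModelDefinition(
            name="m2_firstorder",
            species=("A", "e", "E", "I1", "I2"),
            param_cls=M2FirstOrderParams,
            rhs=_rhs_m2_firstorder,
            perturbation_param="k2",
            background_param="k10",
            oscillatory=False,
            setpoints=setpoints_m2,
        ),
        ModelDefinition(
            name="dual_e",
            species=("A", "a", "E1", "E2", "I1", "I2"),
            param_cls=DualEParams,
            rhs=_rhs_dual_e,
            perturbation_param="k2",
            background_param="k10",
            oscillatory=False,
            setpoints=setpoints_dual_e,
        ),
        ModelDefinition(
            name="m2_incoherent_osc",
            species=("A", "a", "E", "I1", "I2"),
            param_cls=M2IncoherentParams,
            rhs=_rhs_m2_incoherent,
            perturbation_param="k2",
            background_param="k10",
            oscillatory=True,
            setpoints=setpoints_m2_incoherent,
        ),
    )
}


def get_model(name: str) -> ModelDefinition:
    """Look up a model by registry name."""
    from .errors import ConfigError

    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
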