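"""Model library: rate laws, set-points, validation, registry."""

import warnings

import numpy as np
import pytest

import homeostat as h
from homeostat import protocols as P
from homeostat.errors import (
    InvalidParameterError,
    InvalidStateError,
    WindupWarning,
)
from homeostat.models import MODEL_REGISTRY, get_model

# ---------------------------------------------------------------------------
# independent term-by-term oracles: each rate law re-written as an explicit
# list of signed reaction fluxes, evaluated without the compiled kernels
# ---------------------------------------------------------------------------


def _oracle_m2_coherent(s, p):
    A, e, E, I1, I2 = s
    dA = (+ p["kg3"] * I2
          + p["k3"] * p["k5"] / (p["k5"] + E)
          - p["kg"] * A * I1 / (p["k17"] + A)
          - p["k2"] * A / (p["k8"] + A)
          - p["k10"] * A / (p["k8"] + A))
    de = p["k4"] * A - p["k9"] * e
    dE = p["k9"] * e - p["k6"] * E / (p["k7"] + E)
    dI1 = p["k11"] * E - p["k12"] * I1 / (p["k13"] + I1)
    dI2 = p["k14"] - p["k15"] * I2 / (p["k16"] + I2) * E
    return np.array([dA, de, dE, dI1, dI2])


def _oracle_m8_coherent(s, p):
    A, e, E, I1, I2 = s
    dA = (p["k1"] + p["k3"]
          - p["kg2"] * A / (p["k18"] + A) * I2
          + p["kg1"] * I1
          - p["k4"] * A / (p["k5"] + A) * p["k9"] / (p["k9"] + E))
    de = p["k6"] * p["k10"] / (p["k10"] + A) - p["k11"] * e
    dE = p["k11"] * e - p["k7"] * E / (p["k8"] + E)
    dI1 = p["k12"] * E - p["k13"] * I1 / (p["k14"] + I1)
    dI2 = p["k15"] - p["k16"] * I2 / (p["k17"] + I2) * E
    return np.array([dA, de, dE, dI1, dI2])


def _oracle_m2_firstorder(s, p):
    A, e, E, I1, I2 = s
    dA = (p.get("k1", 0.0) + p["kg3"] * I2
          + p["k3"] * p["k5"] / (p["k5"] + E)
          - p["kg"] * A * I1 - p["k2"] * A - p["k10"] * A)
    de = p["k4"] * A - p["k9"] * e
    dE = p["k9"] * e - p["k6"] * E / (p["k7"] + E)
    dI1 = p["k11"] * E - p["k12"] * I1 / (p["k13"] + I1)
    dI2 = p["k14"] - p["k15"] * I2 / (p["k16"] + I2) * E
    return np.array([dA, de, dE, dI1, dI2])


def _oracle_dual_e(s, p):
    A, a, E1, E2, I1, I2 = s
    dA = (p["kg"] * I2 - p["kg3"] * A * I1 - p["k2"] * A - p["k10"] * A
          + p["k9"] * a + p["k11"] * E2)
    da = p["k3"] * p["k5"] / (p["k5"] + E1) - p["k9"] * a
    dE1 = p["k4"] * A - p["k6"] * E1 / (p["k7"] + E1)
    dE2 = p["k12"] - A * p["k13"] * E2 / (p["k14"] + E2)
    dI1 = p["k15"] - p["k16"] * I1 / (p["k17"] + I1) * E2
    dI2 = p["k18"] * E2 - p["k19"] * I2 / (p["k20"] + I2)
    return np.array([dA, da, dE1, dE2, dI1, dI2])


def _oracle_m2_incoherent(s, p):
    A, a, E, I1, I2 = s
    dA = p["k9"] * a - p["k2"] * A - p["k10"] * A
    da = ((p["kg3"] * I2 + p["k3"] / (p["k5"] + E)) * p["k5"]
          - p["kg"] * a * I1 - p["k9"] * a)
    dE = p["k4"] * A - p["k6"] * E / (p["k7"] + E)
    dI1 = p["k11"] * E - p["k12"] * I1 / (p["k13"] + I1)
    dI2 = p["k14"] - p["k15"] * I2 / (p["k16"] + I2) * E
    return np.array([dA, da, dE, dI1, dI2])


_ORACLES = {
    "m2_coherent_osc": _oracle_m2_coherent,
    "m8_coherent_osc": _oracle_m8_coherent,
    "m2_firstorder": _oracle_m2_firstorder,
    "dual_e": _oracle_dual_e,
    "m2_incoherent_osc": _oracle_m2_incoherent,
}

_RHS_OPS = {
    "m2_coherent_osc": h.rhs_m2_coherent,
    "m8_coherent_osc": h.rhs_m8_coherent,
    "m2_firstorder": h.rhs_m2_firstorder,
    "dual_e": h.rhs_dual_e,
    "m2_incoherent_osc": h.rhs_m2_incoherent,
}


def _random_params(model, rng):
    names = model.param_cls.param_names()
    vals = {}
    for n in names:
        vals[n] = 10.0 ** rng.uniform(-3, 2)
    return vals


@pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
def test_rhs_matches_term_enumeration_oracle(name):
    """Compiled rate laws equal an independent signed-flux enumeration."""
    rng = np.random.default_rng(20230828)
    model = get_model(name)
    op = _RHS_OPS[name]
    oracle = _ORACLES[name]
    for _ in range(100):
        pdict = _random_params(model, rng)
        state = 10.0 ** rng.uniform(-4, 3, size=model.n_species)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WindupWarning)
            params = model.make_params(pdict)
        got = op(state, params)
        want = oracle(state, pdict)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=0)


@pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
def test_rhs_nonnegativity_at_zero_species(name):
    """A species at zero never gets a negative net derivative (no unphysical
    outflow), except through unconditional zero-order sinks which these
    networks do not place on any species lacking a matching source."""
    rng = np.random.default_rng(7)
    model = get_model(name)
    op = _RHS_OPS[name]
    for _ in range(25):
        pdict = _random_params(model, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", WindupWarning)
            params = model.make_params(pdict)
        for j, sp in enumerate(model.species):
            if name in ("m2_coherent_osc", "m8_coherent_osc") and sp == "I2":
                # I2 removal is zero-order in I2 only through the saturating
                # factor I2/(k16+I2), which vanishes at I2=0: still safe
                pass
            state = 10.0 ** rng.uniform(-2, 2, size=model.n_species)
            state[j] = 0.0
            dy = op(state, params)
            assert dy[j] >= -1e-12, (sp, dy[j], pdict)


class TestRhsPublishedExamples:
    """Hand-substitution checks at published parameter values."""

    def test_m2_inflow_dominates_at_unit_state(self, fig5_params):
        p = h.M2CoherentParams(**fig5_params)
        dy = h.rhs_m2_coherent([1.0, 0.0, 0.0, 0.0, 0.0], p)
        # derepression fully open (E=0) gives k3 = 100; the only removal is
        # the k2 term 1/(1e-6+1)
        assert dy[0] == pytest.approx(100.0 - 1.0 / (1e-6 + 1.0), rel=1e-12)
        assert dy[1] == pytest.approx(1.0)          # k4*A
        assert dy[2] == pytest.approx(0.0)          # no e yet
        assert dy[4] == pytest.approx(4.99)         # I2 source k14

    def test_m2_e_production_removal_balance(self, fig5_params):
        p = h.M2CoherentParams(**{**fig5_params, "k4": 1.0, "k9": 20.0})
        dy = h.rhs_m2_coherent([2.0, 0.1, 1.0, 1.0, 1.0], p)
        assert dy[1] == pytest.approx(2.0 - 20.0 * 0.1, abs=1e-14)

    def test_m2_all_zero_state_with_zero_sources(self, fig5_params):
        p = h.M2CoherentParams(**{**fig5_params, "k3": 0.0, "k14": 0.0})
        dy = h.rhs_m2_coherent(np.zeros(5), p)
        np.testing.assert_allclose(dy, 0.0, atol=1e-15)

    def test_m8_pure_inflow_at_zero_state(self, fig9_params):
        p = h.M8CoherentParams(**{**fig9_params, "k1": 1.0, "k3": 0.0})
        dy = h.rhs_m8_coherent(np.zeros(5), p)
        assert dy[0] == pytest.approx(1.0)

    def test_m8_i2_zero_order_balance(self, fig9_params):
        p = h.M8CoherentParams(**{**fig9_params, "k15": 50.0, "k16": 1.0,
                                  "k17": 1e-6})
        # I2 >> k17 saturates the removal: dI2 = k15 - k16*E = 50 - 50 = 0
        dy = h.rhs_m8_coherent([1.0, 1.0, 50.0, 1.0, 1e4], p)
        assert dy[4] == pytest.approx(0.0, abs=1e-7)

    def test_firstorder_printed_steady_state_balances(self, fig11_params):
        p = h.M2FirstOrderParams(**fig11_params)
        state = (2.0, 1.0, 100.0, 2.5684e3, 2.8492e4)
        dy = h.rhs_m2_firstorder(state, p)
        # largest individual flux is ~53 au/time; the printed state must
        # balance to printing precision
        assert np.max(np.abs(dy)) < 1e-3 * 53.0

    def test_firstorder_step_reduces_a(self, fig11_params):
        p = h.M2FirstOrderParams(**fig11_params)
        state = (2.0, 1.0, 100.0, 2.5684e3, 2.8492e4)
        base = h.rhs_m2_firstorder(state, p)[0]
        doubled = h.rhs_m2_firstorder(state, p.replace(k2=2.0))[0]
        assert doubled == pytest.approx(base - 2.0)  # extra outflow k2*A

    def test_firstorder_basal_inflow_only(self, fig11_params):
        zeroed = {k: 0.0 for k in fig11_params}
        zeroed.update(k5=1.0, k7=1.0, k13=1.0, k16=1.0, k1=5.0)
        p = h.M2FirstOrderParams(**zeroed)
        dy = h.rhs_m2_firstorder(np.zeros(5), p)
        assert dy[0] == pytest.approx(5.0)

    def test_dual_e2_balance_at_set_point(self, fig14_params):
        p = h.DualEParams(**fig14_params)
        # A = A_set_E2 = 2 with E2 >> k14: dE2 = k12 - A*k13 = 200 - 200
        dy = h.rhs_dual_e([2.0, 0.0, 0.0, 100.0, 0.0, 0.0], p)
        assert dy[3] == pytest.approx(0.0, abs=1e-4)

    def test_dual_full_derepression_inflow(self, fig14_params):
        p = h.DualEParams(**fig14_params)
        dy = h.rhs_dual_e([0.0, 0.0, 0.0, 0.0, 0.0, 0.0], p)
        # da at E1=0: k3*k5/(k5+0) = k3 = 2.5e3
        assert dy[1] == pytest.approx(2.5e3)

    def test_incoherent_a_balance(self, fig16_params):
        p = h.M2IncoherentParams(**{**fig16_params, "k9": 2.0, "k2": 1.0,
                                    "k10": 0.0})
        dy = h.rhs_m2_incoherent([2.0, 1.0, 1.0, 1.0, 1.0], p)
        assert dy[0] == pytest.approx(2.0 * 1.0 - 1.0 * 2.0, abs=1e-14)

    def test_incoherent_precursor_inflow_grouping(self, fig16_params):
        p = h.M2IncoherentParams(**fig16_params)
        s = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        dy = h.rhs_m2_incoherent(s, p)
        # (kg3*I2 + k3/(k5+E))*k5 with E=0: kg3*I2*k5 + k3
        want = (p.kg3 * 10.0 + p.k3 / p.k5) * p.k5
        assert dy[1] == pytest.approx(want, rel=1e-12)


class TestSetpoints:
    def test_m2_published_values(self, fig5_params):
        sp = h.setpoints_m2(h.M2CoherentParams(**fig5_params))
        assert sp["A_set"] == pytest.approx(2.0)
        assert sp["E_set_I1"] == pytest.approx(5.0)
        assert sp["E_set_I2"] == pytest.approx(4.99)

    def test_m2_trivial_ratios(self, fig5_params):
        p = h.M2CoherentParams(**{**fig5_params, "k6": 1.0, "k4": 1.0,
                                  "k12": 1.0, "k11": 1.0, "k14": 0.5,
                                  "k15": 1.0})
        sp = h.setpoints_m2(p)
        assert (sp["A_set"], sp["E_set_I1"], sp["E_set_I2"]) == (1.0, 1.0, 0.5)

    def test_m2_windup_warning(self, fig5_params):
        with pytest.warns(WindupWarning):
            h.setpoints_m2(h.M2CoherentParams(
                **{**fig5_params, "k14": 6.0}))  # E_set_I2 = 6 > 5

    def test_m8_values_and_no_closed_form_flag(self, fig9_params):
        sp = h.setpoints_m8(h.M8CoherentParams(**fig9_params))
        assert sp["E_set_I1"] == pytest.approx(10.0)
        assert sp["E_set_I2"] == pytest.approx(50.0)
        assert np.isnan(sp["A_set"])
        assert sp["inverse_shifted_A_average_prediction"] == pytest.approx(
            fig9_params["k7"] / (fig9_params["k6"] * fig9_params["k10"]))

    def test_m8_equal_ratio_setpoints(self, fig9_params):
        p = h.M8CoherentParams(**{**fig9_params, "k13": 5.0, "k12": 5.0,
                                  "k15": 1.0, "k16": 1.0})
        sp = h.setpoints_m8(p)
        assert sp["E_set_I1"] == 1.0 and sp["E_set_I2"] == 1.0

    def test_dual_e_published_values(self, fig14_params):
        sp = h.setpoints_dual_e(h.DualEParams(**fig14_params))
        assert sp["A_set_E1"] == pytest.approx(2.1)
        assert sp["A_set_E2"] == pytest.approx(2.0)
        assert sp["E2_set_I1"] == pytest.approx(100.0)
        assert sp["E2_set_I2"] == pytest.approx(99.99)

    def test_dual_e_ordering_warning(self, fig14_params):
        with pytest.warns(WindupWarning):
            h.setpoints_dual_e(h.DualEParams(
                **{**fig14_params, "k12": 300.0}))  # A_set_E2 = 3 > 2.1

    def test_zero_denominator_raises(self, fig5_params):
        p = h.M2CoherentParams(**{**fig5_params, "k4": 0.0})
        with pytest.raises(InvalidParameterError):
            h.setpoints_m2(p)

    @pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
    def test_setpoint_residuals_vanish_in_zero_order_limit(self, name):
        """Plugging each analytic set-point back into its zero-order
        steady-state condition yields residual exactly 0."""
        presets = {
            "m2_coherent_osc": P.FIG5_PARAMS,
            "m8_coherent_osc": P.FIG9_PARAMS,
            "m2_firstorder": P.FIG11_PARAMS,
            "dual_e": P.FIG14_PARAMS,
            "m2_incoherent_osc": P.FIG16_PARAMS,
        }
        model = get_model(name)
        params = model.make_params(dict(presets[name]))
        sp = model.setpoints(params)
        zero = pytest.approx(0.0, abs=1e-12)
        if name in ("m2_coherent_osc", "m2_firstorder", "m2_incoherent_osc"):
            assert params.k4 * sp["A_set"] - params.k6 == zero
            assert params.k11 * sp["E_set_I1"] - params.k12 == zero
            assert params.k14 - params.k15 * sp["E_set_I2"] == zero
        elif name == "m8_coherent_osc":
            assert params.k12 * sp["E_set_I1"] - params.k13 == zero
            assert params.k15 - params.k16 * sp["E_set_I2"] == zero
        else:  # dual_e
            assert params.k4 * sp["A_set_E1"] - params.k6 == zero
            assert params.k12 - sp["A_set_E2"] * params.k13 == zero
            assert params.k15 - params.k16 * sp["E2_set_I1"] == zero
            assert params.k18 * sp["E2_set_I2"] - params.k19 == zero


class TestValidationAndRegistry:
    def test_registry_names(self):
        assert set(MODEL_REGISTRY) == {
            "m2_coherent_osc", "m8_coherent_osc", "m2_firstorder",
            "dual_e", "m2_incoherent_osc",
        }

    @pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
    def test_perturbation_and_background_distinct(self, name):
        m = get_model(name)
        assert m.perturbation_param != m.background_param
        names = m.param_cls.param_names()
        assert m.perturbation_param in names
        assert m.background_param in names

    def test_unknown_model(self):
        with pytest.raises(Exception, match="unknown model"):
            get_model("m3_wishful")

    def test_negative_rate_rejected(self, fig5_params):
        with pytest.raises(InvalidParameterError):
            h.M2CoherentParams(**{**fig5_params, "k3": -1.0})

    def test_zero_michaelis_rejected(self, fig5_params):
        with pytest.raises(InvalidParameterError):
            h.M2CoherentParams(**{**fig5_params, "k7": 0.0})

    def test_nonfinite_param_rejected(self, fig5_params):
        with pytest.raises(InvalidParameterError):
            h.M2CoherentParams(**{**fig5_params, "k3": float("nan")})

    def test_unknown_param_key_rejected(self, fig5_params):
        with pytest.raises(InvalidParameterError, match="unknown parameter"):
            h.M2CoherentParams.from_dict({**fig5_params, "k99": 1.0})

    def test_nonfinite_state_rejected(self, fig5_params):
        p = h.M2CoherentParams(**fig5_params)
        with pytest.raises(InvalidStateError):
            h.rhs_m2_coherent([np.inf, 0, 0, 0, 0], p)

    def test_wrong_state_shape_rejected(self, fig5_params):
        p = h.M2CoherentParams(**fig5_params)
        with pytest.raises(InvalidStateError):
            h.rhs_m2_coherent([1.0, 2.0], p)

    def test_param_roundtrip_dict(self, fig9_params):
        p = h.M8CoherentParams(**fig9_params)
        assert h.M8CoherentParams.from_dict(p.to_dict()) == p
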