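import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exosim as ex
from exosim.abeta import (
    ABETA_FIELDS,
    AbetaAstrocyteState,
    AbetaConfig,
    abeta_fluxes,
    abeta_rhs,
    astro_feedback_current,
    make_abeta_rhs,
    make_coupled_rhs,
)
from exosim.neuron import NEURON_FIELDS, NeuronState, make_neuron_rhs
from exosim.protocol import Pulse, StimulusProtocol

conc = st.floats(min_value=1e-4, max_value=10.0)


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def _H(x, K, n):
    return x**n / (x**n + K**n)


def _oracle_abeta_rhs(y, v, l, p):
    """Independent evaluation on the per-second base, then rescaled to ms."""
    Cc, Cr, Pc, mT, hTf, hTs, mL, mN, mR, hR = y
    dv = v - 65.0
    I_T = 0.06 * mT * (hTf + 0.04 * hTs) * dv
    I_L = 3.5 * mL * (0.00045 / (0.00045 + Cc / 1000)) * dv
    I_N = 0.39 * mN * (0.0001 / (0.0001 + Cc / 1000)) * dv
    I_R = 0.2225 * mR * hR * dv
    J_V = -(I_T + (1 + l) * I_L + I_N + I_R) * 1e-15 / (2 * 96485.0 * 3.49e-13) * 1e6
    J_CICR = 4 * 10 * _H(0.15, Cc, 2.02) * _H(Cc, 0.15, 2.02) * _H(Pc, 0.1, 2.2) * (Cr - Cc)
    J_SERCA = 15 * _H(Cc, 0.1, 2)
    J_RyR = (0.013 + 0.18 * _H(Cc, 0.13 + l, 3)) * (Cr - Cc)
    J_r = 0.01 * (Cr - Cc)
    J_in = 0.003 + 0.02 * Pc + 1.0 * l**3.5
    J_pm = 4.2 * _H(Cc, 1.5, 2)
    J_PLC = (1 + l) * 0.05 * _H(Cc, 0.3, 2)
    dCc = (J_V + J_in + J_RyR + J_CICR + J_r - J_SERCA - J_pm) / 1000.0
    dCr = (J_SERCA - J_CICR - J_RyR - J_r) / 1000.0
    dPc = (J_PLC - 0.08 * Pc) / 1000.0
    dmT = (_sig((v + 63.5) / 1.5) - mT) / (65 * math.exp(-(((v + 68) / 6) ** 2)) + 12)
    hT = _sig(-(v + 76.2) / 3)
    dhTf = (hT - hTf) / (50 * math.exp(-(((v + 72) / 10) ** 2)) + 10)
    dhTs = (hT - hTs) / (400 * math.exp(-(((v + 100) / 10) ** 2)) + 400)
    dmL = (_sig((v + 50) / 3) - mL) / (18 * math.exp(-(((v + 45) / 20) ** 2)) + 1.5)
    dmN = (_sig((v + 45) / 7) - mN) / (18 * math.exp(-(((v + 70) / 25) ** 2)) + 0.3)
    dmR = (_sig((v + 10) / 10) - mR) / (0.1 * math.exp(-(((v + 62) / 13) ** 2)) + 0.05)
    dhR = (_sig(-(v + 48) / 5) - hR) / (0.5 * math.exp(-(((v + 55.6) / 18) ** 2)) + 0.5)
    return [dCc, dCr, dPc, dmT, dhTf, dhTs, dmL, dmN, dmR, dhR]


class TestFluxes:
    def test_ryr_zero_gradient(self, p):
        s = AbetaAstrocyteState(C_c=0.5, C_r=0.5)
        J = abeta_fluxes(s, AbetaConfig(l=0.4), p)
        assert J["J_RyR"] == pytest.approx(0.0, abs=1e-15)
        assert J["J_r"] == 0.0

    def test_serca_half_saturation(self, p):
        s = AbetaAstrocyteState(C_c=0.1)
        J = abeta_fluxes(s, AbetaConfig(), p)
        assert J["J_SERCA"] == pytest.approx(7.5)

    def test_membrane_leak_baseline(self, p):
        s = AbetaAstrocyteState(P_c=0.1)
        J = abeta_fluxes(s, AbetaConfig(l=0.0), p)
        assert J["J_in"] == pytest.approx(0.005)

    def test_canonical_params_scale_fluxes(self, p, pc):
        s = AbetaAstrocyteState()
        a = abeta_fluxes(s, AbetaConfig(), p)
        b = abeta_fluxes(s, AbetaConfig(), pc)
        for k in a:
            assert b[k] == pytest.approx(a[k] / 1000.0, rel=1e-12), k

    @given(conc, conc, conc, st.floats(min_value=0, max_value=1))
    @settings(max_examples=100)
    def test_flux_sign_invariants(self, Cc, Cr, Pc, l):
        p = ex.default_parameters()
        s = AbetaAstrocyteState(C_c=Cc, C_r=Cr, P_c=Pc)
        J = abeta_fluxes(s, AbetaConfig(l=l), p)
        assert J["J_pm"] >= 0
        assert J["J_SERCA"] >= 0
        assert J["J_in"] >= p.a1


class TestAbetaRhs:
    def test_matches_independent_oracle_at_printed_ic(self, p):
        y = list(AbetaAstrocyteState.at_voltage(-70.0).to_array())
        rhs = make_abeta_rhs(p, AbetaConfig.from_params(p, l=0.4), v_of_t=-70.0)
        assert rhs(0.0, y) == pytest.approx(_oracle_abeta_rhs(y, -70.0, 0.4, p), rel=1e-10)

    def test_oracle_at_depolarised_state(self, p):
        y = [0.25, 3.0, 0.4, 0.5, 0.1, 0.1, 0.6, 0.4, 0.3, 0.7]
        rhs = make_abeta_rhs(p, AbetaConfig.from_params(p, l=1.0), v_of_t=-20.0)
        assert rhs(0.0, y) == pytest.approx(_oracle_abeta_rhs(y, -20.0, 1.0, p), rel=1e-10)

    @given(conc, conc, conc)
    @settings(max_examples=50)
    def test_er_cytosol_exchange_cancels(self, Cc, Cr, Pc):
        # dCc + dCr equals the membrane terms alone (ER exchange cancels)
        p = ex.default_parameters()
        cfg = AbetaConfig.from_params(p, l=0.4)
        s = AbetaAstrocyteState(C_c=Cc, C_r=Cr, P_c=Pc)
        rhs = make_abeta_rhs(p, cfg, v_of_t=-70.0)
        y = list(s.to_array())
        d = dict(zip(ABETA_FIELDS, rhs(0.0, y)))
        J = abeta_fluxes(s, cfg, p.canonical())
        lhs = d["C_c"] + d["C_r"]
        rhs_val = J["J_VGCC"] + J["J_in"] - J["J_pm"]
        assert lhs == pytest.approx(rhs_val, rel=1e-9, abs=1e-15)

    def test_autonomous_fixed_point_exists(self, p):
        from scipy.optimize import fsolve

        cfg = AbetaConfig.from_params(p, l=0.0)
        rhs = make_abeta_rhs(p, cfg, v_of_t=-70.0)
        y0 = AbetaAstrocyteState.at_voltage(-70.0).to_array()
        root, info, ier, _ = fsolve(lambda y: rhs(0.0, y), y0, full_output=True)
        assert ier == 1
        assert 0.0 < root[0] < 1.0  # C_c in (0, 1) uM

    def test_validated_wrapper(self, p):
        s = AbetaAstrocyteState()
        d = abeta_rhs(s, 0.0, AbetaConfig(), p)
        assert set(d) == set(ABETA_FIELDS)


class TestFeedbackCurrent:
    def test_off_below_threshold(self, p):
        assert astro_feedback_current(0.1, p) == 0.0

    def test_zero_at_log_boundary(self, p):
        assert astro_feedback_current(0.19769, p) == pytest.approx(0.0, abs=1e-10)

    def test_direct_value(self, p):
        # y = 1000*0.2 - 196.69 = 3.31
        assert astro_feedback_current(0.2, p) == pytest.approx(2.11 * math.log(3.31), rel=1e-12)
        assert astro_feedback_current(0.2, p) == pytest.approx(2.526, abs=5e-3)

    def test_literal_heaviside_admits_negative_branch(self, p):
        Cc = 0.1972  # 0 < y < 1
        assert astro_feedback_current(Cc, p) == 0.0
        assert astro_feedback_current(Cc, p, literal_heaviside=True) < 0.0

    def test_continuous_at_threshold(self, p):
        eps = 1e-7
        assert astro_feedback_current(0.19769 + eps, p) < 1e-3


class TestCoupled:
    def test_reduces_to_uncoupled_neuron_without_feedback(self, p):
        proto = StimulusProtocol(pulses=(Pulse(0.0, 50.0, 20.0),))
        cfg = AbetaConfig.from_params(p, l=0.4)
        joint = make_coupled_rhs(p, proto, cfg, feedback=False)
        solo = make_neuron_rhs(p, proto)
        yn = list(NeuronState().to_array())
        ya = list(AbetaAstrocyteState.at_voltage(-65.0).to_array())
        dj = joint(1.0, yn + ya)
        assert dj[: len(NEURON_FIELDS)] == pytest.approx(solo(1.0, yn), rel=1e-12)

    def test_joint_derivative_composition(self, p):
        proto = StimulusProtocol(pulses=(Pulse(0.0, 50.0, 20.0),))
        cfg = AbetaConfig.from_params(p, l=0.4)
        joint = make_coupled_rhs(p, proto, cfg)
        yn = list(NeuronState(v_m=-60.0).to_array())
        Cc = 0.25  # above the feedback threshold
        ya = list(AbetaAstrocyteState.at_voltage(-60.0, C_c=Cc).to_array())
        dj = joint(1.0, yn + ya)
        I_fb = astro_feedback_current(Cc, p)
        assert I_fb > 0
        solo = make_neuron_rhs(p, proto)
        dn = solo(1.0, yn, I_extra=I_fb)
        da = make_abeta_rhs(p, cfg, v_of_t=-60.0)(1.0, ya)
        assert dj == pytest.approx(list(dn) + list(da), rel=1e-12)

    def test_coupled_fields_unique(self, p):
        cfg = AbetaConfig.from_params(p, l=0.4)
        rhs = make_coupled_rhs(p, StimulusProtocol(), cfg, release_micro=True)
        assert len(set(rhs.fields)) == len(rhs.fields)


class TestAmyloidEffectDirection:
    def test_autonomous_baseline_non_decreasing_in_l(self, p):
        from exosim.metrics import oscillation_metrics

        base = []
        for l in (0.0, 0.4, 1.0):
            res = ex.run_scenario("fig4_abeta_autonomous", p, l=l, t_max=200000.0)
            _, _, b = oscillation_metrics(res.t, res.trace("C_c"), window=(100000, 200000))
            base.append(b)
        assert base[0] <= base[1] + 1e-9 <= base[2] + 2e-9
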