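import math

import numpy as np
import pytest

import exosim as ex
from exosim.neuron import (
    NEURON_FIELDS,
    NeuronState,
    make_neuron_rhs,
    neuron_release,
    neuron_rhs,
)
from exosim.protocol import Pulse, StimulusProtocol


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


def _oracle_neuron_rhs(y, t, p, I_ind):
    """Independent term-by-term evaluation of the governing equations.

    Written directly from the printed forms (conserving sign convention),
    sharing no code with the package implementation.
    """
    pc = p.canonical()
    v, mNa, hNa, mK, mCL, hCL, mT, hTf, hTs, CL, Cm, Cc, Cr = y
    # membrane
    gK = 36.0 * mK**4
    gNa = 120.0 * mNa**3 * hNa
    dv = (gK * (-70.0 - v) + gNa * (50.0 - v) + 0.3 * (-54.4 - v) + I_ind) / 1.0
    # HH gates (classic rates)
    amNa = 0.1 * (v + 40) / (1 - math.exp(-(v + 40) / 10))
    bmNa = 4 * math.exp(-(v + 65) / 18)
    ahNa = 0.07 * math.exp(-(v + 65) / 20)
    bhNa = 1 / (1 + math.exp(-(v + 35) / 10))
    amK = 0.01 * (v + 55) / (1 - math.exp(-(v + 55) / 10))
    bmK = 0.125 * math.exp(-(v + 65) / 80)
    dmNa = amNa * (1 - mNa) - bmNa * mNa
    dhNa = ahNa * (1 - hNa) - bhNa * hNa
    dmK = amK * (1 - mK) - bmK * mK
    # L-type gates: signed-table Boltzmann + bell taus
    mCL_inf = _sig((v + 30.0) / 10.0)
    tau_mCL = 1.0 / (math.exp(-(v + 23) / 20.0) + math.exp((v + 23) / 20.0)) + 0.05
    hCL_inf = _sig((v + 33.0) / -5.0)
    tau_hCL = 60.0 / (math.exp(-v / 20.0) + math.exp(v / 20.0)) + 51.0
    dmCL = (mCL_inf - mCL) / tau_mCL
    dhCL = (hCL_inf - hCL) / tau_hCL
    # T-type (two inactivation gates, shared steady state)
    mT_inf = _sig((v + 63.5) / 1.5)
    hT_inf = _sig(-(v + 76.2) / 3.0)
    dmT = (mT_inf - mT) / (65 * math.exp(-(((v + 68) / 6.0) ** 2)) + 12)
    dhTf = (hT_inf - hTf) / (50 * math.exp(-(((v + 72) / 10.0) ** 2)) + 10)
    dhTs = (hT_inf - hTs) / (400 * math.exp(-(((v + 100) / 10.0) ** 2)) + 400)
    # calcium compartments
    f, al = 0.01, 5e-15
    lud, lm, lc = 2.62e-19, 5e-14, 5.7e-13
    lr = lc / 31.0
    i_CL = 0.7 * (v - 65.0) / 200.0
    I_CT = 0.4 * mT * (hTf + 0.04 * hTs) * (v - 65.0)
    dCL = -f * (al * i_CL / lud + 264.0 * (CL - Cm))
    dCm = (f / lm) * (
        -al * I_CT
        + 200.0 * (lud * 264.0) * mCL**2 * hCL * (CL - Cm)
        - lc * 0.3 * Cm
        - lc * 0.128 * (Cm - Cc)
    )
    dCc = f * (0.128 * (Cm - Cc) + 3e-4 * (Cr - Cc) - 0.1 * Cc)
    dCr = -f * 31.0 * (3e-4 * (Cr - Cc) - 0.1 * Cc)
    return [dv, dmNa, dhNa, dmK, dmCL, dhCL, dmT, dhTf, dhTs, dCL, dCm, dCc, dCr]


class TestNeuronRhs:
    def test_matches_independent_oracle(self, p):
        proto = StimulusProtocol(pulses=(Pulse(0.0, 10.0, 15.0),))
        rhs = make_neuron_rhs(p, proto)
        v = -65.0
        y = [
            v,
            0.05, 0.6, 0.32,
            _sig((v + 30) / 10), _sig(-(v + 33) / 5),
            _sig((v + 63.5) / 1.5), _sig(-(v + 76.2) / 3), _sig(-(v + 76.2) / 3),
            0.1, 0.1, 0.1, 1.5,
        ]
        got = rhs(5.0, y)
        want = _oracle_neuron_rhs(y, 5.0, p, 15.0)
        assert got == pytest.approx(want, rel=1e-10)

    def test_oracle_also_matches_spiking_state(self, p):
        rhs = make_neuron_rhs(p, StimulusProtocol())
        y = [12.0, 0.8, 0.2, 0.6, 0.5, 0.4, 0.9, 0.01, 0.02, 25.0, 0.4, 0.05, 4.0]
        assert rhs(0.0, y) == pytest.approx(_oracle_neuron_rhs(y, 0.0, p, 0.0), rel=1e-10)

    def test_exchange_vanishes_when_microdomain_equilibrated(self, p):
        q = p.replace(alpha=0.0)
        rhs = make_neuron_rhs(q, StimulusProtocol())
        y = NeuronState(C_L=0.25, C_m=0.25).to_array()
        dy = dict(zip(NEURON_FIELDS, rhs(0.0, y)))
        assert dy["C_L"] == 0.0

    def test_cytosol_balance_point(self, pc):
        # B_m(Cm-Cc) + p_leak(Cr-Cc) = k_SERCA*Cc  =>  dCc/dt = 0
        Cc = 0.1
        Cr = Cc * (1.0 + pc.k_SERCA / pc.p_leak)
        rhs = make_neuron_rhs(pc, StimulusProtocol())
        y = NeuronState(C_m=Cc, C_c=Cc, C_r=Cr).to_array()
        dy = dict(zip(NEURON_FIELDS, rhs(0.0, y)))
        assert dy["C_c"] == pytest.approx(0.0, abs=1e-15)

    def test_invalid_state_rejected(self, p):
        s = NeuronState(m_Na=1.5)
        with pytest.raises(ValueError):
            neuron_rhs(s, 0.0, p, StimulusProtocol())
        with pytest.raises(ValueError):
            neuron_rhs(NeuronState(v_m=float("nan")), 0.0, p, StimulusProtocol())

    def test_literal_signs_flag_changes_exchange(self, p):
        y = NeuronState(C_L=1.0, C_m=0.1).to_array()
        d_def = make_neuron_rhs(p, StimulusProtocol())(0.0, y)
        d_lit = make_neuron_rhs(p, StimulusProtocol(), literal_signs=True)(0.0, y)
        i = NEURON_FIELDS.index("C_L")
        assert d_def[i] != pytest.approx(d_lit[i])


class TestRelease:
    def test_closed_channel_branch(self, p):
        R_CL, _ = neuron_release(0.0, 0.7, 40.0, 0.3, p)
        assert R_CL == pytest.approx(ex.hill(0.3, p.K_L, p.n_L))

    def test_membrane_hill_midpoint(self, p):
        _, R_Cm = neuron_release(0.1, 1.0, 10.0, 2.0, p)
        assert R_Cm == pytest.approx(0.5)

    def test_total_bounded(self, p):
        R_CL, R_Cm = neuron_release(1.0, 1.0, 1e4, 1e4, p)
        assert 0.0 <= R_CL <= 1.0 and 0.0 <= R_Cm <= 1.0
        assert R_CL + R_Cm <= 2.0


class TestRestingState:
    def test_voltage_bracket(self, neuron_rest):
        assert -75.0 <= neuron_rest.v_m <= -55.0

    def test_gates_at_steady_state(self, p, neuron_rest):
        from exosim.channels import hh_rates, table1_gate

        v = neuron_rest.v_m
        a, b = hh_rates(v)[0], hh_rates(v)[1]
        assert neuron_rest.m_Na == pytest.approx(a / (a + b), abs=1e-5)
        g = table1_gate(p, "CL", "m")
        assert neuron_rest.m_CL == pytest.approx(g.steady(v), abs=1e-5)

    def test_no_spikes_from_rest(self, p, neuron_rest):
        from exosim.engine import build_model, integrate

        m = build_model("neuron", p, StimulusProtocol(), y0=neuron_rest.to_array(), t_max=500.0)
        res = integrate(m)
        assert ex.detect_spikes(res.t, res.trace("v_m")).count == 0
        assert np.max(np.abs(res.trace("v_m") - neuron_rest.v_m)) < 0.5


class TestMassConservation:
    def test_weighted_total_constant_without_membrane_exchange(self, p):
        from exosim.engine import build_model, integrate
        from exosim.neuron import resting_state

        q = p.replace(alpha=0.0, k_PMCA=0.0)
        rest = resting_state(q)
        proto = StimulusProtocol(pulses=(Pulse(50.0, 300.0, 20.0),))
        m = build_model("neuron", q, proto, y0=rest.to_array(), t_max=500.0)
        res = integrate(m)
        qc = q.canonical()
        total = (
            qc.lambda_m * res.trace("C_m")
            + qc.lambda_c * res.trace("C_c")
            + qc.lambda_r * res.trace("C_r")
            + qc.N_L * qc.lambda_ud * res.trace("C_L")
        )
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6


class TestReleaseMonotonicity:
    def test_cumulative_release_non_decreasing(self, fig2_result):
        r = fig2_result.trace("R_total")
        cum = np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(fig2_result.t))
        assert np.all(np.diff(cum) >= -1e-15)
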