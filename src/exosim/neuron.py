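"""Spiking neuron with calcium-microdomain exosomal release.

Hodgkin-Huxley membrane (K+, Na+, leak, induced current) driving a
four-compartment calcium mass balance: per-channel L-type microdomains
(C_L, exchanging with the sub-membrane shell at rate B_ud), the sub-membrane
shell (C_m, fed by the whole-cell T-type current and the open-weighted
microdomain exchange, drained by the plasma-membrane ATPase), the bulk
cytosol (C_c) and the endoplasmic reticulum (C_r, SERCA uptake vs leak).

Release rates are Hill functions of the local calcium levels: the L-pathway
rate mixes the open-microdomain and closed (= sub-membrane) branches with
the channel open probability m^2 h; the membrane pathway is a plain Hill
function of C_m.

Sign conventions: the default microdomain and ER exchange terms are the
mass-conserving forms; ``literal_signs=True`` keeps the printed
(self-amplifying) variants for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .channels import table1_gate
from .kinetics import hill
from .params import ParameterSet
from .protocol import StimulusProtocol
from .thermal import ThermalConfig

__all__ = [
    "NEURON_FIELDS",
    "NeuronState",
    "ReleaseRates",
    "make_neuron_rhs",
    "neuron_rhs",
    "neuron_release",
    "resting_state",
]

NEURON_FIELDS = (
    "v_m",
    "m_Na",
    "h_Na",
    "m_K",
    "m_CL",
    "h_CL",
    "m_CT",
    "h_CTf",
    "h_CTs",
    "C_L",
    "C_m",
    "C_c",
    "C_r",
)

_GATE_FIELDS = NEURON_FIELDS[1:9]
_CONC_FIELDS = NEURON_FIELDS[9:]


@dataclass(frozen=True)
class NeuronState:
    v_m: float = -65.0
    m_Na: float = 0.05
    h_Na: float = 0.6
    m_K: float = 0.32
    m_CL: float = 0.03
    h_CL: float = 1.0
    m_CT: float = 0.27
    h_CTf: float = 0.02
    h_CTs: float = 0.02
    C_L: float = 0.1  # uM, open-microdomain concentration
    C_m: float = 0.1  # uM, sub-membrane shell
    C_c: float = 0.1  # uM, bulk cytosol
    C_r: float = 2.0  # uM, endoplasmic reticulum

    def validate(self):
        for name in _GATE_FIELDS:
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name} out of [0,1]: {x}")
        for name in _CONC_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} negative")
        if not all(math.isfinite(getattr(self, n)) for n in NEURON_FIELDS):
            raise ValueError("non-finite state")
        return self

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in NEURON_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        return cls(**dict(zip(NEURON_FIELDS, map(float, y))))


@dataclass(frozen=True)
class ReleaseRates:
    """Per-pathway relative exosomal release rates (each in [0,1])."""

    R_CL: float
    R_Cm: float
    R_CN: float = 0.0

    @property
    def total(self) -> float:
        return self.R_CL + self.R_Cm + self.R_CN


def make_neuron_rhs(
    p: ParameterSet,
    drive: StimulusProtocol,
    *,
    thermal: Optional[ThermalConfig] = None,
    literal_signs: bool = False,
    literal_rates: bool = False,
    extra_current: Optional[Callable[[float], float]] = None,
) -> Callable:
    """Build the derivative function ``rhs(t, y, I_extra=0.0) -> list``.

    ``y`` is packed in ``NEURON_FIELDS`` order.  ``I_extra`` allows a coupled
    model to inject the astrocytic feedback current; ``extra_current(t)``
    adds a purely time-dependent term.
    """
    p = p.canonical()
    th = thermal if thermal is not None else drive.thermal
    cm = p.c_m
    gK_bar, gNa_bar, gL = p.g_K_bar, p.g_Na_bar, p.g_L
    VK, VNa, VL, VC = p.V_K, p.V_Na, p.V_L, p.V_C
    f, alpha = p.f, p.alpha
    lam_ud, lam_m, lam_c, lam_r = p.lambda_ud, p.lambda_m, p.lambda_c, p.lambda_r
    B_ud, B_m, kP, kS, pleak = p.B_ud, p.B_m, p.k_PMCA, p.k_SERCA, p.p_leak
    NL, gCL, gCT = p.N_L, p.g_CL, p.g_CT
    Gamma = lam_ud * B_ud
    micro_sign = -1.0 if literal_signs else 1.0  # sign of the B_ud relaxation
    er_sign = 1.0 if literal_signs else -1.0  # sign of the printed ER balance

    gate_mCL = table1_gate(p, "CL", "m")
    gate_hCL = table1_gate(p, "CL", "h")
    # hot-loop constants extracted from the gate specs
    mCL_mid, mCL_slo = gate_mCL.midpoint, gate_mCL.slope
    mCL_tp, mCL_tb = gate_mCL.tau_peak, gate_mCL.tau_base
    mCL_tm, mCL_ts = gate_mCL.tau_midpoint, gate_mCL.tau_slope
    hCL_mid, hCL_slo = gate_hCL.midpoint, gate_hCL.slope
    hCL_tp, hCL_tb = gate_hCL.tau_peak, gate_hCL.tau_base
    hCL_tm, hCL_ts = gate_hCL.tau_midpoint, gate_hCL.tau_slope

    trpm8_on = bool(th.active and th.trpm8_enabled)
    g_m8 = th.g_m8 if (th.g_m8 is not None) else p.g_m8
    V_m8 = p.V_m8

    I_ind = drive.I_ind
    exp = math.exp
    dS, dH, zF, Rg = p.dS, p.dH, p.z_gate * p.F / 1000.0, p.R_gas
    kK_pref = (p.phi_mK_pref, p.phi_mK_q10)
    kNa_pref = (p.phi_mNa_pref, p.phi_mNa_q10)
    kh_pref = (p.phi_hNa_pref, p.phi_hNa_q10)
    gk_c = (p.gK_max_amp, p.gK_max_T0, p.gK_max_sigma)
    gna_c = (p.gNa_max_amp, p.gNa_max_T0, p.gNa_max_sigma)

    def _sig(u):
        # overflow-safe logistic in the exponent argument
        if u > 700.0:
            return 1.0
        if u < -700.0:
            return 0.0
        return 1.0 / (1.0 + exp(-u))

    def rhs(t, y, I_extra=0.0):
        (v, mNa, hNa, mK, mCL, hCL, mT, hTf, hTs, CL, Cm, Cc, Cr) = y

        if th.active:
            T = th.temperature(t)
            e10 = (T - 20.0) / 10.0
            phi_mK = kK_pref[0] * kK_pref[1] ** e10
            phi_mNa = kNa_pref[0] * kNa_pref[1] ** e10
            phi_hNa = kh_pref[0] * kh_pref[1] ** e10
            gk = exp(-(((T - gk_c[1]) / gk_c[2]) ** 2))
            gna = exp(-(((T - gna_c[1]) / gna_c[2]) ** 2))
            if th.literal_gmax:
                gK_eff, gNa_eff = gk_c[0] * gk, gna_c[0] * gna
            else:
                gK_eff, gNa_eff = gK_bar * gk, gNa_bar * gna
        else:
            phi_mK = phi_mNa = phi_hNa = 1.0
            gK_eff, gNa_eff = gK_bar, gNa_bar

        # membrane equation
        I_total = (
            gK_eff * mK**4 * (VK - v)
            + gNa_eff * mNa**3 * hNa * (VNa - v)
            + gL * (VL - v)
            + I_ind(t)
            + I_extra
        )
        if extra_current is not None:
            I_total += extra_current(t)
        if trpm8_on and g_m8 > 0.0:
            TK = T + 273.15
            a_m8 = _sig((TK * dS - dH + zF * v) / (Rg * TK))
            I_total += g_m8 * a_m8 * (v - V_m8)
        dv = I_total / cm

        # Hodgkin-Huxley gates
        if literal_rates:
            a_mNa = 0.1 * (v + 40.0) * _sig((v + 40.0) / 10.0)
            a_mK = 0.01 * (v + 55.0) * _sig((v + 55.0) / 10.0)
            b_mK = 0.125 * exp(-(v + 65.0) / 18.0)
        else:
            x = v + 40.0
            a_mNa = 0.1 * (10.0 + x / 2.0 if abs(x) < 1e-7 else x / (1.0 - exp(-x / 10.0)))
            x = v + 55.0
            a_mK = 0.01 * (10.0 + x / 2.0 if abs(x) < 1e-7 else x / (1.0 - exp(-x / 10.0)))
            b_mK = 0.125 * exp(-(v + 65.0) / 80.0)
        b_mNa = 4.0 * exp(-(v + 65.0) / 18.0)
        a_hNa = 0.07 * exp(-(v + 65.0) / 20.0)
        b_hNa = _sig((v + 35.0) / 10.0)
        dmNa = phi_mNa * (a_mNa * (1.0 - mNa) - b_mNa * mNa)
        dhNa = phi_hNa * (a_hNa * (1.0 - hNa) - b_hNa * hNa)
        dmK = phi_mK * (a_mK * (1.0 - mK) - b_mK * mK)

        # microdomain L-type gates (signed-table parameterisation)
        u = (v - mCL_tm) / mCL_ts
        tau = mCL_tp / (exp(-u) + exp(u)) + mCL_tb
        dmCL = (_sig((v - mCL_mid) / mCL_slo) - mCL) / tau
        u = (v - hCL_tm) / hCL_ts
        tau = hCL_tp / (exp(-u) + exp(u)) + hCL_tb
        dhCL = (_sig((v - hCL_mid) / hCL_slo) - hCL) / tau

        # T-type gates: one steady-state curve, fast/slow inactivation taus
        mT_inf = _sig((v + 63.5) / 1.5)
        hT_inf = _sig(-(v + 76.2) / 3.0)
        dmT = (mT_inf - mT) / (65.0 * exp(-(((v + 68.0) / 6.0) ** 2)) + 12.0)
        dhTf = (hT_inf - hTf) / (50.0 * exp(-(((v + 72.0) / 10.0) ** 2)) + 10.0)
        dhTs = (hT_inf - hTs) / (400.0 * exp(-(((v + 100.0) / 10.0) ** 2)) + 400.0)

        # calcium mass balance
        i_CL = gCL * (v - VC) / NL  # pA per open channel
        I_CT = gCT * mT * (hTf + 0.04 * hTs) * (v - VC)  # pA, whole cell
        w_open = mCL * mCL * hCL
        dCL = -f * (alpha * i_CL / lam_ud + micro_sign * B_ud * (CL - Cm))
        dCm = (f / lam_m) * (
            -alpha * I_CT
            + NL * Gamma * w_open * (CL - Cm)
            - lam_c * kP * Cm
            - lam_c * B_m * (Cm - Cc)
        )
        er_flux = pleak * (Cr - Cc) - kS * Cc
        dCc = f * (B_m * (Cm - Cc) + er_flux)
        dCr = er_sign * f * (lam_c / lam_r) * er_flux

        return [dv, dmNa, dhNa, dmK, dmCL, dhCL, dmT, dhTf, dhTs, dCL, dCm, dCc, dCr]

    rhs.fields = NEURON_FIELDS
    return rhs


def neuron_rhs(s: NeuronState, t: float, p: ParameterSet, drive: StimulusProtocol, **kw):
    """Single derivative evaluation (validated), as a NeuronState-shaped dict."""
    s.validate()
    dy = make_neuron_rhs(p, drive, **kw)(t, s.to_array())
    return dict(zip(NEURON_FIELDS, dy))


def neuron_release(m_CL, h_CL, C_L, C_m, p: ParameterSet):
    """Per-pathway release rates from gate and calcium levels.

    Accepts scalars or aligned arrays; the closed-microdomain branch uses the
    sub-membrane concentration.
    """
    w = m_CL * m_CL * h_CL
    R_CL = w * hill(C_L, p.K_L, p.n_L) + (1.0 - w) * hill(C_m, p.K_L, p.n_L)
    R_Cm = hill(C_m, p.K_m, p.n_m)
    return R_CL, R_Cm


def resting_state(
    p: ParameterSet,
    *,
    t_relax: float = 250000.0,
    tol: float = 1e-7,
    **model_kw,
) -> NeuronState:
    """Equilibrium of the unstimulated neuron, found by relaxation.

    Integrates the autonomous system for ``t_relax`` ms with a stiff-capable
    adaptive method and verifies the residual derivative norm.
    """
    from scipy.integrate import solve_ivp

    quiet = StimulusProtocol()
    rhs = make_neuron_rhs(p, quiet, **model_kw)
    y0 = NeuronState().to_array()
    sol = solve_ivp(
        lambda t, y: rhs(t, y),
        (0.0, t_relax),
        y0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"resting-state relaxation failed: {sol.message}")
    y = sol.y[:, -1]
    resid = np.array(rhs(t_relax, y))
    scale = np.maximum(np.abs(y), 1.0)
    worst = float(np.max(np.abs(resid) / scale))
    if worst > tol:
        raise RuntimeError(
            f"resting state did not converge: max scaled residual {worst:.3e} "
            f"(residuals {resid.tolist()})"
        )
    return NeuronState.from_array(y)
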