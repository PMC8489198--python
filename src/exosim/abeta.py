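"""Amyloid-beta-modulated astrocytic calcium network and neuron coupling.

A scalar amyloid level ``l`` scales four calcium pathways: the L-type
channel current (weight A_VL), ryanodine-receptor sensitivity (A_RyR),
plasma-membrane leak (A_in) and PLC-catalysed IP3 production (A_m).  The
astrocyte state is (cytosol C_c, ER C_r, IP3 P_c) plus the voltage gates of
the four whole-membrane channel types; fluxes are on the per-second base in
the printed units and converted to the millisecond base on assembly.

The astrocyte feeds back onto the neuron through a logarithmic
calcium-dependent depolarising current, giving the coupled network model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .channels import ca_inactivation, table1_gate, vgcc_steady
from .kinetics import hill
from .neuron import NEURON_FIELDS, make_neuron_rhs
from .params import ParameterSet
from .protocol import StimulusProtocol
from .thermal import ThermalConfig

__all__ = [
    "ABETA_FIELDS",
    "MICRO_FIELDS",
    "AbetaConfig",
    "AbetaAstrocyteState",
    "abeta_fluxes",
    "make_abeta_rhs",
    "abeta_rhs",
    "astro_feedback_current",
    "make_coupled_rhs",
    "abeta_release",
]

ABETA_FIELDS = ("C_c", "C_r", "P_c", "m_T", "h_Tf", "h_Ts", "m_L", "m_N", "m_R", "h_R")

#: optional microdomain extension used when per-pathway release is tracked
MICRO_FIELDS = ("m_CL", "h_CL", "m_CN", "h_CN", "C_L", "C_N", "C_m")

#: feedback-current threshold offset: I_astro is gated on ln(1000*C_c - 196.69)
_FEEDBACK_SHIFT = 196.69


@dataclass(frozen=True)
class AbetaConfig:
    """Amyloid burden and pathway weights."""

    l: float = 0.0
    A_VL: float = 1.0
    A_RyR: float = 1.0
    A_m: float = 1.0
    A_in: float = 1.0

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("amyloid level l must be non-negative")
        if min(self.A_VL, self.A_RyR, self.A_m, self.A_in) < 0:
            raise ValueError("pathway weights must be non-negative")

    @classmethod
    def from_params(cls, p: ParameterSet, l: float = 0.0) -> "AbetaConfig":
        # A_in carries flux units and is canonicalised with the parameter set
        return cls(l=l, A_VL=p.A_VL, A_RyR=p.A_RyR, A_m=p.A_m, A_in=p.to_printed().A_in)


@dataclass(frozen=True)
class AbetaAstrocyteState:
    C_c: float = 0.1  # uM (printed initial condition)
    C_r: float = 1.5  # uM
    P_c: float = 0.1  # uM
    m_T: float = 0.0
    h_Tf: float = 0.2
    h_Ts: float = 0.2
    m_L: float = 0.0
    m_N: float = 0.0
    m_R: float = 0.0
    h_R: float = 1.0
    v_m: float = -70.0  # shared with the driving membrane equation

    def validate(self):
        for name in ("m_T", "h_Tf", "h_Ts", "m_L", "m_N", "m_R", "h_R"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name} out of [0,1]: {x}")
        for name in ("C_c", "C_r", "P_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} negative")
        return self

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ABETA_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y, v_m: float = -70.0) -> "AbetaAstrocyteState":
        return cls(**dict(zip(ABETA_FIELDS, map(float, y))), v_m=v_m)

    @classmethod
    def at_voltage(cls, v: float, **kw) -> "AbetaAstrocyteState":
        """Printed initial concentrations with gates at steady state for v."""
        return cls(
            m_T=vgcc_steady("T", "m", v),
            h_Tf=vgcc_steady("T", "h", v),
            h_Ts=vgcc_steady("T", "h", v),
            m_L=vgcc_steady("L", "m", v),
            m_N=vgcc_steady("N", "m", v),
            m_R=vgcc_steady("R", "m", v),
            h_R=vgcc_steady("R", "h", v),
            v_m=v,
            **kw,
        )


def _vgcc_total_current(s_arr, v, l, A_VL, p: ParameterSet):
    """Amyloid-weighted total VGCC current in fA."""
    Cc = s_arr[0]
    mT, hTf, hTs, mL, mN, mR, hR = s_arr[3:10]
    drive = v - p.V_C
    I_T = p.g_T_bar * mT * (hTf + 0.04 * hTs) * drive
    I_L = p.g_L_bar * mL * ca_inactivation("L", Cc) * drive
    I_N = p.g_N_bar * mN * ca_inactivation("N", Cc) * drive
    I_R = p.g_R_bar * mR * hR * drive
    return I_T + (1.0 + A_VL * l) * I_L + I_N + I_R


def abeta_fluxes(s: AbetaAstrocyteState, cfg: AbetaConfig, p: ParameterSet) -> dict:
    """Named calcium fluxes for the given state.

    Units follow the parameter set: uM/s for a printed-unit set, uM/ms for a
    canonical one.
    """
    time_base = 1e-3 if p.is_canonical else 1.0  # s per internal time unit
    Cc, Cr, Pc = s.C_c, s.C_r, s.P_c
    l = cfg.l
    arr = s.to_array()
    I_vgcc = _vgcc_total_current(arr, s.v_m, l, cfg.A_VL, p)
    # fA -> uM per time-base unit: 1e-15 A / (z F lambda) * 1e6 uM/M
    cur2flux = 1e-9 / (p.z_Ca * p.F * p.lambda_ast) * time_base
    # cfg.A_in is stored in printed units (uM/s); rescale onto p's base
    A_in = cfg.A_in * (1e-3 if p.is_canonical else 1.0)
    return {
        "J_VGCC": -I_vgcc * cur2flux,
        "J_CICR": 4.0
        * p.M_CICR
        * hill(p.P_CA, Cc, p.n1)
        * hill(Cc, p.P_CI, p.n1)
        * hill(Pc, p.P_IP3, p.n2)
        * (Cr - Cc),
        "J_SERCA": p.M_SERCA * hill(Cc, p.P_SERCA, p.n4),
        "J_RyR": (p.k1 + p.k2 * hill(Cc, p.k_d + cfg.A_RyR * l, p.n3)) * (Cr - Cc),
        "J_r": p.P_f * (Cr - Cc),
        "J_in": p.a1 + p.a2_in * Pc + A_in * l**p.n5,
        "J_pm": p.lambda_PM * hill(Cc, p.K_pm, p.n4),
        "J_PLC": (1.0 + cfg.A_m * l) * p.M_PLC * hill(Cc, p.P_PC, p.n4),
    }


def astro_feedback_current(C_c, p: ParameterSet, literal_heaviside: bool = False):
    """Depolarising feedback current (uA/cm^2) from astrocytic calcium.

    y = 1000*C_c - 196.69.  Default: zero until y > 1 then A_astro*ln(y)
    (continuous at the threshold).  ``literal_heaviside=True`` applies the
    printed step H(y) directly, admitting negative currents for 0 < y < 1.
    """
    y = 1000.0 * np.asarray(C_c, dtype=float) - _FEEDBACK_SHIFT
    if literal_heaviside:
        out = np.where(y > 0.0, p.A_astro * np.log(np.where(y > 0.0, y, 1.0)), 0.0)
    else:
        out = np.where(y > 1.0, p.A_astro * np.log(np.where(y > 1.0, y, 1.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def make_abeta_rhs(
    p: ParameterSet,
    cfg: AbetaConfig,
    *,
    v_of_t: Union[float, Callable[[float], float]] = -70.0,
    release_micro: bool = False,
    literal_signs: bool = False,
) -> Callable:
    """Derivative function for the amyloid astrocyte.

    State packing: ``ABETA_FIELDS`` (+ ``MICRO_FIELDS`` when
    ``release_micro``).  ``v_of_t`` is the driving membrane potential, a
    constant clamp or a callable of time.
    """
    p = p.canonical()
    l, A_VL, A_RyR, A_m = cfg.l, cfg.A_VL, cfg.A_RyR, cfg.A_m
    A_in_ms = cfg.A_in * 1e-3  # printed uM/s -> uM/ms
    M_CICR, M_SERCA, M_PLC = p.M_CICR, p.M_SERCA, p.M_PLC
    P_SERCA, P_PC, P_CA, P_CI, P_IP3 = p.P_SERCA, p.P_PC, p.P_CA, p.P_CI, p.P_IP3
    P_deg, P_f, k1, k2, k_d = p.P_deg, p.P_f, p.k1, p.k2, p.k_d
    a1, a2_in = p.a1, p.a2_in
    n1, n2, n3, n4, n5 = p.n1, p.n2, p.n3, p.n4, p.n5
    lam_PM, K_pm = p.lambda_PM, p.K_pm
    cur2flux = 1e-9 / (p.z_Ca * p.F * p.lambda_ast) * 1e-3  # fA -> uM/ms
    VC = p.V_C
    gT, gLb, gNb, gRb = p.g_T_bar, p.g_L_bar, p.g_N_bar, p.g_R_bar
    K_half = k_d + A_RyR * l

    v_fun = v_of_t if callable(v_of_t) else (lambda t, _v=float(v_of_t): _v)
    exp = math.exp

    def _sig(u):
        if u > 700.0:
            return 1.0
        if u < -700.0:
            return 0.0
        return 1.0 / (1.0 + exp(-u))

    def _h(x, K, n):
        r = (x / K) ** n
        return r / (1.0 + r)

    if release_micro:
        f, alpha = p.f, p.alpha
        lam_ud, lam_m, lam_c = p.lambda_ud, p.lambda_m, p.lambda_c
        B_ud, B_m, kP = p.B_ud, p.B_m, p.k_PMCA
        NL, NN, gCL, gCN, gCT = p.N_L, p.N_N, p.g_CL, p.g_CN, p.g_CT
        Gamma = lam_ud * B_ud
        micro_sign = -1.0 if literal_signs else 1.0
        gate_mCL = table1_gate(p, "CL", "m")
        gate_hCL = table1_gate(p, "CL", "h")
        gate_mCN = table1_gate(p, "CN", "m")
        gate_hCN = table1_gate(p, "CN", "h")

    def rhs(t, y, v=None):
        if v is None:
            v = v_fun(t)
        Cc, Cr, Pc, mT, hTf, hTs, mL, mN, mR, hR = y[:10]
        drive_v = v - VC
        I_T = gT * mT * (hTf + 0.04 * hTs) * drive_v
        I_L = gLb * mL * (0.00045 / (0.00045 + Cc / 1000.0)) * drive_v
        I_N = gNb * mN * (0.0001 / (0.0001 + Cc / 1000.0)) * drive_v
        I_R = gRb * mR * hR * drive_v
        J_VGCC = -(I_T + (1.0 + A_VL * l) * I_L + I_N + I_R) * cur2flux

        J_CICR = (
            4.0
            * M_CICR
            * _h(P_CA, Cc, n1)
            * _h(Cc, P_CI, n1)
            * _h(Pc, P_IP3, n2)
            * (Cr - Cc)
        )
        J_SERCA = M_SERCA * _h(Cc, P_SERCA, n4)
        J_RyR = (k1 + k2 * _h(Cc, K_half, n3)) * (Cr - Cc)
        J_r = P_f * (Cr - Cc)
        J_in = a1 + a2_in * Pc + A_in_ms * l**n5
        J_pm = lam_PM * _h(Cc, K_pm, n4)
        J_PLC = (1.0 + A_m * l) * M_PLC * _h(Cc, P_PC, n4)

        dCc = J_VGCC + J_in + J_RyR + J_CICR + J_r - J_SERCA - J_pm
        dCr = J_SERCA - J_CICR - J_RyR - J_r
        dPc = J_PLC - P_deg * Pc

        dmT = (_sig((v + 63.5) / 1.5) - mT) / (65.0 * exp(-(((v + 68.0) / 6.0) ** 2)) + 12.0)
        hT_inf = _sig(-(v + 76.2) / 3.0)
        dhTf = (hT_inf - hTf) / (50.0 * exp(-(((v + 72.0) / 10.0) ** 2)) + 10.0)
        dhTs = (hT_inf - hTs) / (400.0 * exp(-(((v + 100.0) / 10.0) ** 2)) + 400.0)
        dmL = (_sig((v + 50.0) / 3.0) - mL) / (18.0 * exp(-(((v + 45.0) / 20.0) ** 2)) + 1.5)
        dmN = (_sig((v + 45.0) / 7.0) - mN) / (18.0 * exp(-(((v + 70.0) / 25.0) ** 2)) + 0.3)
        dmR = (_sig((v + 10.0) / 10.0) - mR) / (0.1 * exp(-(((v + 62.0) / 13.0) ** 2)) + 0.05)
        dhR = (_sig(-(v + 48.0) / 5.0) - hR) / (0.5 * exp(-(((v + 55.6) / 18.0) ** 2)) + 0.5)

        out = [dCc, dCr, dPc, dmT, dhTf, dhTs, dmL, dmN, dmR, dhR]

        if release_micro:
            mCL, hCL, mCN, hCN, CL, CN, Cm = y[10:17]
            dmCL = (gate_mCL.steady(v) - mCL) / gate_mCL.tau(v)
            dhCL = (gate_hCL.steady(v) - hCL) / gate_hCL.tau(v)
            dmCN = (gate_mCN.steady(v) - mCN) / gate_mCN.tau(v)
            dhCN = (gate_hCN.steady(v) - hCN) / gate_hCN.tau(v)
            i_CL = gCL * drive_v / NL
            i_CN = gCN * drive_v / NN
            dCL = -f * (alpha * i_CL / lam_ud + micro_sign * B_ud * (CL - Cm))
            dCN = -f * (alpha * i_CN / lam_ud + micro_sign * B_ud * (CN - Cm))
            I_CT = gCT * _sig((v + 63.5) / 1.5) * (1.04 * _sig(-(v + 76.2) / 3.0)) * drive_v
            dCm = (f / lam_m) * (
                -alpha * I_CT
                + NL * Gamma * (mCL * mCL * hCL) * (CL - Cm)
                + NN * Gamma * (mCN * hCN) * (CN - Cm)
                - lam_c * kP * Cm
                - lam_c * B_m * (Cm - Cc)
            )
            out += [dmCL, dhCL, dmCN, dhCN, dCL, dCN, dCm]

        return out

    rhs.fields = ABETA_FIELDS + (MICRO_FIELDS if release_micro else ())
    return rhs


def abeta_rhs(s: AbetaAstrocyteState, t, cfg: AbetaConfig, p: ParameterSet, drive=None, **kw):
    """Single validated derivative evaluation as a field-name dict."""
    s.validate()
    fn = make_abeta_rhs(p, cfg, v_of_t=s.v_m, **kw)
    dy = fn(t, s.to_array())
    return dict(zip(ABETA_FIELDS, dy))


def abeta_release(m_CL, h_CL, m_CN, h_CN, C_L, C_N, C_m, p: ParameterSet):
    """Collective release rates for the amyloid variant (same Hill forms)."""
    from .astrocyte import astrocyte_release

    return astrocyte_release(m_CL, h_CL, m_CN, h_CN, C_L, C_N, C_m, p)


def make_coupled_rhs(
    p: ParameterSet,
    drive: StimulusProtocol,
    cfg: AbetaConfig,
    *,
    thermal: Optional[ThermalConfig] = None,
    release_micro: bool = False,
    literal_signs: bool = False,
    literal_rates: bool = False,
    literal_heaviside: bool = False,
    feedback: bool = True,
) -> Callable:
    """Joint neuron + amyloid-astrocyte derivative.

    Packing: ``NEURON_FIELDS`` then ``ABETA_FIELDS`` (then ``MICRO_FIELDS``).
    The astrocyte sees the neuron membrane potential; the neuron receives the
    calcium-gated feedback current (disable with ``feedback=False``).
    """
    p = p.canonical()
    n_rhs = make_neuron_rhs(
        p, drive, thermal=thermal, literal_signs=literal_signs, literal_rates=literal_rates
    )
    a_rhs = make_abeta_rhs(p, cfg, release_micro=release_micro, literal_signs=literal_signs)
    nn = len(NEURON_FIELDS)
    A_astro = p.A_astro

    def I_astro(Cc):
        y = 1000.0 * Cc - _FEEDBACK_SHIFT
        if literal_heaviside:
            return A_astro * math.log(y) if y > 0.0 else 0.0
        return A_astro * math.log(y) if y > 1.0 else 0.0

    def rhs(t, y):
        v = y[0]
        Cc_astro = y[nn]
        I_fb = I_astro(Cc_astro) if feedback else 0.0
        dn = n_rhs(t, y[:nn], I_extra=I_fb)
        da = a_rhs(t, y[nn:], v=v)
        return list(dn) + list(da)

    # astrocyte block is prefixed to keep joint column names unique
    rhs.fields = NEURON_FIELDS + tuple(f"ast_{f}" for f in a_rhs.fields)
    rhs.I_astro = I_astro
    return rhs
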