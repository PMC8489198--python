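"""Electrically silent astrocyte driven by a depolarisation step v_ind.

The effective gating voltage is V_m + v_ind with the resting membrane
potential fixed at V_m = -70 mV.  IP3 relaxes to its baseline and is
produced at a constant rate while the stimulus is on; cytosolic calcium
follows the two-variable IP3-receptor reduction (channel flux + ER leak +
SERCA uptake) with the ER concentration slaved through (c0 - C_c)/c1.
L- and N-type microdomains and the sub-membrane shell evolve as in the
neuron, evaluated at the effective voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .channels import table1_gate
from .kinetics import hill
from .params import ParameterSet
from .protocol import StimulusProtocol

__all__ = [
    "ASTRO_FIELDS",
    "AstrocyteState",
    "ip3_rhs",
    "make_astrocyte_rhs",
    "astrocyte_rhs",
    "astrocyte_release",
    "er_concentration",
    "astrocyte_resting_state",
]

ASTRO_FIELDS = (
    "P",
    "h_P",
    "m_CL",
    "h_CL",
    "m_CN",
    "h_CN",
    "C_L",
    "C_N",
    "C_m",
    "C_c",
)


@dataclass(frozen=True)
class AstrocyteState:
    P: float = 0.16  # uM IP3
    h_P: float = 0.8
    m_CL: float = 0.02
    h_CL: float = 1.0
    m_CN: float = 0.0
    h_CN: float = 1.0
    C_L: float = 0.1
    C_N: float = 0.1
    C_m: float = 0.1
    C_c: float = 0.1

    def validate(self):
        for name in ("h_P", "m_CL", "h_CL", "m_CN", "h_CN"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name} out of [0,1]: {x}")
        for name in ("P", "C_L", "C_N", "C_m", "C_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} negative")
        if not all(math.isfinite(getattr(self, n)) for n in ASTRO_FIELDS):
            raise ValueError("non-finite state")
        return self

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ASTRO_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "AstrocyteState":
        return cls(**dict(zip(ASTRO_FIELDS, map(float, y))))


def er_concentration(C_c, p: ParameterSet):
    """ER free calcium implied by the conserved-pool relation (c0 - C_c)/c1."""
    return (p.c0 - C_c) / p.c1


def ip3_rhs(P, t, p: ParameterSet, drive: StimulusProtocol, scale_with_v_ind: bool = False):
    """IP3 production/decay rate (uM/ms); production gated by the stimulus.

    ``scale_with_v_ind=True`` scales the production term linearly with the
    instantaneous v_ind amplitude relative to a 10 mV reference (optional
    reading of the stimulus-proportionality remark; default off).
    """
    p = p.canonical()
    gate = 1.0 if drive.v_ind_active(t) else 0.0
    if scale_with_v_ind and gate:
        gate = drive.v_ind_at(t) / 10.0
    return (p.IP3_0 - P) / p.tau_P + p.r_P * gate


def make_astrocyte_rhs(
    p: ParameterSet,
    drive: StimulusProtocol,
    *,
    literal_signs: bool = False,
    scale_ip3_with_v_ind: bool = False,
) -> Callable:
    """Derivative function over ``ASTRO_FIELDS`` packing."""
    p = p.canonical()
    f, alpha = p.f, p.alpha
    lam_ud, lam_m, lam_c = p.lambda_ud, p.lambda_m, p.lambda_c
    B_ud, B_m, kP = p.B_ud, p.B_m, p.k_PMCA
    NL, NN, gCL, gCN, gCT, VC = p.N_L, p.N_N, p.g_CL, p.g_CN, p.g_CT, p.V_C
    Vm = p.V_m_ast
    Gamma = lam_ud * B_ud
    micro_sign = -1.0 if literal_signs else 1.0
    c0, c1, v1, v2, v3, k3, n4 = p.c0, p.c1, p.v1, p.v2, p.v3, p.k3, p.n4
    d1, d2, d3, d5, d6, a2r = p.d1, p.d2, p.d3, p.d5, p.d6, p.a2_ip3r
    IP3_0, tau_P, r_P = p.IP3_0, p.tau_P, p.r_P

    gates = [
        table1_gate(p, "CL", "m"),
        table1_gate(p, "CL", "h"),
        table1_gate(p, "CN", "m"),
        table1_gate(p, "CN", "h"),
    ]
    gc = [
        (g.midpoint, g.slope, g.tau_peak, g.tau_base, g.tau_midpoint, g.tau_slope)
        for g in gates
    ]
    exp = math.exp

    def _sig(u):
        if u > 700.0:
            return 1.0
        if u < -700.0:
            return 0.0
        return 1.0 / (1.0 + exp(-u))

    def _gate_rate(y, v, c):
        mid, slo, tp, tb, tm, ts = c
        u = (v - tm) / ts
        return (_sig((v - mid) / slo) - y) / (tp / (exp(-u) + exp(u)) + tb)

    def rhs(t, y):
        (P, hP, mCL, hCL, mCN, hCN, CL, CN, Cm, Cc) = y
        v = Vm + drive.v_ind_at(t)

        gate = 1.0 if drive.v_ind_active(t) else 0.0
        if scale_ip3_with_v_ind and gate:
            gate = drive.v_ind_at(t) / 10.0
        dP = (IP3_0 - P) / tau_P + r_P * gate

        # IP3-receptor reduction for the bulk cytosol
        Cer = (c0 - Cc) / c1
        m_inf = (P / (P + d1)) * (Cc / (Cc + d5)) if d6 == 1.0 else (
            hill(P, d1, d6) * hill(Cc, d5, d6)
        )
        Q = d2 * (P + d1) / (P + d3)
        h_inf = Q / (Q + Cc)
        tau_h = 1.0 / (a2r * (Q + Cc))
        grad = Cc - Cer
        r3 = (Cc / k3) ** n4
        dCc = -(c1 * v1 * (m_inf**3) * (hP**3) + c1 * v2) * grad - v3 * r3 / (1.0 + r3)
        dhP = (h_inf - hP) / tau_h

        # voltage gates at the effective potential
        dmCL = _gate_rate(mCL, v, gc[0])
        dhCL = _gate_rate(hCL, v, gc[1])
        dmCN = _gate_rate(mCN, v, gc[2])
        dhCN = _gate_rate(hCN, v, gc[3])

        # microdomains and sub-membrane shell
        i_CL = gCL * (v - VC) / NL
        i_CN = gCN * (v - VC) / NN
        dCL = -f * (alpha * i_CL / lam_ud + micro_sign * B_ud * (CL - Cm))
        dCN = -f * (alpha * i_CN / lam_ud + micro_sign * B_ud * (CN - Cm))
        I_CT = gCT * _sig((v + 63.5) / 1.5) * (1.04 * _sig(-(v + 76.2) / 3.0)) * (v - VC)
        dCm = (f / lam_m) * (
            -alpha * I_CT
            + NL * Gamma * (mCL * mCL * hCL) * (CL - Cm)
            + NN * Gamma * (mCN * hCN) * (CN - Cm)
            - lam_c * kP * Cm
            - lam_c * B_m * (Cm - Cc)
        )

        return [dP, dhP, dmCL, dhCL, dmCN, dhCN, dCL, dCN, dCm, dCc]

    rhs.fields = ASTRO_FIELDS
    return rhs


def astrocyte_rhs(s: AstrocyteState, t, p: ParameterSet, drive: StimulusProtocol, **kw):
    """Single validated derivative evaluation as a field-name dict."""
    s.validate()
    dy = make_astrocyte_rhs(p, drive, **kw)(t, s.to_array())
    return dict(zip(ASTRO_FIELDS, dy))


def astrocyte_release(m_CL, h_CL, m_CN, h_CN, C_L, C_N, C_m, p: ParameterSet):
    """Per-pathway astrocytic release rates (R_CL, R_Cm, R_CN)."""
    wL = m_CL * m_CL * h_CL
    wN = m_CN * m_CN * h_CN
    R_CL = wL * hill(C_L, p.K_L, p.n_L) + (1.0 - wL) * hill(C_m, p.K_L, p.n_L)
    R_Cm = hill(C_m, p.K_m, p.n_m)
    R_CN = wN * hill(C_N, p.K_N, p.n_N) + (1.0 - wN) * hill(C_m, p.K_N, p.n_N)
    return R_CL, R_Cm, R_CN


def astrocyte_resting_state(p: ParameterSet, *, t_relax: float = 120000.0, tol: float = 1e-7, **kw):
    """Unstimulated astrocyte equilibrium found by relaxation."""
    from scipy.integrate import solve_ivp

    rhs = make_astrocyte_rhs(p, StimulusProtocol(), **kw)
    sol = solve_ivp(
        lambda t, y: rhs(t, y),
        (0.0, t_relax),
        AstrocyteState().to_array(),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"astrocyte relaxation failed: {sol.message}")
    y = sol.y[:, -1]
    resid = np.array(rhs(t_relax, y))
    if float(np.max(np.abs(resid) / np.maximum(np.abs(y), 1.0))) > tol:
        raise RuntimeError("astrocyte resting state did not converge")
    return AstrocyteState.from_array(y)
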