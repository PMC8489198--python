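"""Channel-level rate functions and currents.

Covers: Hodgkin-Huxley Na+/K+ rate constants, the microdomain L/N channel
sets parameterised by the explicitly signed table entries, the four
whole-membrane voltage-gated calcium channel types (T, L, N, R) used by the
amyloid-modulated astrocyte, and the TRPM8 thermodynamic gate.

Sign convention: steady-state curves printed with unsigned midpoints are
interpreted with negative midpoints (physiological voltages), activation
slopes positive, inactivation slopes negative.  The per-channel calcium
currents are in pA (nS x mV / count); the whole-membrane VGCC currents are
in fA (pS x mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import GateSpec, boltzmann
from .params import ParameterSet

__all__ = [
    "hh_rates",
    "table1_gate",
    "vgcc_steady",
    "vgcc_tau",
    "vgcc_current",
    "ca_inactivation",
    "microdomain_current",
    "trpm8_open_probability",
    "trpm8_current",
    "ChannelCurrents",
]

_T_SLOW_WEIGHT = 0.04  # weight of the slow T-type inactivation gate


@dataclass(frozen=True)
class ChannelCurrents:
    """Named bundle of instantaneous channel currents."""

    I_CT: float = 0.0
    I_CL: float = 0.0
    I_CN: float = 0.0
    I_CR: float = 0.0
    I_Na: float = 0.0
    I_K: float = 0.0
    I_leak: float = 0.0
    I_m8: float = 0.0


def _exp(x):
    if np.isscalar(x):
        return math.exp(max(min(x, 700.0), -700.0))
    return np.exp(np.clip(x, -700.0, 700.0))


def _vtrap(x, s):
    """x / (1 - exp(-x/s)) with the removable singularity filled by limit s."""
    if np.isscalar(x):
        if abs(x) < 1e-7:
            return s + x / 2.0
        return x / (1.0 - _exp(-x / s))
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-7, s + x / 2.0, x / (1.0 - _exp(-x / s)))
    return out


def hh_rates(v_m, literal: bool = False):
    """Six Hodgkin-Huxley rate constants (1/ms) at membrane voltage v_m.

    Returns (a_mNa, b_mNa, a_hNa, b_hNa, a_mK, b_mK).  ``literal=True``
    evaluates the table strings verbatim (logistic in place of the
    expm1 denominator, beta_mK with the /18 exponent); the default uses the
    classic forms, which reproduce repetitive spiking.
    """
    if literal:
        a_mNa = 0.1 * (v_m + 40.0) * boltzmann(v_m, -40.0, 10.0)
        a_mK = 0.01 * (v_m + 55.0) * boltzmann(v_m, -55.0, 10.0)
        b_mK = 0.125 * _exp(-(v_m + 65.0) / 18.0)
    else:
        a_mNa = 0.1 * _vtrap(v_m + 40.0, 10.0)
        a_mK = 0.01 * _vtrap(v_m + 55.0, 10.0)
        b_mK = 0.125 * _exp(-(v_m + 65.0) / 80.0)
    b_mNa = 4.0 * _exp(-(v_m + 65.0) / 18.0)
    a_hNa = 0.07 * _exp(-(v_m + 65.0) / 20.0)
    b_hNa = boltzmann(v_m, -35.0, 10.0)
    return a_mNa, b_mNa, a_hNa, b_hNa, a_mK, b_mK


def table1_gate(p: ParameterSet, channel: str, gate: str) -> GateSpec:
    """GateSpec for a microdomain channel gate from the signed table entries.

    ``channel`` in {"CL", "CT", "CN"}; ``gate`` in {"m", "h"}.
    """
    g = p[f"V_{gate}_{channel}"], p[f"S_{gate}_{channel}"]
    return GateSpec(
        midpoint=g[0],
        slope=g[1],
        tau_peak=p[f"tau_{gate}_V_{channel}"],
        tau_base=p[f"tau_{gate}0_V_{channel}"],
        tau_midpoint=p[f"V_tau_{gate}_{channel}"],
        tau_slope=p[f"S_tau_{gate}_{channel}"],
        activation=(gate == "m"),
    )


# ---------------------------------------------------------------------------
# Whole-membrane VGCC set (T, L, N, R): explicit steady states and taus.
# Midpoints below carry the interpreted negative sign; inactivation slopes
# are negative.
# ---------------------------------------------------------------------------

_VGCC_STEADY = {
    ("T", "m"): (-63.5, 1.5),
    ("T", "h"): (-76.2, -3.0),  # shared by fast and slow inactivation
    ("L", "m"): (-50.0, 3.0),
    ("N", "m"): (-45.0, 7.0),
    ("R", "m"): (-10.0, 10.0),
    ("R", "h"): (-48.0, -5.0),
}


def vgcc_steady(kind: str, gate: str, v_m):
    """Steady-state activation/inactivation for the whole-membrane VGCCs."""
    try:
        mid, slope = _VGCC_STEADY[(kind, gate)]
    except KeyError:
        raise ValueError(f"no voltage-dependent steady state for {kind}/{gate}") from None
    return boltzmann(v_m, mid, slope)


def vgcc_tau(kind: str, gate: str, v_m):
    """Gaussian-bump time constants (ms) for the whole-membrane VGCCs."""
    v = v_m
    if kind == "T" and gate == "m":
        return 65.0 * _exp(-(((v + 68.0) / 6.0) ** 2)) + 12.0
    if kind == "T" and gate == "hf":
        return 50.0 * _exp(-(((v + 72.0) / 10.0) ** 2)) + 10.0
    if kind == "T" and gate == "hs":
        return 400.0 * _exp(-(((v + 100.0) / 10.0) ** 2)) + 400.0
    if kind == "L" and gate == "m":
        return 18.0 * _exp(-(((v + 45.0) / 20.0) ** 2)) + 1.5
    if kind == "N" and gate == "m":
        return 18.0 * _exp(-(((v + 70.0) / 25.0) ** 2)) + 0.3
    if kind == "R" and gate == "m":
        return 0.1 * _exp(-(((v + 62.0) / 13.0) ** 2)) + 0.05
    if kind == "R" and gate == "h":
        return 0.5 * _exp(-(((v + 55.6) / 18.0) ** 2)) + 0.5
    raise ValueError(f"no time constant for {kind}/{gate}")


def ca_inactivation(kind: str, C_c):
    """Calcium-dependent inactivation of the L/N whole-membrane channels.

    The cytosolic concentration enters in mM (C_c/1000 with C_c in uM), as
    printed.
    """
    if kind == "L":
        return 0.00045 / (0.00045 + C_c / 1000.0)
    if kind == "N":
        return 0.0001 / (0.0001 + C_c / 1000.0)
    raise ValueError(f"no calcium-dependent inactivation for kind {kind!r}")


def vgcc_current(kind: str, v_m, gates, C_c, p: ParameterSet):
    """Whole-membrane VGCC current (fA) for one channel type.

    ``gates`` supplies the dynamic gate states: T -> (m, h_f, h_s),
    L -> (m,), N -> (m,), R -> (m, h).  The L/N inactivation is the
    instantaneous calcium-dependent factor.
    """
    drive = v_m - p.V_C
    if kind == "T":
        m, hf, hs = gates
        return p.g_T_bar * m * (hf + _T_SLOW_WEIGHT * hs) * drive
    if kind == "L":
        (m,) = gates
        return p.g_L_bar * m * ca_inactivation("L", C_c) * drive
    if kind == "N":
        (m,) = gates
        return p.g_N_bar * m * ca_inactivation("N", C_c) * drive
    if kind == "R":
        m, h = gates
        return p.g_R_bar * m * h * drive
    raise ValueError(f"unknown VGCC kind {kind!r}")


def microdomain_current(kind: str, v_m, p: ParameterSet):
    """Single-channel current (pA) feeding one L- or N-type microdomain."""
    if kind == "L":
        return p.g_CL * (v_m - p.V_C) / p.N_L
    if kind == "N":
        return p.g_CN * (v_m - p.V_C) / p.N_N
    raise ValueError(f"unknown microdomain kind {kind!r}")


def trpm8_open_probability(T, v_m, p: ParameterSet):
    """Two-state thermodynamic open probability of the TRPM8 channel.

    Logistic in ((T+273.15)*dS - dH + z*F*v) / (R*(T+273.15)), with the
    membrane voltage converted to volts inside the energy term.  With the
    default (negative) enthalpy/entropy the gate opens on cooling and on
    depolarisation.
    """
    TK = T + 273.15
    if np.any(np.asarray(TK) <= 0):
        raise ValueError("temperature below absolute zero")
    return boltzmann(TK * p.dS, p.dH - p.z_gate * p.F * (v_m / 1000.0), p.R_gas * TK)


def trpm8_current(T, v_m, p: ParameterSet):
    """TRPM8 current g_m8 * a_m8 * (v_m - V_m8), in the membrane units."""
    return p.g_m8 * trpm8_open_probability(T, v_m, p) * (v_m - p.V_m8)
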