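"""Pure algebraic kernels shared by every model variant.

All functions accept floats or numpy arrays and are overflow-safe at extreme
arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["hill", "boltzmann", "bell_tau", "gate_rhs", "GateSpec"]

#: logistic arguments beyond this magnitude saturate to 0/1
_EXP_CLIP = 700.0


def hill(x, K, n):
    """Occupancy fraction x^n / (x^n + K^n).

    Zero at x = 0, one-half at x = K, strictly increasing, < 1 for finite x.
    """
    if np.any(np.asarray(x) < 0):
        raise ValueError("hill: x must be non-negative")
    if not np.all(np.asarray(K) > 0):
        raise ValueError("hill: K must be strictly positive")
    if not np.all(np.asarray(n) > 0):
        raise ValueError("hill: n must be strictly positive")
    if np.isscalar(x) and np.isscalar(K):
        r = (x / K) ** n
        return r / (1.0 + r)
    x = np.asarray(x, dtype=float)
    r = (x / K) ** n
    return r / (1.0 + r)


def _logistic(arg):
    if np.isscalar(arg):
        if arg >= _EXP_CLIP:
            return 1.0
        if arg <= -_EXP_CLIP:
            return 0.0
        return 1.0 / (1.0 + math.exp(-arg))
    arg = np.clip(np.asarray(arg, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(-arg))


def boltzmann(x, vshift, vscale):
    """Logistic gate 1 / (1 + exp(-(x - vshift)/vscale)).

    One-half at x = vshift; monotone in x with the sign of vscale.
    """
    if np.any(np.asarray(vscale) == 0):
        raise ValueError("boltzmann: vscale must be non-zero")
    return _logistic((x - vshift) / vscale)


def gate_rhs(y, y_inf, tau):
    """First-order relaxation rate (y_inf - y)/tau."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("gate_rhs: tau must be strictly positive")
    return (y_inf - y) / tau


@dataclass(frozen=True)
class GateSpec:
    """Boltzmann steady state plus a bell-shaped voltage-dependent tau.

    ``midpoint``/``slope`` parameterise the steady-state curve; the tau curve
    peaks at ``tau_peak/2 + tau_base`` at ``tau_midpoint`` and decays to
    ``tau_base`` for |v| large.
    """

    midpoint: float  # mV
    slope: float  # mV, sign selects activation (+) / inactivation (-)
    tau_peak: float  # ms
    tau_base: float  # ms
    tau_midpoint: float  # mV
    tau_slope: float  # mV
    activation: bool = True

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("GateSpec: slope must be non-zero")
        if self.tau_peak < 0 or self.tau_base < 0:
            raise ValueError("GateSpec: tau parameters must be non-negative")

    def steady(self, v):
        return boltzmann(v, self.midpoint, self.slope)

    def tau(self, v):
        return bell_tau(v, self)

    def rhs(self, y, v):
        return gate_rhs(y, self.steady(v), self.tau(v))


def bell_tau(v, g: GateSpec):
    """Symmetric bell time constant tau_peak / (e^-u + e^u) + tau_base.

    u = (v - tau_midpoint)/tau_slope; the maximum tau_peak/2 + tau_base is
    attained at v = tau_midpoint.
    """
    u = (v - g.tau_midpoint) / g.tau_slope
    if np.isscalar(u):
        if abs(u) > _EXP_CLIP:
            return g.tau_base
        return g.tau_peak / (math.exp(-u) + math.exp(u)) + g.tau_base
    u = np.clip(np.asarray(u, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    return g.tau_peak / (np.exp(-u) + np.exp(u)) + g.tau_base
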