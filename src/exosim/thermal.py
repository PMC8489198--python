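"""Temperature extension: rate scaling, peak conductances, TRPM8 assembly.

The gating-rate multipliers (Q10-style phi factors) apply to the sodium and
potassium gate kinetics only; the peak conductances follow Gaussian
temperature profiles.  By default the Gaussian amplitudes are used as
*normalised* multipliers on the table peak conductances (so the
temperature-independent model is recovered exactly at each Gaussian peak);
``literal_gmax=True`` uses the raw printed amplitudes instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .params import ParameterSet, default_parameters

__all__ = [
    "ThermalConfig",
    "TemperatureRamp",
    "phi_factors",
    "peak_conductances",
    "conductance_factors",
    "thermal_neuron_rhs",
]

_DEF = default_parameters()


def phi_factors(T, p: ParameterSet = _DEF):
    """Gating-rate multipliers (phi_mK, phi_mNa, phi_hNa) at temperature T."""
    e = (T - 20.0) / 10.0
    return (
        p.phi_mK_pref * p.phi_mK_q10**e,
        p.phi_mNa_pref * p.phi_mNa_q10**e,
        p.phi_hNa_pref * p.phi_hNa_q10**e,
    )


def peak_conductances(T, p: ParameterSet = _DEF):
    """Raw Gaussian peak-conductance curves (g_K_max, g_Na_max) at T (degC)."""
    gk = p.gK_max_amp * math.exp(-(((T - p.gK_max_T0) / p.gK_max_sigma) ** 2))
    gna = p.gNa_max_amp * math.exp(-(((T - p.gNa_max_T0) / p.gNa_max_sigma) ** 2))
    return gk, gna


def conductance_factors(T, p: ParameterSet = _DEF):
    """Normalised multipliers on the table peak conductances (1 at the peaks)."""
    gk, gna = peak_conductances(T, p)
    return gk / p.gK_max_amp, gna / p.gNa_max_amp


@dataclass(frozen=True)
class TemperatureRamp:
    """Piecewise-linear temperature schedule.

    legs=1: T_start -> T_end over ``leg_ms``.
    legs=2: there and back (T_start -> T_end -> T_start), ``leg_ms`` each way.
    Outside the ramp the temperature holds the boundary value.
    """

    T_start: float
    T_end: float
    leg_ms: float
    legs: int = 2
    t0: float = 0.0

    def __post_init__(self):
        if self.leg_ms <= 0:
            raise ValueError("ramp leg duration must be positive")
        if self.legs not in (1, 2):
            raise ValueError("legs must be 1 or 2")
        if min(self.T_start, self.T_end) <= -273.15:
            raise ValueError("temperature below absolute zero")

    def temperature(self, t: float) -> float:
        u = (t - self.t0) / self.leg_ms
        if u <= 0.0:
            return self.T_start
        if u <= 1.0:
            return self.T_start + (self.T_end - self.T_start) * u
        if self.legs == 1 or u >= 2.0:
            return self.T_end if self.legs == 1 else self.T_start
        return self.T_end + (self.T_start - self.T_end) * (u - 1.0)


@dataclass(frozen=True)
class ThermalConfig:
    """Temperature handling for a run.

    mode: "off" (temperature-independent model), "constant", or "ramp".
    """

    mode: str = "off"
    T: float = 20.0
    ramp: Optional[TemperatureRamp] = None
    trpm8_enabled: bool = False
    g_m8: Optional[float] = None  # overrides the registry value when set
    literal_gmax: bool = False

    def __post_init__(self):
        if self.mode not in ("off", "constant", "ramp"):
            raise ValueError(f"unknown thermal mode {self.mode!r}")
        if self.mode == "ramp" and self.ramp is None:
            raise ValueError("ramp mode requires a TemperatureRamp")
        if self.mode == "constant" and self.T <= -273.15:
            raise ValueError("temperature below absolute zero")

    @property
    def active(self) -> bool:
        return self.mode != "off"

    def temperature(self, t: float) -> float:
        if self.mode == "ramp":
            return self.ramp.temperature(t)
        return self.T


def thermal_neuron_rhs(s, t, p: ParameterSet, drive, th: ThermalConfig):
    """Single evaluation of the temperature-dependent neuron derivative."""
    from .neuron import neuron_rhs

    return neuron_rhs(s, t, p, drive, thermal=th)
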