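"""Time-dependent drive: current pulses, astrocyte depolarisation steps,
temperature schedule."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .thermal import ThermalConfig

__all__ = ["Pulse", "StimulusProtocol"]


@dataclass(frozen=True)
class Pulse:
    """A rectangular pulse: active on [start, start + duration)."""

    start: float  # ms
    duration: float  # ms
    amplitude: float  # uA/cm^2 for current pulses, mV for v_ind steps

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def value(self, t: float) -> float:
        return self.amplitude if self.start <= t < self.end else 0.0


def _check_disjoint(pulses: Sequence[Pulse], what: str):
    ordered = sorted(pulses, key=lambda q: q.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping {what} pulses at t={b.start} ms")


@dataclass(frozen=True)
class StimulusProtocol:
    """Externally applied drive for one run."""

    pulses: tuple[Pulse, ...] = ()  # induced current I_ind
    v_ind: tuple[Pulse, ...] = ()  # astrocyte depolarisation steps
    thermal: ThermalConfig = field(default_factory=ThermalConfig)

    def __post_init__(self):
        object.__setattr__(self, "pulses", tuple(self.pulses))
        object.__setattr__(self, "v_ind", tuple(self.v_ind))
        _check_disjoint(self.pulses, "current")
        _check_disjoint(self.v_ind, "v_ind")

    def I_ind(self, t: float) -> float:
        for q in self.pulses:
            if q.start <= t < q.end:
                return q.amplitude
        return 0.0

    def v_ind_at(self, t: float) -> float:
        for q in self.v_ind:
            if q.start <= t < q.end:
                return q.amplitude
        return 0.0

    def v_ind_active(self, t: float) -> bool:
        return any(q.start <= t < q.end for q in self.v_ind)

    def temperature(self, t: float) -> Optional[float]:
        return self.thermal.temperature(t) if self.thermal.active else None

    def breakpoints(self, t_max: float) -> list[float]:
        """Drive discontinuity times within [0, t_max] (for grid alignment)."""
        ts = {0.0, float(t_max)}
        for q in (*self.pulses, *self.v_ind):
            for x in (q.start, q.end):
                if 0.0 < x < t_max:
                    ts.add(float(x))
        return sorted(ts)
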