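"""Post-processing: spike detection, oscillation metrics, release accounting,
and tabular writers."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = [
    "SpikeTrain",
    "ReleaseBreakdown",
    "detect_spikes",
    "release_breakdown",
    "oscillation_metrics",
    "dominant_frequency",
    "write_result",
    "read_result",
]


@dataclass(frozen=True)
class SpikeTrain:
    times: np.ndarray  # ms, strictly increasing
    amplitudes: np.ndarray  # mV, peak values

    @property
    def count(self) -> int:
        return len(self.times)

    @property
    def mean_isi(self) -> float:
        return float(np.mean(np.diff(self.times))) if self.count > 1 else float("nan")

    @property
    def mean_amplitude(self) -> float:
        return float(np.mean(self.amplitudes)) if self.count else float("nan")


@dataclass(frozen=True)
class ReleaseBreakdown:
    """Cumulative per-pathway release over a window (rate x ms, dimensionless
    'released amount' in arbitrary units) and fractional contributions."""

    window: tuple[float, float]
    cumulative: dict[str, float]
    fractions: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.cumulative.values())


def detect_spikes(t, v, threshold: float = 0.0, refractory: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings separated by at least ``refractory`` ms."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("time and voltage traces must align")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times, amps = [], []
    last = -np.inf
    for i in up:
        tc = t[i + 1]
        if tc - last < refractory:
            continue
        last = tc
        # peak amplitude within the refractory window after the crossing
        j = np.searchsorted(t, tc + refractory)
        amps.append(float(np.max(v[i : max(j, i + 1)])))
        times.append(float(tc))
    return SpikeTrain(np.asarray(times), np.asarray(amps))


def _window_slice(t, window):
    a, b = window
    if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside simulated range [{t[0]}, {t[-1]}]")
    i = np.searchsorted(t, a, side="left")
    j = np.searchsorted(t, b, side="right")
    if j - i < 2:
        raise ValueError("window contains fewer than two samples")
    return slice(i, j)


def release_breakdown(result: SimulationResult, window=None, pathways: Sequence[str] = ("R_CL", "R_Cm", "R_CN")) -> ReleaseBreakdown:
    """Trapezoidal per-pathway release integrals and fractions of the total."""
    t = result.t
    if window is None:
        window = (float(t[0]), float(t[-1]))
    sl = _window_slice(t, window)
    present = [n for n in pathways if n in result.columns]
    if not present:
        raise ValueError("result contains no release-rate traces")
    cumulative = {
        n: float(np.trapezoid(result.trace(n)[sl], t[sl])) for n in present
    }
    total = sum(cumulative.values())
    fractions = {n: (c / total if total > 0 else 0.0) for n, c in cumulative.items()}
    return ReleaseBreakdown(window=tuple(map(float, window)), cumulative=cumulative, fractions=fractions)


def oscillation_metrics(t, x, window=None, min_prominence_frac: float = 0.05):
    """(amplitude, frequency_Hz, baseline) of an oscillatory trace.

    Peaks are counted with a prominence threshold relative to the trace
    range; a trace with fewer than two peaks reports zeros with the trace
    mean as baseline.
    """
    from scipy.signal import find_peaks

    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if window is not None:
        sl = _window_slice(t, window)
        t, x = t[sl], x[sl]
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        return 0.0, 0.0, float(np.mean(x))
    prom = min_prominence_frac * rng
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    if len(peaks) < 2:
        return 0.0, 0.0, float(np.mean(x))
    amp = float(np.mean(x[peaks]) - (np.mean(x[troughs]) if len(troughs) else np.min(x)))
    span_ms = float(t[peaks[-1]] - t[peaks[0]])
    freq = (len(peaks) - 1) / span_ms * 1000.0 if span_ms > 0 else 0.0
    baseline = float(np.mean(x[troughs])) if len(troughs) else float(np.min(x))
    return amp, freq, baseline


def dominant_frequency(t, x, window=None) -> float:
    """Dominant non-DC spectral component (Hz) of a uniformly sampled trace."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if window is not None:
        sl = _window_slice(t, window)
        t, x = t[sl], x[sl]
    dt = float(np.median(np.diff(t)))
    x = x - np.mean(x)
    if np.allclose(x, 0.0):
        return 0.0
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    freqs = np.fft.rfftfreq(len(x), d=dt / 1000.0)
    return float(freqs[1:][np.argmax(spec[1:])])


def write_result(result: SimulationResult, path, fmt: str = "csv") -> Path:
    """Write traces (CSV or JSON) plus a JSON metadata sidecar.

    The CSV carries a header row ``t_ms, v_m_mV?, <columns...>``; reading it
    back reproduces the arrays exactly (full float precision).
    """
    path = Path(path)
    df = pd.DataFrame({"t_ms": result.t})
    for name in result.fields:
        col = f"{name}_mV" if name == "v_m" else name
        df[col] = result.trace(name)
    for name in result.derived:
        df[name] = result.derived[name]
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        path.write_text(json.dumps({c: df[c].tolist() for c in df.columns}))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(result.metadata, indent=2, default=str))
    return path


def read_result(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)
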