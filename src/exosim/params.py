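"""Central registry of model constants.

Every constant used by any model variant lives here, with a unit tag and a
provenance string.  Values are stored in their *printed* units (the units in
which they are reported in the source tables); :meth:`ParameterSet.canonical`
converts every rate-like quantity onto the single internal time base of
milliseconds before the integrators consume them.

Two constants share the printed name ``a2``; they are disambiguated by the
equation that consumes them (``a2_in``: plasma-membrane leak slope, per
second; ``a2_ip3r``: IP3-receptor inactivation rate, per uM per second) and
any attempt to override the bare name ``a2`` is rejected.  The same guard
applies to the bare name ``z`` (``z_gate``: channel gating charge 0.87;
``z_Ca``: calcium valence 2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ParamInfo",
    "ParameterSet",
    "ParameterError",
    "UnknownParameterError",
    "AmbiguousParameterError",
    "PositivityError",
    "default_parameters",
    "load_overrides",
    "canonical_units",
    "ASSUMPTIONS",
]

MS_PER_S = 1000.0


class ParameterError(ValueError):
    """Base class for registry validation failures."""


class UnknownParameterError(ParameterError):
    pass


class AmbiguousParameterError(ParameterError):
    pass


class PositivityError(ParameterError):
    pass


@dataclass(frozen=True)
class ParamInfo:
    """Metadata describing one registry entry."""

    value: float
    unit: str
    where: str
    positive: bool = False
    nonnegative: bool = False
    per_second: bool = False  # printed on a per-second base; /1000 on canonicalisation
    derived: bool = False


def _p(value, unit, where, **kw):
    return ParamInfo(float(value), unit, where, **kw)


# ---------------------------------------------------------------------------
# The registry.  "T1"/"T2" provenance = parameter tables; "sec2.x" = text of
# the corresponding methods subsection; "assumed" = no printed value exists.
# ---------------------------------------------------------------------------
_TABLE: dict[str, ParamInfo] = {
    # -- membrane electrical constants -------------------------------------
    "V_K": _p(-70.0, "mV", "T1"),
    "V_Na": _p(50.0, "mV", "T1"),
    "V_L": _p(-54.4, "mV", "T1"),
    "V_C": _p(65.0, "mV", "T1 (listed twice, stored once)"),
    "g_K_bar": _p(36.0, "mS/cm^3", "T1", positive=True),
    "g_Na_bar": _p(120.0, "mS/cm^3", "T1", positive=True),
    "g_L": _p(0.3, "mS/cm^3", "T1", positive=True),
    "c_m": _p(1.0, "uF/cm^2", "T1", positive=True),
    # -- calcium compartment constants -------------------------------------
    "f": _p(0.01, "1", "T1", positive=True),
    "alpha": _p(5e-15, "umol/(pA*ms)", "T1 (current-to-flux factor ~ 1/(2F))", nonnegative=True),
    "lambda_ud": _p(2.62e-19, "L", "T1", positive=True),
    "lambda_m": _p(5e-14, "L", "T1", positive=True),
    "lambda_c": _p(5.7e-13, "L", "T1", positive=True),
    "lambda_c_over_lambda_r": _p(31.0, "1", "T1", positive=True),
    "lambda_r": _p(5.7e-13 / 31.0, "L", "derived: lambda_c / 31", positive=True, derived=True),
    "lambda_ast": _p(3.49e-13, "L", "T1", positive=True),
    "B_ud": _p(264.0, "ms^-1", "T1", positive=True),
    "B_m": _p(0.128, "ms^-1", "T1", positive=True),
    "k_PMCA": _p(0.300, "ms^-1", "T1", nonnegative=True),
    "k_SERCA": _p(0.100, "ms^-1", "T1", positive=True),
    "p_leak": _p(3e-4, "ms^-1", "T1", positive=True),
    "N_L": _p(200, "channels", "T1", positive=True),
    "N_N": _p(200, "channels", "T1", positive=True),
    # -- release (Hill) constants ------------------------------------------
    "K_L": _p(50.0, "uM", "T1", positive=True),
    "K_m": _p(2.0, "uM", "T1", positive=True),
    "K_N": _p(2.0, "uM", "T1", positive=True),
    "n_L": _p(4.0, "1", "T1", positive=True),
    "n_m": _p(4.0, "1", "T1", positive=True),
    "n_N": _p(4.0, "1", "T1", positive=True),
    # -- microdomain channel-set conductances ------------------------------
    "g_CT": _p(0.4, "nS", "T1", positive=True),
    "g_CL": _p(0.7, "nS", "T1", positive=True),
    "g_CN": _p(0.6, "nS", "T1", positive=True),
    # -- Boltzmann gate constants (explicitly signed entries) --------------
    "V_m_CL": _p(-30.0, "mV", "T1"),
    "S_m_CL": _p(10.0, "mV", "T1"),
    "V_h_CL": _p(-33.0, "mV", "T1"),
    "S_h_CL": _p(-5.0, "mV", "T1"),
    "tau_m_V_CL": _p(1.0, "ms", "T1", nonnegative=True),
    "tau_m0_V_CL": _p(0.05, "ms", "T1", nonnegative=True),
    "V_tau_m_CL": _p(-23.0, "mV", "T1"),
    "S_tau_m_CL": _p(20.0, "mV", "T1"),
    "tau_h_V_CL": _p(60.0, "ms", "T1", nonnegative=True),
    "tau_h0_V_CL": _p(51.0, "ms", "T1", nonnegative=True),
    "V_tau_h_CL": _p(0.0, "mV", "T1"),
    "S_tau_h_CL": _p(20.0, "mV", "T1"),
    "V_m_CT": _p(-49.0, "mV", "T1"),
    "S_m_CT": _p(4.0, "mV", "T1"),
    "V_h_CT": _p(-52.0, "mV", "T1"),
    "S_h_CT": _p(-5.0, "mV", "T1"),
    "tau_m_V_CT": _p(15.0, "ms", "T1", nonnegative=True),
    "tau_m0_V_CT": _p(0.0, "ms", "T1", nonnegative=True),
    "V_tau_m_CT": _p(-50.0, "mV", "T1"),
    "S_tau_m_CT": _p(12.0, "mV", "T1"),
    "tau_h_V_CT": _p(20.0, "ms", "T1", nonnegative=True),
    "tau_h0_V_CT": _p(5.0, "ms", "T1", nonnegative=True),
    "V_tau_h_CT": _p(-50.0, "mV", "T1"),
    "S_tau_h_CT": _p(15.0, "mV", "T1"),
    "V_m_CN": _p(-5.0, "mV", "T1"),
    "S_m_CN": _p(10.0, "mV", "T1"),
    "V_h_CN": _p(33.0, "mV", "T1"),
    "S_h_CN": _p(-5.0, "mV", "T1"),
    "tau_m_V_CN": _p(1.0, "ms", "T1", nonnegative=True),
    "tau_m0_V_CN": _p(0.05, "ms", "T1", nonnegative=True),
    "V_tau_m_CN": _p(-23.0, "mV", "T1"),
    "S_tau_m_CN": _p(20.0, "mV", "T1"),
    "tau_h_V_CN": _p(60.0, "ms", "T1", nonnegative=True),
    "tau_h0_V_CN": _p(51.0, "ms", "T1", nonnegative=True),
    "V_tau_h_CN": _p(0.0, "mV", "T1"),
    "S_tau_h_CN": _p(20.0, "mV", "T1"),
    # -- IP3 / ER dynamics (astrocyte) -------------------------------------
    "c0": _p(2.0, "uM", "T1", positive=True),
    "c1": _p(0.185, "1", "T1", positive=True),
    "v1": _p(6.0, "s^-1", "T1", positive=True, per_second=True),
    "v2": _p(0.11, "s^-1", "T1", positive=True, per_second=True),
    "v3": _p(0.9, "uM/s", "T1", positive=True, per_second=True),
    "k3": _p(0.1, "uM", "T1", positive=True),
    "d1": _p(0.13, "uM", "T1", positive=True),
    "d2": _p(1.049, "uM", "T1", positive=True),
    "d3": _p(0.943, "uM", "T1", positive=True),
    "d5": _p(0.082, "uM", "T1", positive=True),
    "d6": _p(1.0, "1", "sec2.2 text (Hill exponent)", positive=True),
    "a2_ip3r": _p(0.5, "1/(uM*s)", "T1 ('a2' row with uM*s units)", positive=True, per_second=True),
    "IP3_0": _p(0.160, "uM", "T1", positive=True),
    "r_P": _p(0.04, "uM/s", "T1", positive=True, per_second=True),
    "tau_P": _p(1.0 / 0.000140, "ms", "T1 (printed 1/0.000140 ms)", positive=True),
    "V_m_ast": _p(-70.0, "mV", "T1 / sec2.2 (astrocyte resting potential)"),
    "A_astro": _p(2.11, "uA/cm^2", "sec2.3", nonnegative=True),
    # -- amyloid-beta flux network -----------------------------------------
    "M_CICR": _p(10.0, "s^-1", "T1", positive=True, per_second=True),
    "M_SERCA": _p(15.0, "uM/s", "T1", positive=True, per_second=True),
    "M_PLC": _p(0.05, "uM/s", "T1 (listed twice, stored once)", positive=True, per_second=True),
    "P_SERCA": _p(0.1, "uM", "T1 (printed unit uM/s; half-saturation, uM)", positive=True),
    "P_PC": _p(0.3, "uM", "T1 (printed unit uM/s; half-saturation, uM)", positive=True),
    "P_CA": _p(0.15, "uM", "T1 (printed unit uM/s; half-saturation, uM)", positive=True),
    "P_CI": _p(0.15, "uM", "T1", positive=True),
    "P_IP3": _p(0.1, "uM", "T1", positive=True),
    "P_deg": _p(0.08, "s^-1", "T1", positive=True, per_second=True),
    "P_f": _p(0.01, "s^-1", "T1", positive=True, per_second=True),
    "k1": _p(0.013, "s^-1", "T1", positive=True, per_second=True),
    "k2": _p(0.18, "s^-1", "T1", positive=True, per_second=True),
    "k_d": _p(0.13, "uM", "T1", positive=True),
    "a1": _p(0.003, "uM/s", "T1", positive=True, per_second=True),
    "a2_in": _p(0.02, "s^-1", "T1 ('a2' row, dimensionless-slope reading)", nonnegative=True, per_second=True),
    "n1": _p(2.02, "1", "T1", positive=True),
    "n2": _p(2.2, "1", "T1", positive=True),
    "n3": _p(3.0, "1", "T1", positive=True),
    "n4": _p(2.0, "1", "T1", positive=True),
    "n5": _p(3.5, "1", "T1", positive=True),
    "lambda_PM": _p(4.2, "uM/s", "T1", positive=True, per_second=True),
    "K_pm": _p(1.5, "uM", "assumed: no printed value (flagged in run metadata)", positive=True),
    "A_VL": _p(1.0, "1", "T1", nonnegative=True),
    "A_RyR": _p(1.0, "1", "T1", nonnegative=True),
    "A_m": _p(1.0, "1", "T1", nonnegative=True),
    "A_in": _p(1.0, "uM/s", "T1", nonnegative=True, per_second=True),
    # -- whole-membrane VGCC peak conductances -----------------------------
    "g_T_bar": _p(0.0600, "pS", "T1", positive=True),
    "g_L_bar": _p(3.5000, "pS", "T1", positive=True),
    "g_N_bar": _p(0.3900, "pS", "T1", positive=True),
    "g_R_bar": _p(0.2225, "pS", "T1", positive=True),
    # -- TRPM8 thermodynamic gate ------------------------------------------
    "dH": _p(-156e3, "J/mol", "T1 (printed -156 kJ/mol)"),
    "dS": _p(-550.0, "J/(mol*K)", "T1"),
    "z_gate": _p(0.87, "e", "T1 ('z' row; gating charge)"),
    "z_Ca": _p(2.0, "1", "calcium valence (current-to-flux conversion)", positive=True),
    "F": _p(96485.0, "C/mol", "T1", positive=True),
    "R_gas": _p(8.3144, "J/(mol*K)", "T1 ('R' row)", positive=True),
    "g_m8": _p(0.0, "mS/cm^2", "sec2.4 (0 disables TRPM8; scenarios set 3/5/10)", nonnegative=True),
    "V_m8": _p(0.0, "mV", "sec2.4 (reversal potential ~ 0 mV)"),
    # -- temperature dependence of peak conductances and gating rates ------
    "gK_max_amp": _p(1.60, "1 (normalised multiplier)", "sec2.4", positive=True),
    "gK_max_T0": _p(27.88, "degC", "sec2.4"),
    "gK_max_sigma": _p(12.85, "degC", "sec2.4", positive=True),
    "gNa_max_amp": _p(0.42, "1 (normalised multiplier)", "sec2.4", positive=True),
    "gNa_max_T0": _p(31.83, "degC", "sec2.4"),
    "gNa_max_sigma": _p(31.62, "degC", "sec2.4", positive=True),
    "phi_mK_pref": _p(4.3518, "1", "sec2.4", positive=True),
    "phi_mK_q10": _p(2.7, "1", "sec2.4", positive=True),
    "phi_mNa_pref": _p(4.4288, "1", "sec2.4", positive=True),
    "phi_mNa_q10": _p(3.0, "1", "sec2.4", positive=True),
    "phi_hNa_pref": _p(3.8923, "1", "sec2.4", positive=True),
    "phi_hNa_q10": _p(2.3, "1", "sec2.4", positive=True),
    "T_default": _p(10.0, "degC", "T1 ('T' row)"),
}

#: printed names that map onto more than one registry field
_AMBIGUOUS: dict[str, tuple[str, ...]] = {
    "a2": ("a2_in", "a2_ip3r"),
    "z": ("z_gate", "z_Ca"),
}

#: modelling choices that have no printed backing; echoed into run metadata
ASSUMPTIONS: tuple[str, ...] = (
    "K_pm has no printed value; default 1.5 uM (override via config)",
    "IP3 production baseline P0 identified with IP3_0 = 0.160 uM",
    "current-to-flux factor alpha applied to currents in pA on the ms time base",
    "printed 'z' = 0.87 used as TRPM8 gating charge; valence 2 used for ionic flux conversion",
    "Boltzmann midpoints printed unsigned are interpreted as negative (vshift = -printed); "
    "inactivation gates take negative slope",
    "mass-conserving sign convention for microdomain and ER exchange (see literal_signs flag)",
)


class ParameterSet:
    """Immutable named registry of model constants.

    Attribute access returns plain floats (``p.K_L``); :meth:`info` exposes
    unit and provenance.  ``canonical=True`` sets indicate that per-second
    rates have been rescaled to the millisecond time base.
    """

    __slots__ = ("_values", "_canonical")

    def __init__(self, values: Mapping[str, float], canonical: bool = False):
        object.__setattr__(self, "_values", dict(values))
        object.__setattr__(self, "_canonical", bool(canonical))

    # -- mapping-ish surface ------------------------------------------------
    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(f"no parameter named {name!r}") from None

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("ParameterSet is immutable; use replace()")

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self._values == other._values
            and self._canonical == other._canonical
        )

    @property
    def is_canonical(self) -> bool:
        return self._canonical

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    @staticmethod
    def info(name: str) -> ParamInfo:
        """Unit/provenance metadata for a field (printed-unit values)."""
        if name in _AMBIGUOUS:
            raise AmbiguousParameterError(
                f"{name!r} is ambiguous; use one of {_AMBIGUOUS[name]}"
            )
        try:
            return _TABLE[name]
        except KeyError:
            raise UnknownParameterError(f"unknown parameter {name!r}") from None

    @staticmethod
    def conversion_factors() -> dict[str, float]:
        """Printed-unit -> canonical-unit multiplicative factors."""
        return {k: 1.0 / MS_PER_S for k, i in _TABLE.items() if i.per_second}

    def hash(self) -> str:
        payload = json.dumps(
            {"canonical": self._canonical, "values": self._values}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- construction and transformation -----------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields replaced, after validation."""
        values = dict(self._values)
        for name, value in overrides.items():
            if name in _AMBIGUOUS:
                raise AmbiguousParameterError(
                    f"parameter name {name!r} is ambiguous: choose one of "
                    f"{', '.join(_AMBIGUOUS[name])}"
                )
            if name not in _TABLE:
                raise UnknownParameterError(f"unknown parameter {name!r}")
            info = _TABLE[name]
            if info.derived:
                raise ParameterError(
                    f"{name!r} is derived (override lambda_c or the ratio instead)"
                )
            value = float(value)
            if info.positive and not value > 0:
                raise PositivityError(f"{name} must be strictly positive, got {value}")
            if info.nonnegative and value < 0:
                raise PositivityError(f"{name} must be non-negative, got {value}")
            values[name] = value
        values["lambda_r"] = values["lambda_c"] / values["lambda_c_over_lambda_r"]
        return ParameterSet(values, canonical=self._canonical)

    def canonical(self) -> "ParameterSet":
        """Rescale all per-second rates onto the millisecond time base."""
        if self._canonical:
            return self
        values = dict(self._values)
        for name, factor in self.conversion_factors().items():
            values[name] = values[name] * factor
        return ParameterSet(values, canonical=True)

    def to_printed(self) -> "ParameterSet":
        """Inverse of :meth:`canonical`: report fields in printed units."""
        if not self._canonical:
            return self
        values = dict(self._values)
        for name, factor in self.conversion_factors().items():
            values[name] = values[name] / factor
        return ParameterSet(values, canonical=False)


def default_parameters() -> ParameterSet:
    """The complete registry populated from the parameter tables."""
    return ParameterSet({k: i.value for k, i in _TABLE.items()})


def _flatten(mapping: Mapping, prefix: str = "") -> dict[str, float]:
    out: dict[str, float] = {}
    for key, value in mapping.items():
        if isinstance(value, Mapping):
            out.update(_flatten(value))
        else:
            out[str(key)] = value
    return out


def load_overrides(source) -> ParameterSet:
    """Defaults with fields replaced from a config document.

    ``source`` may be a mapping, a YAML string, or a path to a YAML file.
    Sectioned documents are flattened; keys must be canonical field names.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ParameterError("config document must be a key->value mapping")
    elif isinstance(source, Mapping):
        data = source
    else:
        raise ParameterError(f"unsupported config source {type(source).__name__}")
    return default_parameters().replace(**_flatten(data))


def canonical_units(p: ParameterSet) -> ParameterSet:
    """Functional alias for :meth:`ParameterSet.canonical`."""
    return p.canonical()
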