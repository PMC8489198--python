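"""Deterministic integration of every model variant plus the scenario
registry reproducing the simulation experiments.

The default integrator is fixed-step classical RK4 at dt = 0.01 ms (fine
enough to resolve action potentials); an adaptive stiff-capable method
(LSODA, via scipy) serves both the slow amyloid/IP3 scenarios and as an
independent cross-check of the fixed-step results.  Stimulus discontinuities
are aligned with segment boundaries for both integrators.  There is no
randomness anywhere; a seed, when supplied, is recorded in the run metadata
and otherwise unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import abeta as _ab
from . import astrocyte as _as
from . import neuron as _ne
from .abeta import ABETA_FIELDS, MICRO_FIELDS, AbetaConfig, make_abeta_rhs, make_coupled_rhs
from .astrocyte import ASTRO_FIELDS, AstrocyteState, astrocyte_release, make_astrocyte_rhs
from .channels import ca_inactivation
from .neuron import NEURON_FIELDS, NeuronState, make_neuron_rhs, neuron_release
from .params import ASSUMPTIONS, ParameterSet, default_parameters
from .protocol import Pulse, StimulusProtocol
from .thermal import TemperatureRamp, ThermalConfig

__all__ = [
    "SimulationResult",
    "ModelSpec",
    "IntegratorOptions",
    "InstabilityError",
    "UnknownScenarioError",
    "build_model",
    "integrate",
    "scenario",
    "scenario_names",
    "run_scenario",
    "sweep",
]

_STATE_PACKING_VERSION = 1


class InstabilityError(RuntimeError):
    def __init__(self, t_last: float):
        super().__init__(f"state became non-finite; last finite time t = {t_last:.6g} ms")
        self.t_last = t_last


class UnknownScenarioError(KeyError):
    pass


@dataclass(frozen=True)
class IntegratorOptions:
    method: str = "rk4"  # "rk4" or any scipy solve_ivp method name
    dt: float = 0.01  # ms; fixed step / output grid spacing
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_every: int = 1  # store every n-th fixed step

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass
class SimulationResult:
    t: np.ndarray  # ms, strictly increasing
    fields: tuple[str, ...]
    states: np.ndarray  # (len(t), len(fields))
    derived: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.states.shape != (len(self.t), len(self.fields)):
            raise ValueError("trace shape does not match grid/fields")
        if len(set(self.fields)) != len(self.fields):
            raise ValueError("duplicate state column names")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def trace(self, name: str) -> np.ndarray:
        if name in self.fields:
            return self.states[:, self.fields.index(name)]
        return self.derived[name]

    @property
    def columns(self) -> list[str]:
        return list(self.fields) + list(self.derived)


@dataclass
class ModelSpec:
    """A fully specified runnable configuration."""

    variant: str
    rhs: Callable
    fields: tuple[str, ...]
    y0: np.ndarray
    params: ParameterSet
    protocol: StimulusProtocol
    derived: Optional[Callable] = None  # (t, Y) -> dict of extra traces
    cfg: Optional[AbetaConfig] = None
    t_max: float = 700.0
    opts: IntegratorOptions = field(default_factory=IntegratorOptions)
    name: str = ""
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _rk4(rhs, y0, t0, t1, dt, stride, ts_out, ys_out):
    """Fixed-step RK4 over [t0, t1]; appends samples to the output lists."""
    n = int(round((t1 - t0) / dt))
    n = max(n, 1)
    h = (t1 - t0) / n
    y = list(map(float, y0))
    half = 0.5 * h
    sixth = h / 6.0
    for i in range(n):
        t = t0 + i * h
        try:
            k1 = rhs(t, y)
            k2 = rhs(t + half, [yi + half * ki for yi, ki in zip(y, k1)])
            k3 = rhs(t + half, [yi + half * ki for yi, ki in zip(y, k2)])
            k4 = rhs(t + h, [yi + h * ki for yi, ki in zip(y, k3)])
        except (OverflowError, ValueError) as err:
            raise InstabilityError(t) from err
        y = [
            yi + sixth * (a + 2.0 * (b + c) + d)
            for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
        ]
        v = y[0]
        if not (-1e7 < v < 1e7):  # catches NaN and blow-up cheaply
            raise InstabilityError(t)
        if (i + 1) % stride == 0 or i == n - 1:
            if not all(map(math.isfinite, y)):
                raise InstabilityError(t)
            ts_out.append(t + h)
            ys_out.append(list(y))
    return y


def integrate(model: ModelSpec, t_max: Optional[float] = None, opts: Optional[IntegratorOptions] = None) -> SimulationResult:
    """Integrate a model over [0, t_max] and assemble the result traces."""
    t_max = float(model.t_max if t_max is None else t_max)
    opts = opts or model.opts
    y0 = np.asarray(model.y0, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state contains non-finite values")

    ts: list[float] = [0.0]
    ys: list[Sequence[float]] = [list(map(float, y0))]
    if t_max > 0:
        edges = model.protocol.breakpoints(t_max)
        y = list(map(float, y0))
        if opts.method == "rk4":
            for a, b in zip(edges, edges[1:]):
                # clamp stage times into the half-open segment so the final
                # k4 stage does not sample the drive across a discontinuity
                b_in = b - 1e-9
                seg_rhs = lambda t, yy, _b=b_in: model.rhs(min(t, _b), yy)
                y = _rk4(seg_rhs, y, a, b, opts.dt, opts.sample_every, ts, ys)
        else:
            from scipy.integrate import solve_ivp

            for a, b in zip(edges, edges[1:]):
                grid = np.arange(a, b, opts.dt * opts.sample_every)[1:]
                t_eval = np.append(grid, b)
                b_in = b - 1e-9
                sol = solve_ivp(
                    lambda t, yy, _b=b_in: model.rhs(min(t, _b), yy),
                    (a, b),
                    y,
                    method=opts.method,
                    rtol=opts.rtol,
                    atol=opts.atol,
                    t_eval=t_eval,
                    dense_output=False,
                )
                if not sol.success:
                    raise InstabilityError(float(sol.t[-1]) if len(sol.t) else a)
                ts.extend(sol.t.tolist())
                ys.extend(sol.y.T.tolist())
                y = list(map(float, sol.y[:, -1]))
                if not all(map(math.isfinite, y)):
                    raise InstabilityError(float(sol.t[-1]))

    t = np.asarray(ts)
    Y = np.asarray(ys)
    # drop duplicated segment-edge samples
    keep = np.concatenate(([True], np.diff(t) > 1e-12))
    t, Y = t[keep], Y[keep]

    derived = model.derived(t, Y) if model.derived is not None else {}
    meta = {
        "variant": model.variant,
        "scenario": model.name,
        "state_packing": list(model.fields),
        "packing_version": _STATE_PACKING_VERSION,
        "params_hash": model.params.hash(),
        "integrator": {
            "method": opts.method,
            "dt": opts.dt,
            "rtol": opts.rtol,
            "atol": opts.atol,
            "sample_every": opts.sample_every,
        },
        "t_max": t_max,
        "abeta": None
        if model.cfg is None
        else {
            "l": model.cfg.l,
            "A_VL": model.cfg.A_VL,
            "A_RyR": model.cfg.A_RyR,
            "A_m": model.cfg.A_m,
            "A_in": model.cfg.A_in,
        },
        "assumptions": list(ASSUMPTIONS) + list(model.notes),
    }
    return SimulationResult(t=t, fields=model.fields, states=Y, derived=derived, metadata=meta)


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

_REST_CACHE: dict = {}


def _neuron_rest(p: ParameterSet, **kw) -> NeuronState:
    key = ("neuron", p.hash(), tuple(sorted(kw.items())))
    if key not in _REST_CACHE:
        _REST_CACHE[key] = _ne.resting_state(p, **kw)
    return _REST_CACHE[key]


def _astro_rest(p: ParameterSet) -> AstrocyteState:
    key = ("astro", p.hash())
    if key not in _REST_CACHE:
        _REST_CACHE[key] = _as.astrocyte_resting_state(p)
    return _REST_CACHE[key]


def _neuron_derived(p: ParameterSet):
    i_mCL = NEURON_FIELDS.index("m_CL")
    i_hCL = NEURON_FIELDS.index("h_CL")
    i_CL = NEURON_FIELDS.index("C_L")
    i_Cm = NEURON_FIELDS.index("C_m")

    def derived(t, Y):
        R_CL, R_Cm = neuron_release(
            Y[:, i_mCL], Y[:, i_hCL], Y[:, i_CL], Y[:, i_Cm], p
        )
        return {"R_CL": R_CL, "R_Cm": R_Cm, "R_total": R_CL + R_Cm}

    return derived


def _astro_derived(p: ParameterSet):
    idx = {n: ASTRO_FIELDS.index(n) for n in ASTRO_FIELDS}

    def derived(t, Y):
        R_CL, R_Cm, R_CN = astrocyte_release(
            Y[:, idx["m_CL"]],
            Y[:, idx["h_CL"]],
            Y[:, idx["m_CN"]],
            Y[:, idx["h_CN"]],
            Y[:, idx["C_L"]],
            Y[:, idx["C_N"]],
            Y[:, idx["C_m"]],
            p,
        )
        return {"R_CL": R_CL, "R_Cm": R_Cm, "R_CN": R_CN, "R_total": R_CL + R_Cm + R_CN}

    return derived


def _abeta_derived(p: ParameterSet, cfg: AbetaConfig, fields, v_of=None):
    """Vectorised flux traces (uM/ms) plus release when microdomains exist."""
    from .kinetics import hill

    pc = p.canonical()
    off = fields.index("ast_C_c") if "ast_C_c" in fields else fields.index("C_c")
    if "ast_m_CL" in fields:
        micro_at = fields.index("ast_m_CL")
    elif fields[0] != "v_m" and "m_CL" in fields:
        micro_at = fields.index("m_CL")
    else:
        micro_at = None
    has_vm = fields[0] == "v_m"
    cur2flux = 1e-9 / (pc.z_Ca * pc.F * pc.lambda_ast) * 1e-3
    A_in_ms = cfg.A_in * 1e-3

    def derived(t, Y):
        Cc = Y[:, off]
        Cr = Y[:, off + 1]
        Pc = Y[:, off + 2]
        mT, hTf, hTs = Y[:, off + 3], Y[:, off + 4], Y[:, off + 5]
        mL, mN = Y[:, off + 6], Y[:, off + 7]
        mR, hR = Y[:, off + 8], Y[:, off + 9]
        if has_vm:
            v = Y[:, 0]
        elif v_of is not None:
            v = np.array([v_of(x) for x in t])
        else:
            v = np.full_like(t, -70.0)
        dv = v - pc.V_C
        I_T = pc.g_T_bar * mT * (hTf + 0.04 * hTs) * dv
        I_L = pc.g_L_bar * mL * ca_inactivation("L", Cc) * dv
        I_N = pc.g_N_bar * mN * ca_inactivation("N", Cc) * dv
        I_R = pc.g_R_bar * mR * hR * dv
        out = {
            "J_VGCC": -(I_T + (1.0 + cfg.A_VL * cfg.l) * I_L + I_N + I_R) * cur2flux,
            "J_CICR": 4.0
            * pc.M_CICR
            * hill(pc.P_CA, Cc, pc.n1)
            * hill(Cc, pc.P_CI, pc.n1)
            * hill(Pc, pc.P_IP3, pc.n2)
            * (Cr - Cc),
            "J_SERCA": pc.M_SERCA * hill(Cc, pc.P_SERCA, pc.n4),
            "J_RyR": (pc.k1 + pc.k2 * hill(Cc, pc.k_d + cfg.A_RyR * cfg.l, pc.n3))
            * (Cr - Cc),
            "J_r": pc.P_f * (Cr - Cc),
            "J_in": pc.a1 + pc.a2_in * Pc + A_in_ms * cfg.l**pc.n5,
            "J_pm": pc.lambda_PM * hill(Cc, pc.K_pm, pc.n4),
            "J_PLC": (1.0 + cfg.A_m * cfg.l) * pc.M_PLC * hill(Cc, pc.P_PC, pc.n4),
        }
        if micro_at is not None:
            m0 = micro_at
            R_CL, R_Cm, R_CN = astrocyte_release(
                Y[:, m0],
                Y[:, m0 + 1],
                Y[:, m0 + 2],
                Y[:, m0 + 3],
                Y[:, m0 + 4],
                Y[:, m0 + 5],
                Y[:, m0 + 6],
                p,
            )
            out.update(
                {"R_CL": R_CL, "R_Cm": R_Cm, "R_CN": R_CN, "R_total": R_CL + R_Cm + R_CN}
            )
        if has_vm:
            out["I_astro"] = _ab.astro_feedback_current(Cc, pc)
        return out

    return derived


def _micro_init(p: ParameterSet, v: float, C0: float = 0.1) -> list[float]:
    """Microdomain block initial values: gates at steady state, C at C0."""
    from .channels import table1_gate

    g = [
        table1_gate(p, "CL", "m").steady(v),
        table1_gate(p, "CL", "h").steady(v),
        table1_gate(p, "CN", "m").steady(v),
        table1_gate(p, "CN", "h").steady(v),
    ]
    return g + [C0, C0, C0]


def build_model(
    variant: str,
    p: Optional[ParameterSet] = None,
    protocol: Optional[StimulusProtocol] = None,
    *,
    cfg: Optional[AbetaConfig] = None,
    thermal: Optional[ThermalConfig] = None,
    y0=None,
    t_max: float = 700.0,
    opts: Optional[IntegratorOptions] = None,
    name: str = "",
    notes: tuple[str, ...] = (),
    clamp_v: float = -70.0,
    feedback: bool = True,
    **flags,
) -> ModelSpec:
    """Assemble a runnable ModelSpec for one of the model variants.

    Variants: neuron | astrocyte | abeta | abeta_release | coupled |
    coupled_release.
    """
    p = (p or default_parameters()).canonical()
    protocol = protocol or StimulusProtocol()
    opts = opts or IntegratorOptions()
    sign_kw = {k: v for k, v in flags.items() if k in ("literal_signs",)}
    rate_kw = {k: v for k, v in flags.items() if k in ("literal_rates",)}
    heavi_kw = {k: v for k, v in flags.items() if k in ("literal_heaviside",)}

    if variant == "neuron":
        rhs = make_neuron_rhs(p, protocol, thermal=thermal, **sign_kw, **rate_kw)
        if y0 is None:
            y0 = _neuron_rest(p, **sign_kw, **rate_kw).to_array()
        return ModelSpec(
            variant,
            lambda t, y: rhs(t, y),
            NEURON_FIELDS,
            np.asarray(y0, dtype=float),
            p,
            protocol,
            _neuron_derived(p),
            None,
            t_max,
            opts,
            name,
            notes,
        )

    if variant == "astrocyte":
        rhs = make_astrocyte_rhs(p, protocol, **sign_kw)
        if y0 is None:
            y0 = _astro_rest(p).to_array()
        return ModelSpec(
            variant,
            rhs,
            ASTRO_FIELDS,
            np.asarray(y0, dtype=float),
            p,
            protocol,
            _astro_derived(p),
            None,
            t_max,
            opts,
            name,
            notes,
        )

    cfg = cfg or AbetaConfig.from_params(p)

    if variant in ("abeta", "abeta_release"):
        release = variant == "abeta_release"
        rhs = make_abeta_rhs(p, cfg, v_of_t=clamp_v, release_micro=release, **sign_kw)
        fields = ABETA_FIELDS + (MICRO_FIELDS if release else ())
        if y0 is None:
            s0 = _ab.AbetaAstrocyteState.at_voltage(clamp_v)
            y0 = list(s0.to_array())
            if release:
                y0 += _micro_init(p, clamp_v)
        return ModelSpec(
            variant,
            rhs,
            fields,
            np.asarray(y0, dtype=float),
            p,
            protocol,
            _abeta_derived(p, cfg, fields, v_of=lambda t: clamp_v),
            cfg,
            t_max,
            opts,
            name,
            notes + (f"v_m clamped at {clamp_v} mV",),
        )

    if variant in ("coupled", "coupled_release"):
        release = variant == "coupled_release"
        rhs = make_coupled_rhs(
            p,
            protocol,
            cfg,
            thermal=thermal,
            release_micro=release,
            feedback=feedback,
            **sign_kw,
            **rate_kw,
            **heavi_kw,
        )
        fields = rhs.fields
        if y0 is None:
            rest = _neuron_rest(p, **sign_kw, **rate_kw)
            s0 = _ab.AbetaAstrocyteState.at_voltage(rest.v_m)
            y0 = list(rest.to_array()) + list(s0.to_array())
            if release:
                y0 += _micro_init(p, rest.v_m)
        return ModelSpec(
            variant,
            rhs,
            fields,
            np.asarray(y0, dtype=float),
            p,
            protocol,
            _abeta_derived(p, cfg, fields),
            cfg,
            t_max,
            opts,
            name,
            notes,
        )

    raise ValueError(f"unknown model variant {variant!r}")


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------


def _fig2_neuron(p, amplitude=20.0, t_max=700.0, **kw):
    proto = StimulusProtocol(pulses=(Pulse(100.0, 500.0, amplitude),))
    return build_model("neuron", p, proto, t_max=t_max, **kw)


def _fig2_astro(p, v_amplitude=20.0, t_max=700.0, **kw):
    proto = StimulusProtocol(v_ind=(Pulse(100.0, 500.0, v_amplitude),))
    return build_model("astrocyte", p, proto, t_max=t_max, **kw)


def _fig4(p, l=0.4, t_max=600000.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    opts = IntegratorOptions(method="LSODA", dt=10.0, rtol=1e-8, atol=1e-10)
    return build_model("abeta", p, None, cfg=cfg, t_max=t_max, opts=kw.pop("opts", opts), **kw)


def _fig6(p, l=0.4, t_max=600000.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    opts = IntegratorOptions(method="LSODA", dt=10.0, rtol=1e-8, atol=1e-10)
    return build_model(
        "abeta_release", p, None, cfg=cfg, t_max=t_max, opts=kw.pop("opts", opts), **kw
    )


def _fig7(p, l=0.4, amplitude=20.0, pulse_ms=400.0, t_max=1300.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    proto = StimulusProtocol(pulses=(Pulse(100.0, pulse_ms, amplitude),))
    notes = ("pulse duration 400 ms chosen so the amyloid-free run stays below the feedback threshold",)
    return build_model("coupled_release", p, proto, cfg=cfg, t_max=t_max, notes=notes, **kw)


def _fig8(p, l=0.4, amplitude=20.0, pulse_ms=400.0, t_max=1300.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    proto = StimulusProtocol(pulses=(Pulse(100.0, pulse_ms, amplitude),))
    notes = ("pulse duration 400 ms chosen so the amyloid-free run stays below the feedback threshold",)
    return build_model("coupled", p, proto, cfg=cfg, t_max=t_max, notes=notes, **kw)


def _fig9(p, T=25.0, amplitude=20.0, t_max=700.0, **kw):
    proto = StimulusProtocol(pulses=(Pulse(100.0, 500.0, amplitude),))
    th = ThermalConfig(mode="constant", T=T)
    return build_model("neuron", p, proto, thermal=th, t_max=t_max, **kw)


def _fig11(p, T=10.0, g_m8=3.0, amplitude=20.0, t_max=700.0, **kw):
    proto = StimulusProtocol(pulses=(Pulse(100.0, 500.0, amplitude),))
    th = ThermalConfig(mode="constant", T=T, trpm8_enabled=True, g_m8=g_m8)
    return build_model("neuron", p, proto, thermal=th, t_max=t_max, **kw)


def _fig12(p, g_m8=3.0, amplitude=20.0, T_warm=35.0, T_cold=5.0, leg_ms=1000.0, **kw):
    t_max = 2.0 * leg_ms
    proto = StimulusProtocol(pulses=(Pulse(0.0, t_max, amplitude),))
    ramp = TemperatureRamp(T_warm, T_cold, leg_ms, legs=2)
    th = ThermalConfig(mode="ramp", ramp=ramp, trpm8_enabled=True, g_m8=g_m8)
    return build_model("neuron", p, proto, thermal=th, t_max=t_max, **kw)


def _fig13(p, T=25.0, l=0.4, amplitude=20.0, t_max=700.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    proto = StimulusProtocol(pulses=(Pulse(100.0, 500.0, amplitude),))
    th = ThermalConfig(mode="constant", T=T)
    return build_model("coupled", p, proto, cfg=cfg, thermal=th, t_max=t_max, **kw)


def _fig14(p, T=10.0, g_m8=3.0, l=0.4, amplitude=20.0, t_max=700.0, **kw):
    cfg = AbetaConfig.from_params(p, l=l)
    proto = StimulusProtocol(pulses=(Pulse(100.0, 500.0, amplitude),))
    th = ThermalConfig(mode="constant", T=T, trpm8_enabled=True, g_m8=g_m8)
    return build_model("coupled", p, proto, cfg=cfg, thermal=th, t_max=t_max, **kw)


_SCENARIOS: dict[str, Callable] = {
    "fig2_neuron_pulse": _fig2_neuron,
    "fig2_astrocyte": _fig2_astro,
    "fig4_abeta_autonomous": _fig4,
    "fig6_abeta_release": _fig6,
    "fig7_abeta_driven": _fig7,
    "fig8_coupled": _fig8,
    "fig9_thermal_pulse": _fig9,
    "fig11_trpm8_const_T": _fig11,
    "fig12_trpm8_ramp": _fig12,
    "fig13_thermal_abeta": _fig13,
    "fig14_trpm8_abeta": _fig14,
}


def scenario_names() -> list[str]:
    return sorted(_SCENARIOS)


def scenario(name: str, p: Optional[ParameterSet] = None, **kw) -> ModelSpec:
    """Fully specified runnable configuration for a registered experiment."""
    try:
        factory = _SCENARIOS[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(scenario_names())}"
        ) from None
    spec = factory(p or default_parameters(), **kw)
    spec.name = name
    return spec


def run_scenario(name: str, p: Optional[ParameterSet] = None, **kw) -> SimulationResult:
    t_max = kw.pop("run_t_max", None)
    return integrate(scenario(name, p, **kw), t_max=t_max)


#: scenario keyword arguments reachable through sweep parameter paths
_SWEEP_KW = {"amplitude", "v_amplitude", "l", "T", "g_m8", "t_max", "leg_ms"}


def sweep(name: str, param_path: str, values: Sequence[float], p: Optional[ParameterSet] = None, **kw) -> list[SimulationResult]:
    """One deterministic run per value of a parameter path.

    ``param_path`` is either a scenario knob (amplitude, l, T, g_m8, ...) or
    a registry field name applied as a parameter override.
    """
    p = p or default_parameters()
    out = []
    for value in values:
        if param_path in _SWEEP_KW:
            spec = scenario(name, p, **{param_path: value}, **kw)
        elif param_path in p:
            spec = scenario(name, p.replace(**{param_path: value}), **kw)
        else:
            raise KeyError(f"cannot resolve parameter path {param_path!r}")
        res = integrate(spec)
        res.metadata["sweep"] = {"path": param_path, "value": value}
        out.append(res)
    return out
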