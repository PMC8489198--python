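# exosim

Deterministic simulator for calcium-dependent exosomal release in coupled
neuron–astrocyte models: a Hodgkin–Huxley neuron with L/T-type calcium
microdomains, an IP₃-driven (Li-Rinzel-type) astrocyte with L/N-type
microdomains, an amyloid-beta-modulated astrocytic calcium flux network with
astrocyte→neuron feedback, and a temperature extension with TRPM8
(cold-receptor) channel gating.

## Layout

| module | contents |
|---|---|
| `exosim.params` | named constant registry (units, provenance, validation, YAML overrides, ms-canonical unit conversion) |
| `exosim.kinetics` | algebraic kernels: Hill, Boltzmann, bell-shaped time constants, first-order gate relaxation |
| `exosim.channels` | HH Na⁺/K⁺ rates, the four whole-membrane VGCC types (T/L/N/R), microdomain per-channel currents, TRPM8 thermodynamic gate |
| `exosim.neuron` | spiking neuron + four-compartment Ca²⁺ mass balance + release rates |
| `exosim.astrocyte` | electrically silent astrocyte driven by a depolarisation step |
| `exosim.abeta` | amyloid-modulated flux network, feedback current, coupled network model |
| `exosim.thermal` | φ rate factors, Gaussian peak conductances, temperature ramps |
| `exosim.engine` | RK4 / adaptive integration, scenario registry, sweeps |
| `exosim.metrics` | spike detection, oscillation metrics, release accounting, CSV/JSON writers |

## CLI

```sh
exosim scenarios                          # list registered experiments
exosim simulate --scenario fig2_neuron_pulse --amplitude 20 --out run.csv
exosim simulate --scenario fig8_coupled --l 0.4 --param K_pm=1.5 --out run.csv
exosim sweep --scenario fig12_trpm8_ramp --param-path g_m8 --values 3,5,10
```

`--param KEY=VALUE` (repeatable) and `--config file.yaml` apply registry
overrides; unknown or ambiguous names (e.g. the bare `a2`) are rejected.
Every run writes a JSON metadata sidecar carrying the parameter hash,
integrator settings and the assumption log.

## Scenarios

`fig2_neuron_pulse`, `fig2_astrocyte`, `fig4_abeta_autonomous`,
`fig6_abeta_release`, `fig7_abeta_driven`, `fig8_coupled`,
`fig9_thermal_pulse`, `fig11_trpm8_const_T`, `fig12_trpm8_ramp`,
`fig13_thermal_abeta`, `fig14_trpm8_abeta` — each returns a fully specified
configuration (variant, initial state, stimulus protocol, parameters) and
runs in under a minute at default settings.

Model-variant flags expose the literal printed forms for comparison with the
corrected defaults: `literal_signs` (self-amplifying microdomain/ER
exchange), `literal_rates` (verbatim HH rate strings), `literal_heaviside`
(feedback-current step), `ThermalConfig(literal_gmax=True)` (raw Gaussian
conductance amplitudes).

## Python API sketch

```python
import exosim as ex

p = ex.default_parameters().replace(g_m8=3.0)
res = ex.run_scenario("fig2_neuron_pulse", p, amplitude=15.0)
train = ex.detect_spikes(res.t, res.trace("v_m"))
bd = ex.release_breakdown(res, window=(100.0, 600.0))
print(train.count, bd.fractions)
```
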