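import json

import numpy as np
import pytest

import exosim as ex
from exosim.metrics import (
    detect_spikes,
    dominant_frequency,
    oscillation_metrics,
    read_result,
    release_breakdown,
    write_result,
)


def _triangle_train(k, period=20.0, dt=0.05):
    """k triangular spikes crossing 0 mV from a -65 mV baseline."""
    t = np.arange(0.0, k * period + period, dt)
    v = np.full_like(t, -65.0)
    for i in range(k):
        c = (i + 0.5) * period
        mask = np.abs(t - c) < 2.0
        v[mask] = -65.0 + 85.0 * (1.0 - np.abs(t[mask] - c) / 2.0)
    return t, v


class TestDetectSpikes:
    def test_constant_trace(self):
        t = np.linspace(0, 100, 1000)
        assert detect_spikes(t, np.full_like(t, -65.0)).count == 0

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_triangle_train_counts(self, k):
        t, v = _triangle_train(k)
        train = detect_spikes(t, v)
        assert train.count == k
        assert np.all(np.diff(train.times) > 0)

    def test_refractory_merges_close_crossings(self):
        t = np.linspace(0, 10, 10001)
        v = -65 + 100 * (np.sin(2 * np.pi * t) > 0.99)  # chattering crossings
        train = detect_spikes(t, v, refractory=2.0)
        assert train.count <= 10

    def test_grid_refinement_invariance(self):
        t1, v1 = _triangle_train(5, dt=0.05)
        t2, v2 = _triangle_train(5, dt=0.005)
        assert detect_spikes(t1, v1).count == detect_spikes(t2, v2).count

    def test_amplitudes_recorded(self):
        t, v = _triangle_train(2)
        train = detect_spikes(t, v)
        assert train.mean_amplitude == pytest.approx(20.0, abs=2.0)

    def test_fine_step_reference_agreement(self, p):
        from exosim.engine import IntegratorOptions, integrate, scenario

        spec = scenario("fig2_neuron_pulse", p, t_max=300.0)
        coarse = integrate(spec)
        fine = integrate(spec, opts=IntegratorOptions(dt=0.001, sample_every=10))
        nc = detect_spikes(coarse.t, coarse.trace("v_m")).count
        nf = detect_spikes(fine.t, fine.trace("v_m")).count
        assert abs(nc - nf) <= 1


class TestReleaseBreakdown:
    def test_fractions_sum_to_one(self, fig2_result):
        bd = release_breakdown(fig2_result, window=(100.0, 600.0))
        assert sum(bd.fractions.values()) == pytest.approx(1.0)
        assert all(f >= 0 for f in bd.fractions.values())

    def test_window_validation(self, fig2_result):
        with pytest.raises(ValueError):
            release_breakdown(fig2_result, window=(0.0, 1e6))

    def test_zero_pathway_gives_zero_fraction(self, fig2_result):
        import copy

        res = copy.deepcopy(fig2_result)
        res.derived["R_Cm"] = np.zeros_like(res.t)
        bd = release_breakdown(res, window=(100.0, 600.0))
        assert bd.fractions["R_Cm"] == 0.0

    def test_rescaling_invariance(self, fig2_result):
        import copy

        bd0 = release_breakdown(fig2_result, window=(100.0, 600.0))
        res = copy.deepcopy(fig2_result)
        for k in ("R_CL", "R_Cm"):
            res.derived[k] = res.derived[k] * 7.3
        bd1 = release_breakdown(res, window=(100.0, 600.0))
        for k in bd0.fractions:
            assert bd1.fractions[k] == pytest.approx(bd0.fractions[k], rel=1e-12)

    def test_cumulative_non_decreasing_in_window_length(self, fig2_result):
        short = release_breakdown(fig2_result, window=(100.0, 300.0))
        long = release_breakdown(fig2_result, window=(100.0, 600.0))
        for k in short.cumulative:
            assert long.cumulative[k] >= short.cumulative[k] - 1e-15


class TestOscillationMetrics:
    def test_constant_trace(self):
        t = np.linspace(0, 1e5, 1000)
        amp, freq, base = oscillation_metrics(t, np.full_like(t, 0.3))
        assert amp == 0.0 and freq == 0.0
        assert base == pytest.approx(0.3)

    def test_synthetic_sinusoid_recovered(self):
        t = np.arange(0, 30000.0, 10.0)  # 30 s at 10 ms sampling
        x = 0.1 + 0.05 * np.sin(2 * np.pi * 0.1 * t / 1000.0)  # 0.1 Hz
        amp, freq, base = oscillation_metrics(t, x)
        assert freq == pytest.approx(0.1, rel=0.05)
        assert amp == pytest.approx(0.1, rel=0.05)  # peak-to-trough
        assert base == pytest.approx(0.05, abs=0.01)

    def test_dominant_frequency_sinusoid(self):
        t = np.arange(0, 2000.0, 0.5)
        x = np.sin(2 * np.pi * 25.0 * t / 1000.0)
        assert dominant_frequency(t, x) == pytest.approx(25.0, rel=0.05)


class TestWriters:
    def test_csv_round_trip(self, fig2_result, tmp_path):
        path = tmp_path / "run.csv"
        write_result(fig2_result, path)
        df = read_result(path)
        assert df["t_ms"].to_numpy() == pytest.approx(fig2_result.t, rel=1e-15)
        assert df["v_m_mV"].to_numpy() == pytest.approx(fig2_result.trace("v_m"), rel=1e-15)
        assert df["R_Cm"].to_numpy() == pytest.approx(fig2_result.trace("R_Cm"), rel=1e-12)

    def test_column_schema(self, fig2_result, tmp_path):
        path = tmp_path / "run.csv"
        write_result(fig2_result, path)
        df = read_result(path)
        assert len(df.columns) == 1 + len(fig2_result.fields) + len(fig2_result.derived)
        assert list(df.columns)[0] == "t_ms"

    def test_metadata_sidecar(self, fig2_result, tmp_path):
        path = tmp_path / "run.csv"
        write_result(fig2_result, path)
        meta = json.loads((tmp_path / "run.csv.meta.json").read_text())
        assert meta["params_hash"] == fig2_result.metadata["params_hash"]
        assert meta["assumptions"]

    def test_json_format(self, fig2_result, tmp_path):
        path = tmp_path / "run.json"
        write_result(fig2_result, path, fmt="json")
        df = read_result(path)
        assert df["t_ms"].to_numpy() == pytest.approx(fig2_result.t, rel=1e-15)


class TestCLI:
    def test_scenarios_listing(self, capsys):
        from exosim.cli import main

        assert main(["scenarios"]) == 0
        out = capsys.readouterr().out
        assert "fig2_neuron_pulse" in out

    def test_simulate_writes_output(self, tmp_path, capsys):
        from exosim.cli import main

        out = tmp_path / "short.csv"
        code = main(
            [
                "simulate", "--scenario", "fig2_neuron_pulse",
                "--t-max", "5", "--param", "K_L=40", "--out", str(out),
            ]
        )
        assert code == 0
        assert out.exists() and out.with_suffix(".csv.meta.json").exists()

    def test_sweep_command(self, capsys):
        from exosim.cli import main

        code = main(
            [
                "sweep", "--scenario", "fig2_neuron_pulse",
                "--param-path", "amplitude", "--values", "10,20", "--t-max", "5",
            ]
        )
        assert code == 0
        rows = json.loads(capsys.readouterr().out)
        assert [r["value"] for r in rows] == [10.0, 20.0]
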