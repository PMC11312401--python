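"""Unit and property tests for trajectory generation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ciliabeat as cb
from ciliabeat.beat_kinematics import FRAME_MS, ConfigurationError


def params(**kw):
    base = dict(t_eff=44.0, t_rec=38.0, interval_mean=120.0, amplitude=1.0)
    base.update(kw)
    return cb.BeatParameters(**base)


class TestSampleInterval:
    def test_zero_variance_is_exact(self):
        p = params(interval_mean=234.0, interval_sigma_log=0.0)
        rng = np.random.default_rng(0)
        assert all(cb.sample_interval(p, rng) == 234.0 for _ in range(10))

    def test_arithmetic_mean_and_spread(self):
        # pH 7.0 preset: mean 234 ms, log-sd 0.45
        p = cb.get_preset("pH7.0").params
        draws = cb.sample_interval(p, np.random.default_rng(1), size=100_000)
        assert draws.mean() == pytest.approx(234.0, rel=0.01)
        q_lo, q_hi = np.percentile(draws, [2.5, 97.5])
        # central 95% spans roughly 90-520 ms, and the full sampled range
        # brackets the observed physiological range 112-584 ms
        assert 80.0 < q_lo < 100.0
        assert 470.0 < q_hi < 560.0
        assert draws.min() < 112.0 < 584.0 < draws.max()

    @pytest.mark.parametrize("label", [p.label for p in cb.load_preset_table()])
    def test_sample_mean_matches_configured_mean(self, label):
        p = cb.get_preset(label).params
        if p.interval_mean == 0:
            pytest.skip("degenerate zero-mean interval")
        draws = np.asarray(
            cb.sample_interval(p, np.random.default_rng(7), size=10_000), dtype=float
        )
        se = draws.std(ddof=1) / math.sqrt(len(draws)) if draws.std() > 0 else 1e-12
        assert abs(draws.mean() - p.interval_mean) <= max(3 * se, 1e-9)
        assert draws.min() >= 0

    def test_negative_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            params(interval_mean=-1.0)


class TestStrokeWaveform:
    def test_boundary_values(self):
        p = params(amplitude=1.45, t_eff=136.0, t_rec=38.0)
        assert cb.stroke_waveform(0.0, p) == pytest.approx(0.0)
        assert cb.stroke_waveform(p.t_eff, p) == pytest.approx(1.45)
        assert cb.stroke_waveform(p.t_eff + p.t_rec, p) == pytest.approx(0.0, abs=1e-12)

    def test_raised_cosine_midpoint(self):
        p = params(amplitude=1.45)
        assert cb.stroke_waveform(p.t_eff / 2, p) == pytest.approx(0.725)

    def test_out_of_beat_phase_rejected(self):
        p = params()
        with pytest.raises(ValueError):
            cb.stroke_waveform(-1.0, p)
        with pytest.raises(ValueError):
            cb.stroke_waveform(p.t_eff + p.t_rec + 0.1, p)

    @settings(max_examples=25, derandomize=True)
    @given(
        t_eff=st.floats(8, 300),
        t_rec=st.floats(8, 300),
        amp=st.floats(0.1, 3.0),
    )
    def test_monotone_rise_and_fall(self, t_eff, t_rec, amp):
        p = params(t_eff=t_eff, t_rec=t_rec, amplitude=amp)
        tr = np.linspace(0, t_eff, 50)
        tf = np.linspace(t_eff, t_eff + t_rec, 50)
        assert np.all(np.diff(cb.stroke_waveform(tr, p)) >= 0)
        assert np.all(np.diff(cb.stroke_waveform(tf, p)) <= 0)


class TestBuildTrajectory:
    def test_deterministic_beat_count(self):
        # 44 + 38 + 120 = 202 ms cycle; 2 s record holds floor(2000/202) = 9
        # complete beats
        p = params(interval_sigma_log=0.0, mode="component_matched")
        traj = cb.build_trajectory(p, 2.0, np.random.default_rng(0))
        complete = [e for e in traj.event_log if e[2] <= 2000.0]
        assert len(complete) == 9

    def test_rate_matched_deterministic_cycle(self):
        p = params(interval_sigma_log=0.0, mode="rate_matched", target_cbf=5.0)
        traj = cb.build_trajectory(p, 2.0, np.random.default_rng(0))
        assert set(np.diff(traj.peak_times)) == {200.0}

    def test_component_matched_emergent_rate(self):
        # pH 7.0 components: cycle 136 + 38 + 234 = 408 ms -> ~2.45 Hz
        p = cb.get_preset("pH7.0").params.with_mode("component_matched")
        assert p.expected_rate_hz == pytest.approx(1000.0 / 408.0, rel=1e-6)
        traj = cb.build_trajectory(p, 60.0, np.random.default_rng(3))
        rate = len(traj.event_log) / 60.0
        assert rate == pytest.approx(2.45, rel=0.10)

    @pytest.mark.parametrize("label", ["pH7.0", "pH8.0", "ATP2.5"])
    def test_rate_matched_long_run_rate(self, label):
        # long enough that renewal sampling noise sits well inside the band
        p = cb.get_preset(label).params.with_mode("rate_matched")
        dur = 600.0
        traj = cb.build_trajectory(p, dur, np.random.default_rng(5))
        rate = len(traj.event_log) / dur
        assert rate == pytest.approx(p.target_cbf, rel=0.03)

    def test_event_log_on_grid_and_baseline(self):
        p = cb.get_preset("pH7.4").params.with_mode("rate_matched")
        traj = cb.build_trajectory(p, 4.0, np.random.default_rng(11))
        idx = {round(t / FRAME_MS): t for e in traj.event_log for t in e}
        for frame, t in idx.items():
            assert t == frame * FRAME_MS  # exactly on the 4 ms grid
        n = len(traj.positions)
        for e0, _, e1 in traj.event_log:
            for t in (e0, e1):
                k = int(round(t / FRAME_MS))
                if k < n:
                    assert abs(traj.positions[k]) < 1e-9

    def test_amplitude_linearity(self):
        p = cb.get_preset("pH7.6").params.with_mode("rate_matched")
        t1 = cb.build_trajectory(p, 2.0, np.random.default_rng(9))
        t2 = cb.build_trajectory(
            replace(p, amplitude=2 * p.amplitude), 2.0, np.random.default_rng(9)
        )
        np.testing.assert_allclose(t2.positions, 2 * t1.positions, atol=1e-12)

    def test_null_parameters_make_fluctuation_only_trajectory(self):
        p = cb.get_preset("unstimulated").params
        traj = cb.build_trajectory(p, 2.0, np.random.default_rng(2))
        assert traj.event_log == []
        assert np.std(traj.positions) > 0  # OU fluctuation present

    def test_invalid_configurations(self):
        with pytest.raises(ConfigurationError):
            params(t_eff=0)
        with pytest.raises(ConfigurationError):
            params(mode="nonsense")
        with pytest.raises(ConfigurationError):
            params(mode="rate_matched")  # missing target_cbf
        with pytest.raises(ConfigurationError):
            cb.build_trajectory(params(), 0.0, np.random.default_rng(0))


class TestPresetTable:
    def test_bundled_values(self):
        table = cb.load_preset_table()
        assert cb.get_preset("pH7.0", table).params.amplitude == 0.57
        assert cb.get_preset("pH8.0", table).params.interval_mean == 31.0
        assert cb.get_preset("pH7.4", table).n_cilia == 11
        labels = [p.label for p in table]
        assert len(labels) == len(set(labels))

    def test_bad_tables_rejected(self, tmp_path):
        empty = tmp_path / "empty.yaml"
        empty.write_text("presets: []\n")
        with pytest.raises(ConfigurationError, match="empty"):
            cb.load_preset_table(empty)

        bad_mode = tmp_path / "mode.yaml"
        bad_mode.write_text(
            "presets:\n"
            "  - {label: x, n_cilia: 1, t_eff_ms: 40, t_rec_ms: 40,\n"
            "     interval_mean_ms: 100, amplitude_um: 1.0, default_mode: wobbly}\n"
        )
        with pytest.raises(ConfigurationError, match="mode"):
            cb.load_preset_table(bad_mode)

        missing = tmp_path / "missing.yaml"
        missing.write_text("presets:\n  - {label: x, n_cilia: 1}\n")
        with pytest.raises(ConfigurationError, match="t_eff_ms"):
            cb.load_preset_table(missing)

        unknown = tmp_path / "unknown.yaml"
        unknown.write_text(
            "presets:\n"
            "  - {label: x, n_cilia: 1, t_eff_ms: 40, t_rec_ms: 40,\n"
            "     interval_mean_ms: 100, amplitude_um: 1.0, frobnicate: 3}\n"
        )
        with pytest.raises(ConfigurationError, match="frobnicate"):
            cb.load_preset_table(unknown)
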