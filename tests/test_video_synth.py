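"""Tests for the synthetic renderer and TIFF I/O."""

from dataclasses import replace

import numpy as np
import pytest

import ciliabeat as cb
from ciliabeat.beat_kinematics import ConfigurationError
from ciliabeat.video_synth import FormatError


def _arc_length(pts):
    return np.hypot(*np.diff(pts, axis=0).T).sum()


def _flat_trajectory(n, value=0.0):
    t = np.arange(n) * cb.FRAME_MS
    p = cb.BeatParameters(t_eff=40, t_rec=40, interval_mean=100, amplitude=max(value, 1.0))
    return cb.BeatTrajectory(times=t, positions=np.full(n, value), event_log=[], params=p)


class TestPoseCilium:
    def test_rest_pose_is_straight(self):
        geo = cb.CiliumGeometry()
        pts = cb.pose_cilium(geo, 0.0)
        assert np.allclose(pts[:, 1], geo.anchor[1], atol=1e-12)
        assert pts[-1, 0] == pytest.approx(geo.anchor[0] + geo.length, abs=1e-6)

    def test_mirror_symmetry(self):
        geo = cb.CiliumGeometry()
        up = cb.pose_cilium(geo, 0.9)
        down = cb.pose_cilium(geo, -0.9)
        np.testing.assert_allclose(up[:, 0], down[:, 0], atol=1e-12)
        np.testing.assert_allclose(
            up[:, 1] - geo.anchor[1], -(down[:, 1] - geo.anchor[1]), atol=1e-12
        )

    @pytest.mark.parametrize("d", [-1.45, -0.5, 0.3, 1.0, 1.45, 2.9])
    def test_arc_length_preserved(self, d):
        geo = cb.CiliumGeometry()
        pts = cb.pose_cilium(geo, d)
        assert _arc_length(pts) == pytest.approx(geo.length, rel=0.01)

    def test_displacement_at_scanline_station(self):
        # with the default geometry the point at 7 µm arc length is offset
        # by the commanded 1.45 µm perpendicular to the base pose
        geo = cb.CiliumGeometry()
        pts = cb.pose_cilium(geo, 1.45, n_points=2000)
        s = np.concatenate([[0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
        k = np.argmin(np.abs(s - 0.7 * geo.length))
        assert pts[k, 1] - geo.anchor[1] == pytest.approx(1.45, abs=0.01)


class TestRenderStack:
    def test_static_scene_gives_identical_frames(self):
        cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
        stack = cb.render_stack(_flat_trajectory(20), config=cfg)
        assert all(np.array_equal(stack.frames[0], f) for f in stack.frames[1:])

    def test_two_seconds_is_500_frames(self):
        p = cb.get_preset("rep_pH7.4").params
        traj = cb.build_trajectory(p, 2.0, np.random.default_rng(0))
        cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
        stack = cb.render_stack(traj, config=cfg)
        assert stack.n_frames == 500

    def test_noise_off_is_deterministic(self):
        p = cb.get_preset("rep_pH7.4").params
        traj = cb.build_trajectory(p, 0.4, np.random.default_rng(0))
        cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
        a = cb.render_stack(traj, config=cfg)
        b = cb.render_stack(traj, config=cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_argmax_tracks_truth_within_half_pixel(self, sinusoid_stack):
        stack, line, offset, traj = sinusoid_stack
        tr = cb.extract_trace(stack, line)
        err = tr.positions - offset - traj.positions
        assert np.abs(err).max() <= 0.05

    def test_integrated_intensity_invariant_to_displacement(self):
        cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
        totals = []
        for d in (0.0, 0.7, 1.45):
            stack = cb.render_stack(_flat_trajectory(1, d), config=cfg)
            totals.append(stack.frames[0].astype(float).sum() - cfg.background_level * stack.frames[0].size)
        assert np.ptp(totals) / np.mean(totals) < 0.01

    def test_undersampled_beat_refused(self):
        # 4 frames per cycle is below the renderer's floor of 6
        p = cb.BeatParameters(
            t_eff=8, t_rec=4, interval_mean=4, interval_sigma_log=0,
            amplitude=1.0, mode="component_matched",
        )
        traj = cb.build_trajectory(p, 0.5, np.random.default_rng(0))
        with pytest.raises(ConfigurationError, match="frames"):
            cb.render_stack(traj, config=replace(cb.ImagingConfig(), noise_sd=0.0))

    def test_out_of_frame_pose_names_frame(self):
        geo = cb.CiliumGeometry(anchor=(1.4, 12.0))
        with pytest.raises(ConfigurationError, match="frame 0"):
            cb.render_stack(
                _flat_trajectory(3, 2.0), geo, replace(cb.ImagingConfig(), noise_sd=0.0)
            )

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            cb.render_stack(_flat_trajectory(0))

    def test_noise_requires_rng(self):
        with pytest.raises(ConfigurationError, match="generator"):
            cb.render_stack(_flat_trajectory(2), config=cb.ImagingConfig())


class TestStackIO:
    def test_round_trip_is_pixel_identical(self, tmp_path, sinusoid_stack):
        stack = sinusoid_stack[0]
        path = tmp_path / "stack.tif"
        cb.write_stack(stack, path)
        back = cb.read_stack(path)
        assert np.array_equal(back.frames, stack.frames)
        assert back.config.fps == 250.0
        assert back.config.pixel_size == stack.config.pixel_size

    def test_single_page_reads_as_one_frame(self, tmp_path):
        cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
        stack = cb.render_stack(_flat_trajectory(1), config=cfg)
        path = tmp_path / "one.tif"
        cb.write_stack(stack, path)
        back = cb.read_stack(path)
        assert back.frames.shape == (1, *cfg.frame_shape)

    def test_truncated_file_raises_format_error(self, tmp_path):
        path = tmp_path / "broken.tif"
        path.write_bytes(b"II*\x00garbage")
        with pytest.raises(FormatError):
            cb.read_stack(path)

    def test_foreign_tiff_needs_metadata(self, tmp_path):
        import tifffile

        path = tmp_path / "foreign.tif"
        tifffile.imwrite(
            path, np.zeros((3, 16, 16), dtype=np.uint16), photometric="minisblack"
        )
        with pytest.raises(FormatError, match="metadata"):
            cb.read_stack(path)
        back = cb.read_stack(path, fps=250.0, pixel_size=0.1)
        assert back.n_frames == 3
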