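"""Image-level stage: rendering, background correction, RVT, linking."""

import numpy as np
import pytest

from inta.config import ContrastCalibration, DetectionConfig, InstrumentSpec, OpticalConfig
from inta.frames import (
    FrameStack,
    PSFModel,
    detect_and_link,
    link_localizations,
    median_background_correct,
    radial_variance_transform,
    render_frames,
)
from inta.simulate import Trajectory, TrajectorySet

OPTICS = OpticalConfig()
CALIB = ContrastCalibration()
SMALL_INSTR = InstrumentSpec(fov_side_um=3.52, duration_s=0.2)
DET = DetectionConfig()


def tiny_set(trajectories):
    return TrajectorySet(trajectories, OPTICS, SMALL_INSTR, CALIB)


def static_trajectory(x_px, y_px, n_frames, contrast=0.02, pid=0):
    x_um = (x_px + 0.5) * DET.pixel_size_um
    y_um = (y_px + 0.5) * DET.pixel_size_um
    pos = np.tile([x_um, y_um], (n_frames, 1))
    return Trajectory(pid, np.arange(n_frames), pos, np.full(n_frames, contrast))


class TestRendering:
    def test_empty_set_is_pure_background(self):
        stack = render_frames(tiny_set([]), DET, noise_sd=0.0, n_frames=3)
        np.testing.assert_allclose(stack.frames, 1.0)

    def test_static_particle_peaks_at_rendered_pixel(self):
        stack = render_frames(
            tiny_set([static_trajectory(20, 30, 4)]), DET, noise_sd=0.0
        )
        for frame in stack.frames:
            y, x = np.unravel_index(np.argmax(frame), frame.shape)
            assert (x, y) == (20, 30)
            assert frame[y, x] == pytest.approx(1.02, abs=1e-3)

    def test_incompatible_pixel_size_rejected(self):
        coarse = DetectionConfig(pixel_size_um=2.0)  # 2 px frame
        with pytest.raises(ValueError, match="pixel size"):
            render_frames(tiny_set([]), coarse, n_frames=2)


class TestMedianBackground:
    def test_constant_stack_maps_to_zero(self):
        stack = FrameStack(np.full((9, 16, 16), 3.7), 0.055, 5000.0)
        out = median_background_correct(stack, window=5, mode="subtract")
        np.testing.assert_allclose(out.frames, 0.0)

    def test_static_spot_removed(self):
        stack = render_frames(
            tiny_set([static_trajectory(20, 20, 31)]), DET, noise_sd=0.0
        )
        out = median_background_correct(stack, window=31, mode="subtract")
        assert np.abs(out.frames[15]).max() < 1e-6

    def test_divide_mode_returns_relative_contrast(self):
        stack = FrameStack(np.full((5, 8, 8), 2.0), 0.055, 5000.0)
        out = median_background_correct(stack, window=5, mode="divide")
        np.testing.assert_allclose(out.frames, 0.0)

    def test_moving_spot_amplitude_preserved(self):
        # particle crossing at ~2 px/frame: an 11-frame median barely sees it
        n = 41
        xs = np.arange(n) * 2.0 + 5.0
        pos = np.stack([(xs + 0.5) * DET.pixel_size_um,
                        np.full(n, (32 + 0.5) * DET.pixel_size_um)], axis=1)
        traj = Trajectory(0, np.arange(n), pos, np.full(n, 0.02))
        stack = render_frames(tiny_set([traj]), DET, noise_sd=0.0, n_frames=n)
        out = median_background_correct(stack, window=11, mode="subtract")
        mid = out.frames[20]
        assert mid.max() >= 0.9 * 0.02  # <= 10% amplitude loss

    def test_window_validation(self):
        stack = FrameStack(np.ones((5, 8, 8)), 0.055, 5000.0)
        with pytest.raises(ValueError):
            median_background_correct(stack, window=4)
        with pytest.raises(ValueError):
            median_background_correct(stack, window=7)
        with pytest.raises(ValueError):
            median_background_correct(stack, window=5, guard=2)


class TestRadialVarianceTransform:
    def test_constant_frame_gives_zero_response(self):
        resp = radial_variance_transform(np.full((32, 32), 2.5), 1, 6)
        assert np.abs(resp).max() < 1e-20

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(32, 32))
        r1 = radial_variance_transform(frame, 1, 6)
        r2 = radial_variance_transform(frame + 100.0, 1, 6)
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_concentric_ring_pattern_peaks_at_centre(self):
        yy, xx = np.mgrid[0:41, 0:41]
        r = np.hypot(xx - 20, yy - 23)
        frame = np.cos(r * 1.3) * np.exp(-r / 10)
        resp = radial_variance_transform(frame, 1, 6)
        y, x = np.unravel_index(np.argmax(resp), resp.shape)
        assert (x, y) == (20, 23)

    def test_rendered_spot_localized_within_one_pixel(self):
        stack = render_frames(
            tiny_set([static_trajectory(24.3, 31.7, 1)]), DET, noise_sd=0.002, rng=3
        )
        resp = radial_variance_transform(stack.frames[0] - 1.0, 1, 6)
        y, x = np.unravel_index(np.argmax(resp), resp.shape)
        assert np.hypot(x - 24.3, y - 31.7) < 1.0

    def test_radius_bounds_validated(self):
        with pytest.raises(ValueError):
            radial_variance_transform(np.zeros((8, 8)), 3, 2)
        with pytest.raises(ValueError):
            radial_variance_transform(np.zeros((8, 8)), 1, 10)


class TestLinking:
    @staticmethod
    def walk_detections(n_frames, step_px, start, rng, drop_frames=()):
        pos = start + np.cumsum(rng.normal(0, step_px, (n_frames, 2)), axis=0)
        dets = []
        for f in range(n_frames):
            if f in drop_frames:
                dets.append((np.empty((0, 2)), np.empty(0)))
            else:
                dets.append((pos[f][None, :], np.array([0.02])))
        return dets, pos

    def test_min_localization_boundary(self):
        rng = np.random.default_rng(1)
        for n, kept in ((100, 0), (101, 1)):
            dets, _ = self.walk_detections(n, 0.5, np.array([30.0, 30.0]), rng)
            trajs = link_localizations(dets, 4.0, 100, 0.055)
            assert len(trajs) == kept

    def test_two_separated_particles_no_swaps(self):
        rng = np.random.default_rng(2)
        d1, p1 = self.walk_detections(150, 0.4, np.array([15.0, 15.0]), rng)
        d2, p2 = self.walk_detections(150, 0.4, np.array([45.0, 45.0]), rng)
        merged = [
            (np.vstack([a[0], b[0]]), np.concatenate([a[1], b[1]]))
            for a, b in zip(d1, d2)
        ]
        trajs = link_localizations(merged, 4.0, 100, 0.055)
        assert len(trajs) == 2
        for traj in trajs:
            start = traj.positions_um[0] / 0.055 - 0.5
            ref = p1 if np.linalg.norm(start - p1[0]) < 1 else p2
            np.testing.assert_allclose(
                traj.positions_um / 0.055 - 0.5, ref, atol=1e-6
            )

    def test_memory_bridges_single_missed_frame(self):
        rng = np.random.default_rng(3)
        dets, _ = self.walk_detections(
            150, 0.4, np.array([30.0, 30.0]), rng, drop_frames={60}
        )
        without = link_localizations(dets, 4.0, 100, 0.055, memory=0)
        with_mem = link_localizations(dets, 4.0, 100, 0.055, memory=3)
        assert len(without) == 0  # fragments of 60 and 89 localizations
        assert len(with_mem) == 1
        assert len(with_mem[0]) == 149
        assert 60 not in with_mem[0].frame_indices


class TestDetectionClosure:
    def test_single_noiseless_particle_recovered(self):
        n = 120
        rng = np.random.default_rng(4)
        xs = 30 + np.cumsum(rng.normal(0, 0.4, n))
        ys = 30 + np.cumsum(rng.normal(0, 0.4, n))
        pos = np.stack([(xs + 0.5) * DET.pixel_size_um, (ys + 0.5) * DET.pixel_size_um], axis=1)
        traj = Trajectory(0, np.arange(n), pos, np.full(n, 0.02))
        stack = render_frames(tiny_set([traj]), DET, noise_sd=0.0, n_frames=n)
        det = DetectionConfig(median_window=101, median_guard=20)
        found = detect_and_link(stack, SMALL_INSTR, det)
        assert len(found) == 1
        common = np.intersect1d(found.trajectories[0].frame_indices, np.arange(n))
        assert len(common) >= 0.95 * n

    def test_detected_positions_match_truth_subpixel(self):
        # track in the stack interior: the rolling median needs preceding
        # and following background frames (its edge frames are degraded,
        # a negligible fraction of a real 10-minute recording)
        n, start = 130, 120
        rng = np.random.default_rng(5)
        xs = 28 + np.cumsum(rng.normal(0, 0.4, n))
        ys = 36 + np.cumsum(rng.normal(0, 0.4, n))
        pos = np.stack([(xs + 0.5) * DET.pixel_size_um, (ys + 0.5) * DET.pixel_size_um], axis=1)
        traj = Trajectory(0, np.arange(start, start + n), pos, np.full(n, 0.02))
        stack = render_frames(
            tiny_set([traj]), DET, noise_sd=0.004, rng=6, n_frames=start + n + 120
        )
        det = DetectionConfig(median_window=101, median_guard=20)
        found = detect_and_link(stack, SMALL_INSTR, det)
        assert len(found) == 1
        rec = found.trajectories[0]
        common, ia, ib = np.intersect1d(
            traj.frame_indices, rec.frame_indices, return_indices=True
        )
        assert len(common) > 0.9 * n
        err = np.linalg.norm(pos[ia] - rec.positions_um[ib], axis=1)
        rms_px = np.sqrt(np.mean(err**2)) / DET.pixel_size_um
        assert rms_px < 1.0  # SNR 5: subpixel localization


class TestTiffRoundTrip:
    def test_save_and_load(self, tmp_path):
        rng = np.random.default_rng(7)
        frames = 1.0 + 0.01 * rng.standard_normal((4, 16, 16))
        stack = FrameStack(frames, 0.055, 5000.0)
        path = tmp_path / "movie.tiff"
        stack.save_tiff(path)
        back = FrameStack.load_tiff(path, 0.055, 5000.0)
        np.testing.assert_allclose(back.frames, frames.astype(np.float32), atol=1e-7)
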