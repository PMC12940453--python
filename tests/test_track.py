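"""Marker detection, sub-pixel refinement, tracking robustness, calibration."""

import numpy as np
import pytest

from vibrotrack.frames import FrameStack
from vibrotrack.scene_sim import MarkerSpec, SceneConfig, simulate_clip
from vibrotrack.track import (
    DEFAULT_CALIBRATION,
    TrackingError,
    calibrate,
    detect_markers,
    make_template,
    refine_subpixel,
    track_clip,
)

from .conftest import PITCH, small_scene, tone


def _frame_with_cross(center, shape=(96, 128), arm_length_mm=8.0, seed=None, noise=0.0):
    markers = tuple(
        MarkerSpec(center_px=c, arm_length_mm=arm_length_mm, marker_id=f"m{i}")
        for i, c in enumerate(np.atleast_2d(center))
    )
    cfg = SceneConfig(
        width_px=shape[1],
        height_px=shape[0],
        fps=1000.0,
        duration_s=0.002,
        pixel_pitch_mm=PITCH,
        noise_sigma=noise,
        texture_amp=0.0,
        markers=markers,
        seed=seed or 0,
    )
    clip, _ = simulate_clip(cfg)
    return clip


class TestDetect:
    def test_single_cross_found_at_integer_position(self, template):
        clip = _frame_with_cross([(40.0, 60.0)])
        hits = detect_markers(clip.frames[0], template, min_corr=0.8)
        assert hits == [(40, 60)]

    def test_two_separated_crosses_found(self, template):
        clip = _frame_with_cross([(30.0, 30.0), (95.0, 60.0)])
        hits = detect_markers(clip.frames[0], template, min_corr=0.8)
        assert len(hits) == 2
        assert set(hits) == {(30, 30), (95, 60)}

    def test_pure_noise_gives_empty_list(self, template):
        for seed in range(5):
            frame = np.random.default_rng(seed).random((64, 64))
            assert detect_markers(frame, template, min_corr=0.8) == []


class TestRefineSubpixel:
    def test_symmetric_surface_zero_offset(self):
        x = np.arange(7) - 3.0
        surface = 1.0 - np.add.outer(x**2, x**2) / 20
        (sx, sy), ok = refine_subpixel(surface, (3, 3))
        assert ok
        assert (sx, sy) == pytest.approx((3.0, 3.0), abs=1e-12)

    def test_known_paraboloid_peak_recovered(self):
        ys, xs = np.mgrid[:7, :7]
        surface = 1.0 - 0.05 * (xs - 3.3) ** 2 - 0.08 * (ys - 2.6) ** 2
        (sx, sy), ok = refine_subpixel(surface, (3, 3))
        assert ok
        assert (sx, sy) == pytest.approx((3.3, 2.6), abs=1e-9)

    def test_flat_surface_flags_failure(self):
        (sx, sy), ok = refine_subpixel(np.ones((5, 5)), (2, 2))
        assert not ok and (sx, sy) == (2.0, 2.0)

    def test_border_peak_rejected(self):
        with pytest.raises(ValueError, match="border"):
            refine_subpixel(np.ones((5, 5)), (0, 2))

    def test_noise_free_subpixel_recovery(self, template):
        """Cross rendered at (64.30, 40.70) is recovered within 0.02 px."""
        clip = _frame_with_cross([(64.30, 40.70)])
        trk = track_clip(clip, [(64.0, 41.0)], template)[0]
        assert trk.positions[0] == pytest.approx((64.30, 40.70), abs=0.02)

    def test_noisy_subpixel_recovery_monte_carlo(self, template):
        """With sensor noise sigma=0.01 the center stays within 0.1 px
        (20 seeded realizations)."""
        for seed in range(1, 21):
            clip = _frame_with_cross([(64.30, 40.70)], seed=seed, noise=0.01)
            trk = track_clip(clip, [(64.0, 41.0)], template)[0]
            assert trk.positions[0] == pytest.approx((64.30, 40.70), abs=0.1)


class TestTrackClip:
    def test_static_clip_positions_constant(self, template):
        cfg = small_scene(duration_s=0.02)
        clip, _ = simulate_clip(cfg)
        trk = track_clip(clip, [(48.0, 48.0)], template)[0]
        assert np.abs(trk.positions - trk.positions[0]).max() < 1e-6

    def test_half_pixel_sinusoid_tracked_accurately(self, template):
        """A +/-0.5 px translation (already-amplified scale) tracks to
        better than 0.05 px per frame."""
        amp_um = 0.5 * PITCH[0] * 1000  # 0.5 px on the x axis
        cfg = small_scene(
            duration_s=0.2,
            markers=(
                MarkerSpec(center_px=(48.0, 48.0), arm_length_mm=8.0, tones=(tone(amp_um),)),
            ),
        )
        clip, gt = simulate_clip(cfg)
        trk = track_clip(clip, [(48.0, 48.0)], template)[0]
        tracked_dx = trk.positions[:, 0] - trk.positions[:, 0].mean()
        assert np.abs(tracked_dx - gt.disp_px[0, :, 0]).max() < 0.05

    def test_integer_shift_equivariance(self, template):
        cfg = small_scene(duration_s=0.05, noise_sigma=0.005)
        clip, _ = simulate_clip(cfg)
        dx, dy = 3, -2
        shifted = FrameStack(np.roll(clip.frames, (dy, dx), axis=(1, 2)), clip.fps)
        base = track_clip(clip, [(48.0, 48.0)], template)[0]
        moved = track_clip(shifted, [(48.0 + dx, 48.0 + dy)], template)[0]
        np.testing.assert_allclose(
            moved.positions, base.positions + np.array([dx, dy]), atol=1e-9
        )

    def test_static_noise_floor_below_tenth_pixel(self, template):
        """Tracked position SD on a noisy static scene stays below 0.1 px:
        the tracker's detection floor."""
        cfg = small_scene(duration_s=0.1, noise_sigma=0.01, seed=5)
        clip, _ = simulate_clip(cfg)
        trk = track_clip(clip, [(48.0, 48.0)], template)[0]
        assert trk.positions.std(axis=0).max() < 0.1

    def test_error_decreases_with_noise(self, template):
        """Mean tracking error is non-increasing as sensor noise drops
        (3 noise levels, 10 seeds each)."""
        mean_err = []
        for sigma in (0.02, 0.005, 0.001):
            errs = []
            for seed in range(10):
                cfg = small_scene(
                    width_px=64,
                    height_px=64,
                    duration_s=0.05,
                    noise_sigma=sigma,
                    seed=seed,
                    markers=(MarkerSpec(center_px=(32.0, 32.0), arm_length_mm=8.0),),
                )
                clip, _ = simulate_clip(cfg)
                trk = track_clip(clip, [(32.0, 32.0)], template)[0]
                errs.append(np.abs(trk.positions - (32.0, 32.0)).mean())
            mean_err.append(np.mean(errs))
        assert mean_err[0] >= mean_err[1] >= mean_err[2]

    def test_unmatchable_clip_raises(self, template):
        frames = np.random.default_rng(0).random((20, 96, 96))
        with pytest.raises(TrackingError, match="m0"):
            track_clip(FrameStack(frames, 1000.0), [(48.0, 48.0)], template)

    def test_centroid_method_close_to_paraboloid(self, template):
        clip = _frame_with_cross([(64.30, 40.70)])
        para = track_clip(clip, [(64.0, 41.0)], template, method="paraboloid")[0]
        cent = track_clip(clip, [(64.0, 41.0)], template, method="centroid")[0]
        assert np.abs(para.positions[0] - cent.positions[0]).max() < 0.1


class TestCalibrate:
    def test_simple_ratio(self):
        cal = calibrate((10.0, 10.0), (20.0, 20.0))
        assert cal.mm_per_px_x == pytest.approx(0.5)
        assert cal.mm_per_px_y == pytest.approx(0.5)

    def test_uncertainty_first_order_propagation(self):
        cal = calibrate((10.0, 10.0), (20.0, 20.0), extent_error_px=0.5)
        assert cal.uncertainty_mm_per_px[0] == pytest.approx(10 / 20**2 * 0.5)

    def test_default_calibration_is_half_millimeter_scale(self):
        assert DEFAULT_CALIBRATION.mm_per_px_x == 0.49
        assert DEFAULT_CALIBRATION.mm_per_px_y == 0.46

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate((10.0, 10.0), (0.0, 20.0))
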