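import numpy as np
import pytest

from fieldtrack import ArenaGeometry, MotionSpec, Trajectory
from fieldtrack.preprocess import (
    BinaryStack,
    FrameStack,
    antialias,
    align_background,
    detect_arena,
    minimum_threshold_value,
    preprocess_pair,
    spatial_bin,
    subtract_background,
    threshold_minimum,
    track_blobs,
)
from fieldtrack.synthetic import generate_trajectory, render_video


def disc_frame(cx, cy, r, width=320, height=240, fg=200, bg=30):
    yy, xx = np.ogrid[:height, :width]
    frame = np.full((height, width), bg, dtype=np.uint8)
    frame[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = fg
    return frame


class TestSpatialBin:
    def test_640x480_binned_to_320x240(self):
        stack = FrameStack(np.zeros((2, 480, 640), dtype=np.uint8))
        out = spatial_bin(stack, 2)
        assert (out.width, out.height) == (320, 240)

    def test_factor_one_identity(self):
        stack = FrameStack(np.arange(16, dtype=np.uint8).reshape(1, 4, 4))
        assert spatial_bin(stack, 1) is stack

    def test_block_mean_of_constant(self):
        stack = FrameStack(np.full((1, 4, 4), 100, dtype=np.uint8))
        out = spatial_bin(stack, 2)
        np.testing.assert_array_equal(out.frames, np.full((1, 2, 2), 100))

    def test_non_divisible_names_padding(self):
        stack = FrameStack(np.zeros((1, 5, 6), dtype=np.uint8))
        with pytest.raises(ValueError, match="pad to"):
            spatial_bin(stack, 2)


class TestDetectArena:
    def test_synthetic_disc_geometry(self):
        arena = detect_arena(disc_frame(160, 120, 100))
        assert arena.centre_x == pytest.approx(160, abs=1)
        assert arena.centre_y == pytest.approx(120, abs=1)
        assert arena.radius == pytest.approx(100, abs=1)

    def test_blank_frame_raises(self):
        with pytest.raises(ValueError, match="no circular arena"):
            detect_arena(np.full((240, 320), 128, dtype=np.uint8))

    def test_translation_equivariance(self):
        a = detect_arena(disc_frame(160, 120, 80))
        b = detect_arena(disc_frame(165, 117, 80))
        assert b.centre_x - a.centre_x == pytest.approx(5, abs=0.5)
        assert b.centre_y - a.centre_y == pytest.approx(-3, abs=0.5)

    def test_square_region_rejected(self):
        frame = np.full((240, 320), 30, dtype=np.uint8)
        frame[40:200, 60:280] = 200  # rectangle, not a disc
        with pytest.raises(ValueError, match="no circular arena"):
            detect_arena(frame)


class TestAlignBackground:
    def test_identical_stacks_zero_shift(self):
        frames = np.stack([disc_frame(160, 120, 100)] * 3)
        exp = FrameStack(frames)
        bg = FrameStack(frames.copy())
        out = align_background(exp, bg)
        np.testing.assert_array_equal(out.frames, exp.frames)

    @pytest.mark.parametrize("dx, dy", [(4, 0), (3, 7), (-5, 2)])
    def test_known_shift_recovered(self, dx, dy):
        exp = FrameStack(np.stack([disc_frame(160, 120, 90)] * 2))
        bg = FrameStack(np.stack([disc_frame(160 - dx, 120 - dy, 90)] * 2))
        aligned = align_background(exp, bg)
        # oracle: exhaustive integer-shift search minimising |difference|
        best = min(
            (
                (np.abs(np.roll(bg.frames[0], (sy, sx), axis=(0, 1)).astype(int)
                        - exp.frames[0]).mean(), (sx, sy))
                for sx in range(-8, 9)
                for sy in range(-8, 9)
            )
        )[1]
        assert best == (dx, dy)
        assert np.abs(aligned.frames[0].astype(int) - exp.frames[0]).mean() \
            <= np.abs(bg.frames[0].astype(int) - exp.frames[0]).mean()
        assert detect_arena(aligned.frames[0]).centre_x == pytest.approx(160, abs=1)


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self):
        frames = np.stack([disc_frame(160, 120, 100)] * 4)
        stack = FrameStack(frames)
        out = subtract_background(stack, FrameStack(frames.copy()))
        assert out.frames.max() == 0

    def test_nonzero_only_at_blob(self):
        bg = np.stack([disc_frame(160, 120, 100)] * 3)
        exp = bg.copy()
        exp[:, 115:125, 155:165] = 60  # dark blob on the bright floor
        diff = subtract_background(FrameStack(exp), FrameStack(bg))
        assert diff.frames[:, 115:125, 155:165].min() > 0
        mask = np.zeros_like(diff.frames, dtype=bool)
        mask[:, 115:125, 155:165] = True
        assert diff.frames[~mask].max() == 0

    def test_contrast_linearity(self):
        bg = np.stack([np.full((40, 40), 200, dtype=np.uint8)])
        exp1, exp2 = bg.copy(), bg.copy()
        exp1[:, 10:20, 10:20] = 180  # -20
        exp2[:, 10:20, 10:20] = 160  # -40
        d1 = subtract_background(FrameStack(exp1), FrameStack(bg))
        d2 = subtract_background(FrameStack(exp2), FrameStack(bg))
        np.testing.assert_array_equal(2 * d1.frames[:, 10:20, 10:20],
                                      d2.frames[:, 10:20, 10:20])


class TestThresholdMinimum:
    def test_two_delta_histogram(self):
        counts = np.zeros(256)
        counts[10], counts[200] = 5000, 300
        thresh = minimum_threshold_value(counts)
        assert 10 < thresh < 200

    def test_constant_frames_raise(self):
        stack = FrameStack(np.full((3, 20, 20), 77, dtype=np.uint8))
        with pytest.raises(ValueError, match="bimodal"):
            threshold_minimum(stack)

    def test_gaussian_mixture_misclassification_below_0_1_percent(self, rng):
        n = 200_000
        lo = rng.normal(30, 10, n)
        hi = rng.normal(220, 10, n // 4)
        values = np.clip(np.round(np.concatenate([lo, hi])), 0, 255).astype(np.uint8)
        stack = FrameStack(values.reshape(1, -1, 500))
        binary = threshold_minimum(stack)
        # oracle: classify by the nearer mixture mean
        oracle = values > 125
        assert np.mean(binary.frames.ravel() != oracle) < 1e-3


class TestAntialias:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((1, 30, 30), dtype=bool)
        mask[0, 15, 15] = True
        out = antialias(BinaryStack(mask))
        assert not out.frames.any()

    def test_large_square_nearly_unchanged(self):
        mask = np.zeros((1, 60, 60), dtype=bool)
        mask[0, 20:40, 20:40] = True
        out = antialias(BinaryStack(mask))
        assert abs(out.frames.sum() - 400) / 400 < 0.05

    def test_idempotent_on_smooth_blobs(self, rng):
        # oracle: direct double application on random disc unions
        yy, xx = np.ogrid[:80, :80]
        mask = np.zeros((1, 80, 80), dtype=bool)
        for _ in range(4):
            cx, cy = rng.uniform(20, 60, 2)
            mask[0] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= rng.uniform(6, 12) ** 2
        once = antialias(BinaryStack(mask))
        twice = antialias(once)
        np.testing.assert_array_equal(once.frames, twice.frames)


class TestTrackBlobs:
    @staticmethod
    def moving_disc_stack(n=30, step=2.0, r=6, start=(40.0, 60.0)):
        yy, xx = np.ogrid[:120, :160]
        frames = np.zeros((n, 120, 160), dtype=bool)
        truth = []
        for i in range(n):
            cx, cy = start[0] + step * i, start[1]
            frames[i] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            truth.append((cx, cy))
        return BinaryStack(frames, frame_rate=25.0), truth

    def test_moving_disc_step_recovered(self):
        stack, truth = self.moving_disc_stack()
        traj = track_blobs(stack, min_area=20, max_area=500, max_step=20)
        assert len(traj) == 30
        dx = np.diff(traj.x)
        np.testing.assert_allclose(dx, 2.0, atol=0.5)

    def test_stationary_disc_constant_centroid(self):
        stack, _ = self.moving_disc_stack(n=10, step=0.0)
        traj = track_blobs(stack, min_area=20, max_area=500, max_step=20)
        assert np.ptp(traj.x) == 0 and np.ptp(traj.y) == 0

    def test_speck_noise_removed_by_antialias_gives_clean_track(self, rng):
        stack, _ = self.moving_disc_stack()
        clean = track_blobs(antialias(stack), min_area=20, max_area=500,
                            max_step=20)
        noisy_frames = stack.frames.copy()
        for i in range(stack.n_frames):
            for _ in range(20):
                noisy_frames[i, rng.integers(0, 120), rng.integers(0, 160)] = True
        noisy = track_blobs(
            antialias(BinaryStack(noisy_frames, 25.0)),
            min_area=20, max_area=500, max_step=20,
        )
        np.testing.assert_allclose(noisy.x, clean.x, atol=0.2)
        np.testing.assert_allclose(noisy.y, clean.y, atol=0.2)

    def test_short_gap_interpolated(self):
        stack, _ = self.moving_disc_stack(n=20)
        frames = stack.frames.copy()
        frames[8:11] = False  # 3 empty frames
        traj = track_blobs(BinaryStack(frames, 25.0), min_area=20,
                           max_area=500, max_step=20)
        assert len(traj) == 20  # bridged
        assert np.all(np.diff(traj.frames) == 1)
        np.testing.assert_allclose(np.diff(traj.x), 2.0, atol=0.5)

    def test_long_gap_splits_longest_run_wins(self):
        stack, _ = self.moving_disc_stack(n=30)
        frames = stack.frames.copy()
        frames[10:18] = False  # 8 empty frames > max_gap
        traj = track_blobs(BinaryStack(frames, 25.0), min_area=20,
                           max_area=500, max_step=20)
        assert len(traj) == 12  # frames 18..29
        assert traj.frames[0] == 18

    def test_mostly_empty_stack_errors(self):
        frames = np.zeros((10, 50, 50), dtype=bool)
        frames[0, 10:20, 10:20] = True
        with pytest.raises(ValueError, match="tracking failed"):
            track_blobs(BinaryStack(frames, 25.0), min_area=20, max_area=500,
                        max_step=20)


class TestEndToEnd:
    def test_render_preprocess_track_recovers_truth(self, arena):
        spec = MotionSpec(kind="circle", radius=60, angular_speed=0.5,
                          duration=30, frame_rate=2.5)
        traj, _ = generate_trajectory(spec)
        exp, bg = render_video(traj, arena)
        tracked = preprocess_pair(exp, bg, bin_factor=1)
        assert len(tracked) == len(traj)
        err = np.hypot(tracked.x - traj.x, tracked.y - traj.y)
        assert err.mean() < 1.0

    def test_translation_equivariance_of_pipeline(self, arena):
        spec = MotionSpec(kind="circle", radius=40, angular_speed=0.5,
                          duration=20, frame_rate=2.5)
        traj, _ = generate_trajectory(spec)
        exp, bg = render_video(traj, arena)
        shifted_exp = FrameStack(np.roll(exp.frames, (6, 10), axis=(1, 2)),
                                 exp.frame_rate)
        shifted_bg = FrameStack(np.roll(bg.frames, (6, 10), axis=(1, 2)),
                                bg.frame_rate)
        a = preprocess_pair(exp, bg, bin_factor=1)
        b = preprocess_pair(shifted_exp, shifted_bg, bin_factor=1)
        np.testing.assert_allclose(b.x, a.x + 10, atol=1e-6)
        np.testing.assert_allclose(b.y, a.y + 6, atol=1e-6)

    def test_background_only_pair_yields_no_track(self, arena):
        spec = MotionSpec(kind="line", centre_x=60, centre_y=120,
                          linear_speed=5, duration=10, frame_rate=2.5)
        traj, _ = generate_trajectory(spec)
        _, bg = render_video(traj, arena)
        with pytest.raises(ValueError):
            preprocess_pair(bg, bg, bin_factor=1)
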