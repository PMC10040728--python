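import numpy as np
import pytest

from fidgetkit import (
    BlurSpec,
    KeypointSequence,
    apply_blur,
    blur_video,
    build_mask_track,
    expected_noise_fraction,
    mask_center_raw,
)
from fidgetkit.deidentify import (
    FrameAlignmentError,
    NoFaceAnchorError,
    _ellipse_mask,
)
from fidgetkit.skeleton import N_KEYPOINTS


def _frame_with_head(eyL, eyR, ns, erL, erR):
    """(25, 3) frame with the 5 head keypoints set and body zeros."""
    kps = np.zeros((N_KEYPOINTS, 3))
    for i, kp in enumerate([eyL, eyR, ns, erL, erR]):
        kps[i] = kp
    return kps


def box_blur_oracle(img, center, spec):
    """Direct double-loop normalized box convolution composited in-ellipse."""
    k = spec.kernel
    pad = k // 2
    arr = img.astype(float)
    padded = np.pad(arr, pad, mode="symmetric")
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = padded[i: i + k, j: j + k].mean()
    res = img.copy()
    inside = _ellipse_mask(arr.shape, center, spec)
    res[inside] = np.clip(np.rint(out[inside]), 0, 255).astype(np.uint8)
    return res


class TestMaskCenter:
    def test_printed_mean_formulas(self):
        frame = _frame_with_head(
            (100, 50, 0.9), (140, 50, 0.9), (120, 70, 0.9),
            (80, 60, 0.8), (160, 60, 0.8),
        )
        (cx, cy), gated = mask_center_raw(frame, None, BlurSpec())
        assert gated
        assert cx == pytest.approx(120.0)       # mean of 5 head x
        assert cy == pytest.approx(56.6667, abs=1e-3)  # mean of eye/nose y

    def test_identical_head_points_give_that_point(self):
        frame = _frame_with_head(*[(300, 200, 1.0)] * 5)
        (cx, cy), _ = mask_center_raw(frame, None, BlurSpec())
        assert (cx, cy) == (300, 200)

    def test_gate_failure_carries_forward(self):
        frame = _frame_with_head(
            (100, 50, 0.3), (140, 50, 0.3), (120, 70, 0.3),
            (80, 60, 0.8), (160, 60, 0.8),
        )
        center, gated = mask_center_raw(frame, (200, 100), BlurSpec())
        assert not gated and center == (200, 100)

    def test_gate_uses_eye_nose_reliability_only(self):
        # ears at r=0 must not affect the gate
        frame = _frame_with_head(
            (100, 50, 0.5), (140, 50, 0.5), (120, 70, 0.5),
            (0, 0, 0.0), (0, 0, 0.0),
        )
        (cx, _), gated = mask_center_raw(frame, None, BlurSpec())
        assert gated
        # undetected ears excluded from the x-mean by default
        assert cx == pytest.approx(120.0)

    def test_strict_literal_mode_includes_zero_ears(self):
        frame = _frame_with_head(
            (100, 50, 0.5), (140, 50, 0.5), (120, 70, 0.5),
            (0, 0, 0.0), (0, 0, 0.0),
        )
        (cx, _), _ = mask_center_raw(frame, None, BlurSpec(strict_literal=True))
        assert cx == pytest.approx(360 / 5)


class TestMaskTrack:
    def test_ema_hand_recursion(self, head_track_sequence):
        track = build_mask_track(head_track_sequence, BlurSpec(a=0.5))
        np.testing.assert_allclose(track.centers[:, 0], [0.0, 5.0, 7.5])

    def test_backfill_of_leading_gate_failures(self):
        data = np.zeros((3, N_KEYPOINTS, 3))
        data[0, :5] = [[5, 5, 0.1]] * 5      # fails gate
        data[1, :5] = [[10, 10, 0.9]] * 5
        data[2, :5] = [[10, 10, 0.9]] * 5
        track = build_mask_track(KeypointSequence(data=data), BlurSpec())
        np.testing.assert_allclose(track.centers[:, 0], [10, 10, 10])
        assert track.n_carried_forward == 1

    def test_a_zero_is_identity_on_raw_track(self, head_track_sequence):
        track = build_mask_track(head_track_sequence, BlurSpec(a=0.0))
        np.testing.assert_allclose(track.centers[:, 0], [0, 10, 10])

    def test_constant_track_is_ema_fixed_point(self):
        data = np.zeros((4, N_KEYPOINTS, 3))
        data[:, :5] = [[50, 40, 0.9]] * 5
        track = build_mask_track(KeypointSequence(data=data))
        np.testing.assert_allclose(track.centers, [[50, 40]] * 4)

    def test_no_gated_frame_raises(self):
        data = np.zeros((3, N_KEYPOINTS, 3))
        data[:, :5, 2] = 0.1
        with pytest.raises(NoFaceAnchorError):
            build_mask_track(KeypointSequence(data=data))

    def test_ema_stays_in_convex_hull_of_raw_centers(self):
        rng = np.random.default_rng(0)
        data = np.zeros((50, N_KEYPOINTS, 3))
        xs = rng.uniform(100, 500, size=50)
        for f in range(50):
            data[f, :5] = [[xs[f], xs[f] / 2, 0.9]] * 5
        track = build_mask_track(KeypointSequence(data=data))
        assert track.centers[:, 0].min() >= xs.min() - 1e-9
        assert track.centers[:, 0].max() <= xs.max() + 1e-9

    def test_gating_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        data = np.zeros((40, N_KEYPOINTS, 3))
        for f in range(40):
            r = rng.uniform(0, 1)
            data[f, :5] = [[100, 100, r]] * 5
        carried = [
            build_mask_track(KeypointSequence(data=data),
                             BlurSpec(r_thresh=th)).n_carried_forward
            for th in (0.1, 0.35, 0.6, 0.85)
        ]
        assert carried == sorted(carried)


class TestApplyBlur:
    def test_outside_ellipse_bit_identical(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(80, 80), dtype=np.uint8)
        spec = BlurSpec(mask_w=30, mask_h=16, kernel=5)
        out = apply_blur(img, (40, 40), spec, np.random.default_rng(0))
        inside = _ellipse_mask(img.shape, (40, 40), spec)
        np.testing.assert_array_equal(out[~inside], img[~inside])

    def test_constant_image_noise_off_is_fixed_point(self):
        img = np.full((60, 60), 77, dtype=np.uint8)
        out = apply_blur(img, (30, 30),
                         BlurSpec(noise_enabled=False, kernel=9))
        np.testing.assert_array_equal(out, img)

    def test_matches_convolution_oracle_on_random_images(self):
        rng = np.random.default_rng(3)
        spec = BlurSpec(mask_w=30, mask_h=16, kernel=5, noise_enabled=False)
        for _ in range(5):
            img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
            center = (rng.uniform(10, 54), rng.uniform(10, 54))
            np.testing.assert_array_equal(
                apply_blur(img, center, spec),
                box_blur_oracle(img, center, spec),
            )

    def test_blur_reduces_variance_inside_ellipse(self):
        yy, xx = np.mgrid[0:64, 0:64]
        checker = (((xx // 4) + (yy // 4)) % 2 * 255).astype(np.uint8)
        spec = BlurSpec(mask_w=40, mask_h=24, kernel=9, noise_enabled=False)
        out = apply_blur(checker, (32, 32), spec)
        inside = _ellipse_mask(checker.shape, (32, 32), spec)
        assert out[inside].astype(float).var() < checker[inside].astype(float).var()

    def test_ellipse_outside_image_warns_and_returns_copy(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        with pytest.warns(UserWarning, match="outside"):
            out = apply_blur(img, (500, 500), BlurSpec())
        np.testing.assert_array_equal(out, img)

    def test_three_channel_images_supported(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = apply_blur(img, (32, 32), BlurSpec(mask_w=30, mask_h=16, kernel=5),
                         np.random.default_rng(0))
        assert out.shape == img.shape


class TestBlurVideo:
    def _video_and_seq(self, n=4):
        rng = np.random.default_rng(5)
        frames = [rng.integers(0, 256, size=(60, 80), dtype=np.uint8)
                  for _ in range(n)]
        data = np.zeros((n, N_KEYPOINTS, 3))
        data[:, :5] = [[40, 30, 0.9]] * 5
        return frames, KeypointSequence(data=data)

    def test_shape_preserved_and_deterministic(self):
        frames, seq = self._video_and_seq()
        spec = BlurSpec(mask_w=30, mask_h=16, kernel=5)
        r1 = blur_video(frames, seq, spec, seed=11)
        r2 = blur_video(frames, seq, spec, seed=11)
        assert r1["n_frames"] == 4
        for a, b in zip(r1["frames"], r2["frames"]):
            np.testing.assert_array_equal(a, b)
            assert a.shape == (60, 80)

    def test_frame_count_mismatch_raises(self):
        frames, seq = self._video_and_seq()
        with pytest.raises(FrameAlignmentError, match="3.*4|4.*3"):
            blur_video(frames[:3], seq, BlurSpec(), seed=0)

    def test_png_directory_round_trip(self, tmp_path):
        import imageio.v3 as iio

        frames, seq = self._video_and_seq()
        indir = tmp_path / "in"
        indir.mkdir()
        for i, f in enumerate(frames, start=1):
            iio.imwrite(indir / f"frame_{i:06d}.png", f)
        outdir = tmp_path / "out"
        res = blur_video(indir, seq, BlurSpec(mask_w=30, mask_h=16, kernel=5),
                         seed=3, video_out=outdir)
        assert res["n_frames"] == 4
        assert len(sorted(outdir.glob("*.png"))) == 4


def test_expected_noise_fraction_is_about_five_percent():
    assert expected_noise_fraction() == pytest.approx(12.5 / 255)
    assert expected_noise_fraction(BlurSpec(noise_max=25)) == pytest.approx(
        0.049, abs=0.001
    )
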