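"""Keypoint-driven face blurring for infant videos.

The mask center is anchored on the five head keypoints: horizontally on
eyes + nose + ears, vertically on eyes + nose only, so the eye/nose
region is obscured while the mouth stays visible for behavioural
assessment. The center updates only when the mean eye/nose reliability
clears a gate (default 0.35); otherwise it is carried forward from the
previous frame. An exponential moving average then removes jerk, and an
axis-aligned elliptic region (default 150x68 px) is replaced by a
normalized k x k box blur (default k=25) plus additive integer uniform
noise (default U[0, 25], about 5% of the 8-bit range) to hinder
deblurring-based reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .skeleton import EYES_NOSE_INDICES, HEAD_INDICES, KeypointSequence


class NoFaceAnchorError(RuntimeError):
    """No frame in the sequence ever passed the reliability gate."""


class FrameAlignmentError(ValueError):
    """Video frame count does not match the keypoint sequence."""


@dataclass(frozen=True)
class BlurSpec:
    """Parameters of the blurring procedure (defaults as published)."""

    r_thresh: float = 0.35   # gate on mean eye/nose reliability
    a: float = 0.5           # EMA coefficient
    mask_w: float = 150.0    # ellipse full width, px
    mask_h: float = 68.0     # ellipse full height, px
    kernel: int = 25         # box-filter size, px (odd)
    noise_max: int = 25      # max additive noise, intensity units
    noise_enabled: bool = True
    strict_literal: bool = False  # include r=0 keypoints in the c_x mean

    def __post_init__(self) -> None:
        if not 0 <= self.r_thresh <= 1:
            raise ValueError("r_thresh must be in [0, 1]")
        if not 0 <= self.a < 1:
            raise ValueError("EMA coefficient a must be in [0, 1)")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")
        if self.mask_w <= 0 or self.mask_h <= 0:
            raise ValueError("mask dimensions must be positive")
        if self.noise_max < 0:
            raise ValueError("noise_max must be >= 0")


@dataclass
class MaskTrack:
    """Per-frame blur-mask centers with gating provenance.

    ``gated[f]`` is True where the reliability gate passed and the
    center was recomputed; False where it was carried forward (or
    back-filled at the start).
    """

    centers: np.ndarray  # (n_frames, 2) float, (c_x, c_y)
    gated: np.ndarray    # (n_frames,) bool

    @property
    def n_carried_forward(self) -> int:
        return int((~self.gated).sum())


def mask_center_raw(
    frame_kps: np.ndarray,
    prev_center: tuple[float, float] | None,
    spec: BlurSpec,
) -> tuple[tuple[float, float] | None, bool]:
    """Raw (ungated-smoothing-free) mask center for one frame.

    ``frame_kps`` is the (25, 3) canonical keypoint array of the frame.
    Returns ``(center, gated)``; center is None when the gate fails on a
    frame with no previous center (resolved later by back-fill).
    """
    head = frame_kps[[i - 1 for i in HEAD_INDICES]]
    eyes_nose = frame_kps[[i - 1 for i in EYES_NOSE_INDICES]]
    r_avg = float(eyes_nose[:, 2].mean())
    if r_avg > spec.r_thresh:
        if spec.strict_literal:
            cx_pts = head[:, 0]
        else:
            # undetected keypoints sit at (0, 0); including them would
            # drag the center toward the image corner
            detected = head[:, 2] > 0
            cx_pts = head[detected, 0] if detected.any() else head[:, 0]
        c_x = float(np.mean(cx_pts))
        c_y = float(eyes_nose[:, 1].mean())
        return (c_x, c_y), True
    return prev_center, False


def build_mask_track(seq: KeypointSequence, spec: BlurSpec | None = None) -> MaskTrack:
    """Gated carry-forward pass, back-fill of leading frames, then EMA.

    The EMA ``c(f) = a*c(f-1) + (1-a)*c(f)`` starts at f=2 with the
    first frame unchanged; gating consumes raw (unsmoothed) previous
    centers, so the two passes are independent.
    """
    spec = spec or BlurSpec()
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    centers: list[tuple[float, float] | None] = []
    gated = np.zeros(seq.n_frames, dtype=bool)
    prev: tuple[float, float] | None = None
    for f in range(seq.n_frames):
        center, ok = mask_center_raw(seq.data[f], prev, spec)
        centers.append(center)
        gated[f] = ok
        prev = center
    if not gated.any():
        raise NoFaceAnchorError(
            "no frame passed the reliability gate; cannot place a blur mask"
        )
    first_ok = int(np.argmax(gated))
    for f in range(first_ok):  # back-fill leading pending frames
        centers[f] = centers[first_ok]
    track = np.asarray(centers, dtype=float)
    smoothed = track.copy()
    for f in range(1, len(smoothed)):
        smoothed[f] = spec.a * smoothed[f - 1] + (1 - spec.a) * track[f]
    return MaskTrack(centers=smoothed, gated=gated)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  spec: BlurSpec) -> np.ndarray:
    h, w = shape
    cy, cx = center[1], center[0]
    yy, xx = np.mgrid[0:h, 0:w]
    a, b = spec.mask_w / 2.0, spec.mask_h / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def apply_blur(
    image: np.ndarray,
    center: tuple[float, float],
    spec: BlurSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Blur the elliptic face region of one frame.

    Pixels outside the ellipse are returned bit-identical. Inside, the
    image is replaced by its normalized box filter (reflected borders,
    computed over the surrounding image so border pixels mix with the
    unblurred context exactly as a whole-frame blur would) plus, when
    enabled, independent per-pixel-per-channel integer noise uniform on
    [0, noise_max], clipped to the 8-bit range.
    """
    spec = spec or BlurSpec()
    if rng is None:
        rng = np.random.default_rng()
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    gray = img.ndim == 2
    arr = img[:, :, None] if gray else img
    h, w = arr.shape[:2]

    cx, cy = center
    a, b = spec.mask_w / 2.0, spec.mask_h / 2.0
    if cx + a < 0 or cx - a > w - 1 or cy + b < 0 or cy - b > h - 1:
        warnings.warn("blur ellipse lies fully outside the image; frame unchanged")
        return img.copy()

    pad = spec.kernel // 2 + 1
    x0 = max(0, int(np.floor(cx - a)) - pad)
    x1 = min(w, int(np.ceil(cx + a)) + pad + 1)
    y0 = max(0, int(np.floor(cy - b)) - pad)
    y1 = min(h, int(np.ceil(cy + b)) + pad + 1)

    crop = arr[y0:y1, x0:x1].astype(float)
    blurred = np.empty_like(crop)
    for c in range(crop.shape[2]):
        blurred[:, :, c] = ndimage.uniform_filter(
            crop[:, :, c], size=spec.kernel, mode="reflect"
        )
    inside = _ellipse_mask((y1 - y0, x1 - x0), (cx - x0, cy - y0), spec)
    out = arr.copy()
    region = out[y0:y1, x0:x1]
    vals = blurred[inside]
    if spec.noise_enabled and spec.noise_max > 0:
        vals = vals + rng.integers(0, spec.noise_max + 1, size=vals.shape)
    region[inside] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
    out[y0:y1, x0:x1] = region
    return out[:, :, 0] if gray else out


def _load_frames(video_in) -> list[np.ndarray]:
    if isinstance(video_in, (str, Path)):
        files = sorted(Path(video_in).glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no .png frames in {video_in}")
        return [iio.imread(f) for f in files]
    return [np.asarray(f) for f in video_in]


def blur_video(
    video_in,
    seq: KeypointSequence,
    spec: BlurSpec | None = None,
    seed: int = 0,
    video_out: str | Path | None = None,
) -> dict:
    """Blur every frame of a video at its tracked mask center.

    ``video_in`` is a numbered-PNG directory or an iterable of frames;
    ``video_out``, when given, receives numbered PNGs. Deterministic
    under a fixed seed. Returns a summary record.
    """
    spec = spec or BlurSpec()
    frames = _load_frames(video_in)
    if len(frames) != seq.n_frames:
        raise FrameAlignmentError(
            f"video has {len(frames)} frames but keypoint sequence has {seq.n_frames}"
        )
    track = build_mask_track(seq, spec)
    rng = np.random.default_rng(seed)
    out_frames = []
    noise_sum, noise_n = 0.0, 0
    for f, frame in enumerate(frames):
        before = frame
        after = apply_blur(frame, tuple(track.centers[f]), spec, rng)
        changed = after.astype(int) - before.astype(int)
        noise_sum += float(np.abs(changed).sum())
        noise_n += int((changed != 0).size)
        out_frames.append(after)
    if video_out is not None:
        outdir = Path(video_out)
        outdir.mkdir(parents=True, exist_ok=True)
        ndigits = max(6, len(str(len(out_frames))))
        for f, frame in enumerate(out_frames, start=1):
            iio.imwrite(outdir / f"frame_{f:0{ndigits}d}.png", frame)
    return {
        "n_frames": len(out_frames),
        "n_carried_forward": track.n_carried_forward,
        "mean_abs_change": noise_sum / max(noise_n, 1),
        "frames": out_frames if video_out is None else None,
    }


def expected_noise_fraction(spec: BlurSpec | None = None) -> float:
    """Mean of U[0, noise_max] as a fraction of the 8-bit range.

    With the default noise_max=25 this is 12.5/255 ~ 4.9%, i.e. about
    5% relative noise.
    """
    spec = spec or BlurSpec()
    return (spec.noise_max / 2.0) / 255.0
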