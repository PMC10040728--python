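"""Synthetic inputs for the whole pipeline.

Real infant videos cannot be shared, so every input the pipeline
consumes is emulated here at desk scale:

* 250-frame, 25-keypoint trajectories of a supine infant on a
  1920x1080 canvas. Slow postural motion (0.1-1 Hz, 20-60 px) is
  realized as a whole-body sway shared by all keypoints — an infant on
  a mat shifts and rotates largely as a unit — plus a small independent
  per-keypoint drift and frame-to-frame jitter. FM+ snippets
  additionally superpose small band-limited bursts (2-5 Hz, 5-15 px) on
  the wrists and ankles over a fraction of the frames. Head keypoints
  receive base motion only in both classes, so by construction the
  class signal lives exclusively in the limbs — the property the
  head-ablation experiment probes.
* detection dropout ((x, y, r) zeroed independently per
  keypoint-frame) and Beta(8, 2) reliability scores;
* renderable grayscale frames with limb segments and a face-like
  elliptic blob carrying two dark eye dots, for blur demonstrations;
* paired rater label tables with a controlled target kappa via a
  symmetric label-flip model.

The burst band (2-5 Hz) is a generator parameter chosen to be separable
from the postural band while staying far below the 25 Hz Nyquist limit
of 50-fps video; it is not a claim about the kinematics of real fidgety
movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .agreement import LABELS, NA, RatingTable
from .skeleton import (
    HEAD_INDICES,
    LIMB_END_INDICES,
    N_KEYPOINTS,
    KeypointSequence,
)

#: resting pose of a supine infant, canonical order, px on a 1920x1080 canvas
DEFAULT_TEMPLATE: dict[int, tuple[float, float]] = {
    1: (985, 185),   # left eye
    2: (935, 185),   # right eye
    3: (960, 210),   # nose
    4: (1015, 205),  # left ear
    5: (905, 205),   # right ear
    6: (960, 320),   # neck
    7: (860, 360),   # right shoulder
    8: (800, 480),   # right elbow
    9: (780, 590),   # right wrist
    10: (1060, 360),  # left shoulder
    11: (1120, 480),  # left elbow
    12: (1140, 590),  # left wrist
    13: (960, 640),   # mid hip
    14: (900, 655),   # right hip
    15: (870, 790),   # right knee
    16: (850, 920),   # right ankle
    17: (1020, 655),  # left hip
    18: (1110, 790),  # left knee
    19: (1130, 920),  # left ankle
    20: (1140, 990),  # left big toe
    21: (840, 990),   # right big toe
    22: (1160, 995),  # left small toe
    23: (820, 995),   # right small toe
    24: (1125, 960),  # left heel
    25: (855, 960),   # right heel
}

#: skeleton edges (canonical indices) used by the frame renderer
SKELETON_EDGES: tuple[tuple[int, int], ...] = (
    (6, 7), (7, 8), (8, 9), (6, 10), (10, 11), (11, 12),
    (6, 13), (13, 14), (14, 15), (15, 16), (13, 17), (17, 18), (18, 19),
    (16, 21), (19, 20),
)


@dataclass
class MotionConfig:
    """Study conditions of the synthetic snippets (defaults are canonical)."""

    n_frames: int = 250
    fps: float = 50.0
    template: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE)
    )
    base_freq_range: tuple[float, float] = (0.1, 1.0)   # Hz
    base_amp_range: tuple[float, float] = (20.0, 60.0)  # px, whole-body sway
    drift_amp_range: tuple[float, float] = (0.4, 1.2)   # px, per-keypoint
    fm_freq_range: tuple[float, float] = (2.0, 5.0)     # Hz
    fm_amp_range: tuple[float, float] = (5.0, 15.0)     # px
    fm_duty: float = 0.7          # fraction of frames carrying FM bursts
    jitter_sd: float = 2.0        # px
    dropout_rate: float = 0.02    # per keypoint-frame
    canvas: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.fm_freq_range[0] <= self.base_freq_range[1]:
            raise ValueError("fm_freq_range must lie above base_freq_range")
        for rng_ in (self.base_freq_range, self.base_amp_range,
                     self.drift_amp_range, self.fm_freq_range,
                     self.fm_amp_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("ranges must be positive and ordered")


@dataclass
class LabelPairConfig:
    """Conditions for generating paired rater tables at a target kappa."""

    n: int = 1000
    prevalence: float = 0.5
    target_kappa: float = 0.9
    na_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_kappa <= 1:
            raise ValueError("target_kappa must be in [0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.na_rate < 1:
            raise ValueError("na_rate must be in [0, 1)")


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    return float(rng.uniform(*lohi))


def gen_skeleton(label: str, cfg: MotionConfig | None = None,
                 seed: int | None = None) -> KeypointSequence:
    """One synthetic snippet of the given class ("FM+" or "FM-").

    Base motion is one sinusoidal whole-body sway per axis (amplitude
    and frequency drawn from the base ranges, shared by every keypoint)
    plus an independent per-keypoint slow drift from
    ``drift_amp_range``. Deterministic under (cfg, seed). Dropout
    zeroes (x, y, r) jointly, matching the missing-detection encoding
    of pose estimators.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    cfg = cfg or MotionConfig()
    rng = np.random.default_rng(seed)
    t = np.arange(cfg.n_frames) / cfg.fps
    data = np.zeros((cfg.n_frames, N_KEYPOINTS, 3))
    burst_keypoints = set(LIMB_END_INDICES)
    sway = {}
    for axis in (0, 1):
        amp = _uniform(rng, cfg.base_amp_range)
        freq = _uniform(rng, cfg.base_freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        sway[axis] = amp * np.sin(2 * np.pi * freq * t + phase)
    # fidgety movements form one continuous stream affecting all limbs
    # at once, so the bout envelope is shared across burst channels
    stream = _burst_mask(cfg, rng)
    for idx in range(1, N_KEYPOINTS + 1):
        x0, y0 = cfg.template[idx]
        for axis, base in ((0, x0), (1, y0)):
            freq = _uniform(rng, cfg.base_freq_range)
            amp = _uniform(rng, cfg.drift_amp_range)
            phase = rng.uniform(0, 2 * np.pi)
            traj = base + sway[axis] + amp * np.sin(2 * np.pi * freq * t + phase)
            if label == "FM+" and idx in burst_keypoints:
                f_fm = _uniform(rng, cfg.fm_freq_range)
                a_fm = _uniform(rng, cfg.fm_amp_range)
                ph_fm = rng.uniform(0, 2 * np.pi)
                traj = traj + stream * a_fm * np.sin(2 * np.pi * f_fm * t + ph_fm)
            traj = traj + rng.normal(0, cfg.jitter_sd, size=cfg.n_frames)
            data[:, idx - 1, axis] = traj
    data[:, :, 2] = rng.beta(8, 2, size=(cfg.n_frames, N_KEYPOINTS))
    dropped = rng.random((cfg.n_frames, N_KEYPOINTS)) < cfg.dropout_rate
    data[dropped] = 0.0
    return KeypointSequence(data=data, fps=cfg.fps,
                            snippet_id=f"syn_{label}_{seed}")


def _burst_mask(cfg: MotionConfig, rng: np.random.Generator) -> np.ndarray:
    """0/1 envelope covering ~fm_duty of the frames in contiguous bursts."""
    n = cfg.n_frames
    mask = np.zeros(n)
    target = int(round(cfg.fm_duty * n))
    burst_len = max(int(cfg.fps / cfg.fm_freq_range[0]), 5)  # >= one period
    covered = 0
    guard = 0
    while covered < target and guard < 200:
        start = int(rng.integers(0, n))
        stop = min(start + burst_len, n)
        covered += int((mask[start:stop] == 0).sum())
        mask[start:stop] = 1.0
        guard += 1
    return mask


def gen_dataset(
    n_pos: int, n_neg: int,
    cfg: MotionConfig | None = None,
    seed: int | None = None,
) -> tuple[list[KeypointSequence], np.ndarray]:
    """A labeled snippet collection (labels: 1 = FM+, 0 = FM-).

    Per-snippet seeds derive from the master seed; the interleaved
    class order is shuffled deterministically.
    """
    if n_pos + n_neg < 2:
        raise ValueError("need at least 2 snippets")
    cfg = cfg or MotionConfig()
    master = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * n_neg)
    master.shuffle(labels)
    seqs = [
        gen_skeleton("FM+" if lab else "FM-", cfg,
                     seed=int(master.integers(2**31)))
        for lab in labels
    ]
    return seqs, labels


def render_frames(
    seq: KeypointSequence,
    canvas: tuple[int, int] = (480, 270),
    scale: float | None = None,
    face_axes: tuple[int, int] = (40, 28),
    eye_radius: int = 3,
    background: int = 60,
    bone_value: int = 140,
    face_value: int = 200,
    eye_value: int = 30,
) -> list[np.ndarray]:
    """Render grayscale frames: skeleton bones, face blob, dark eye dots.

    ``canvas`` is (width, height); coordinates are rescaled from the
    sequence's native 1920x1080 layout by ``scale`` (default: fit the
    canvas). Eye dots are darker than the blob by construction
    (face_value - eye_value >= 80 at the defaults), giving the blur an
    identifiable structure to destroy.
    """
    from skimage.draw import disk, ellipse, line

    w, h = canvas
    if scale is None:
        scale = min(w / 1920.0, h / 1080.0)
    frames = []
    clipped = False
    eye_cols = [list(seq.indices).index(i) for i in (1, 2) if i in seq.indices]
    head_cols = [list(seq.indices).index(i) for i in HEAD_INDICES if i in seq.indices]
    for f in range(seq.n_frames):
        img = np.full((h, w), background, dtype=np.uint8)
        pts = seq.data[f, :, :2] * scale
        present = ~seq.missing_mask()[f]
        for a, b in SKELETON_EDGES:
            try:
                ca, cb = seq.indices.index(a), seq.indices.index(b)
            except ValueError:
                continue
            if not (present[ca] and present[cb]):
                continue
            r0, c0 = int(round(pts[ca, 1])), int(round(pts[ca, 0]))
            r1, c1 = int(round(pts[cb, 1])), int(round(pts[cb, 0]))
            rr, cc = line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            clipped |= not ok.all()
            img[rr[ok], cc[ok]] = bone_value
        if head_cols and present[head_cols].any():
            vis = [c for c in head_cols if present[c]]
            cy, cx = pts[vis, 1].mean(), pts[vis, 0].mean()
            rr, cc = ellipse(cy, cx, face_axes[1], face_axes[0], shape=img.shape)
            img[rr, cc] = face_value
            for c in eye_cols:
                if present[c]:
                    rr, cc = disk((pts[c, 1], pts[c, 0]), eye_radius,
                                  shape=img.shape)
                    img[rr, cc] = eye_value
        frames.append(img)
    if clipped:
        import warnings

        warnings.warn("some keypoints fell outside the canvas and were clipped")
    return frames


def _kappa_of_flip(eps: float, prevalence: float) -> float:
    """Analytic kappa of the symmetric flip model at error rate eps."""
    po = (1 - eps) ** 2 + eps ** 2
    m = prevalence * (1 - eps) + (1 - prevalence) * eps  # P(rater says FM+)
    pe = m ** 2 + (1 - m) ** 2
    if pe >= 1:
        return 1.0
    return (po - pe) / (1 - pe)


def flip_rate_for_kappa(target_kappa: float, prevalence: float) -> float:
    """Symmetric per-rater flip rate achieving a target kappa.

    Each rater independently flips the latent truth with probability
    eps; kappa(eps) is monotone decreasing on [0, 0.5], so the inverse
    is found by bisection. target_kappa=1 -> eps=0, 0 -> eps=0.5.
    """
    if target_kappa >= 1:
        return 0.0
    if target_kappa <= 0:
        return 0.5
    lo_k = _kappa_of_flip(0.5, prevalence)
    if target_kappa < lo_k:
        raise ValueError(
            f"target_kappa={target_kappa} infeasible at prevalence={prevalence}; "
            f"feasible range is [{lo_k:.3f}, 1]"
        )
    return float(brentq(
        lambda e: _kappa_of_flip(e, prevalence) - target_kappa, 1e-12, 0.5
    ))


def gen_rater_pair(cfg: LabelPairConfig) -> tuple[RatingTable, RatingTable]:
    """Two rating tables over the same snippets at a controlled kappa."""
    rng = np.random.default_rng(cfg.seed)
    eps = flip_rate_for_kappa(cfg.target_kappa, cfg.prevalence)
    truth = rng.random(cfg.n) < cfg.prevalence
    tables = []
    for rater in ("rater_a", "rater_b"):
        flips = rng.random(cfg.n) < eps
        nas = rng.random(cfg.n) < cfg.na_rate
        labels = {}
        for i in range(cfg.n):
            if nas[i]:
                labels[f"snip_{i:05d}"] = NA
            else:
                pos = truth[i] ^ flips[i]
                labels[f"snip_{i:05d}"] = "FM+" if pos else "FM-"
        tables.append(RatingTable(labels=labels, rater_id=rater, session="s1"))
    return tables[0], tables[1]


def tables_from_counts(
    n_pp: int, n_mm: int, n_pm: int, n_mp: int,
    n_na_either: int = 0,
    rater_ids: tuple[str, str] = ("rater_a", "rater_b"),
) -> tuple[RatingTable, RatingTable]:
    """Deterministic paired tables realizing exact contingency counts.

    ``n_pm`` counts snippets rated FM+ by the first rater and FM- by
    the second; ``n_na_either`` appends snippets labeled NA by both.
    Useful for reconstructing published agreement tables whose raw
    labels are unavailable.
    """
    la, lb = {}, {}
    blocks = (
        (n_pp, "FM+", "FM+"), (n_mm, "FM-", "FM-"),
        (n_pm, "FM+", "FM-"), (n_mp, "FM-", "FM+"),
        (n_na_either, NA, NA),
    )
    i = 0
    for count, a_lab, b_lab in blocks:
        for _ in range(count):
            sid = f"snip_{i:05d}"
            la[sid], lb[sid] = a_lab, b_lab
            i += 1
    return (
        RatingTable(labels=la, rater_id=rater_ids[0], session="s1"),
        RatingTable(labels=lb, rater_id=rater_ids[1], session="s1"),
    )
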