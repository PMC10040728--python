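"""Canonical 25-point infant skeleton model.

The canonical numbering is 1-based: keypoints 1-5 are the head set
(left eye, right eye, nose, left ear, right ear), 6-21 the body set used
for movement classification, and 22-25 the foot points (small toes and
heels) that are excluded everywhere because pose estimators localize
them poorly on supine infants.

The widely used BODY_25 pose-estimator layout is 0-based and ordered
differently; :data:`BODY25_TO_CANONICAL` maps it onto the canonical
order at read time so that all downstream formulas can be written
against the canonical indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical index -> human-readable name (1-based)
KEYPOINT_NAMES: dict[int, str] = {
    1: "left_eye",
    2: "right_eye",
    3: "nose",
    4: "left_ear",
    5: "right_ear",
    6: "neck",
    7: "right_shoulder",
    8: "right_elbow",
    9: "right_wrist",
    10: "left_shoulder",
    11: "left_elbow",
    12: "left_wrist",
    13: "mid_hip",
    14: "right_hip",
    15: "right_knee",
    16: "right_ankle",
    17: "left_hip",
    18: "left_knee",
    19: "left_ankle",
    20: "left_big_toe",
    21: "right_big_toe",
    22: "left_small_toe",
    23: "right_small_toe",
    24: "left_heel",
    25: "right_heel",
}

N_KEYPOINTS = 25

HEAD_INDICES: tuple[int, ...] = (1, 2, 3, 4, 5)
#: eyes + nose drive the vertical mask center and the reliability gate
EYES_NOSE_INDICES: tuple[int, ...] = (1, 2, 3)
#: foot points excluded from every analysis
EXCLUDED_INDICES: tuple[int, ...] = (22, 23, 24, 25)
#: wrists and ankles: where fidgety bursts live in the synthetic generator
LIMB_END_INDICES: tuple[int, ...] = (9, 12, 16, 19)

#: BODY_25 native 0-based slot -> canonical 1-based index.
#: Native order: Nose, Neck, RShoulder, RElbow, RWrist, LShoulder, LElbow,
#: LWrist, MidHip, RHip, RKnee, RAnkle, LHip, LKnee, LAnkle, REye, LEye,
#: REar, LEar, LBigToe, LSmallToe, LHeel, RBigToe, RSmallToe, RHeel.
BODY25_TO_CANONICAL: tuple[int, ...] = (
    3, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19,
    2, 1, 5, 4, 20, 22, 24, 21, 23, 25,
)


@dataclass(frozen=True)
class SkeletonSubset:
    """An ordered selection of canonical keypoint indices.

    ``with_head=True`` keeps keypoints 1-21 (21 keypoints: head + body);
    ``with_head=False`` keeps 6-21 (16 body keypoints). Toes/heels
    (22-25) are excluded in both conditions.
    """

    indices: tuple[int, ...]
    with_head: bool

    def __post_init__(self) -> None:
        if any(i < 1 or i > N_KEYPOINTS for i in self.indices):
            raise ValueError(f"keypoint indices must be in 1..{N_KEYPOINTS}")

    def __len__(self) -> int:
        return len(self.indices)


WITH_HEAD = SkeletonSubset(indices=tuple(range(1, 22)), with_head=True)
WITHOUT_HEAD = SkeletonSubset(indices=tuple(range(6, 22)), with_head=False)


def subset_for(with_head: bool) -> SkeletonSubset:
    return WITH_HEAD if with_head else WITHOUT_HEAD


@dataclass
class KeypointSequence:
    """Per-frame (x, y, reliability) for a skeleton over one snippet.

    ``data`` has shape ``(n_frames, n_keypoints, 3)`` with the last axis
    ordered (x, y, r). Coordinates are pixels, origin top-left, x
    rightward, y downward. A missing detection is encoded exactly as
    ``x == y == 0`` (r typically 0). ``indices`` records which canonical
    keypoints the second axis holds, so subset views stay addressable.
    """

    data: np.ndarray
    fps: float = 50.0
    snippet_id: str = ""
    indices: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 26)))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(
                f"data must have shape (n_frames, n_keypoints, 3), got {self.data.shape}"
            )
        if self.data.shape[1] != len(self.indices):
            raise ValueError(
                f"{self.data.shape[1]} keypoints per frame but {len(self.indices)} indices"
            )
        r = self.data[:, :, 2]
        if r.size and (r.min() < -1e-9 or r.max() > 1 + 1e-9):
            raise ValueError("reliability scores must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.data.shape[1]

    def keypoint(self, canonical_index: int) -> np.ndarray:
        """(n_frames, 3) view of one canonical keypoint."""
        try:
            col = self.indices.index(canonical_index)
        except ValueError:
            raise KeyError(f"keypoint {canonical_index} not in this sequence") from None
        return self.data[:, col, :]

    def missing_mask(self) -> np.ndarray:
        """(n_frames, n_keypoints) boolean: True where (x, y) == (0, 0)."""
        return (self.data[:, :, 0] == 0) & (self.data[:, :, 1] == 0)

    def copy(self) -> "KeypointSequence":
        return KeypointSequence(
            data=self.data.copy(), fps=self.fps,
            snippet_id=self.snippet_id, indices=self.indices,
        )


def select_subset(seq: KeypointSequence, subset: SkeletonSubset) -> KeypointSequence:
    """Restrict a sequence to a skeleton subset, preserving subset order.

    Idempotent: applying the same subset twice equals applying it once.
    """
    cols = [seq.indices.index(i) for i in subset.indices]
    return KeypointSequence(
        data=seq.data[:, cols, :].copy(),
        fps=seq.fps,
        snippet_id=seq.snippet_id,
        indices=subset.indices,
    )
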