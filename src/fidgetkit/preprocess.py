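"""Keypoint sequences -> classifier feature matrices.

Pose estimators emit (0, 0) for keypoints they cannot detect (e.g.
occlusions). Interior missing runs are filled by linear interpolation
between the flanking detected frames; leading/trailing runs have no
flanking value on one side and are left at the 0 sentinel, which the
subsequent min-max normalization then excludes so the sentinels cannot
act as outliers. Normalization is per snippet and per axis, pooled over
the selected keypoints, mapping coordinates into [0, 1] to remove the
influence of body size while preserving relative amplitudes between
limbs (a per-channel alternative is available as ``norm="per-channel"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import KeypointSequence, SkeletonSubset, select_subset, subset_for


class ShapeError(ValueError):
    """Feature-matrix shape does not match the configured snippet length."""


@dataclass
class FeatureMatrix:
    """frames x channels array of normalized coordinates in [0, 1].

    Channels are keypoint-major, x then y per keypoint, following the
    canonical subset order: 42 channels with head keypoints (21
    keypoints), 32 without (16). Residual 0 values are sentinels for
    never-observed boundary frames, not data.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]
    with_head: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def interpolate_missing(seq: KeypointSequence) -> KeypointSequence:
    """Fill interior missing frames of each keypoint by linear interpolation.

    Operates on raw pixel coordinates; missingness is (x, y) == (0, 0)
    exactly. Leading/trailing missing runs stay 0. Reliabilities are
    untouched.
    """
    out = seq.copy()
    missing = seq.missing_mask()
    n = seq.n_frames
    if n == 0:
        return out
    t = np.arange(n)
    for k in range(seq.n_keypoints):
        gaps = missing[:, k]
        if not gaps.any() or gaps.all():
            continue
        ok = ~gaps
        first, last = t[ok][0], t[ok][-1]
        interior = gaps & (t > first) & (t < last)
        if not interior.any():
            continue
        for axis in (0, 1):
            out.data[interior, k, axis] = np.interp(
                t[interior], t[ok], seq.data[ok, k, axis]
            )
    return out


def minmax_normalize(
    seq: KeypointSequence,
    subset: SkeletonSubset,
    norm: str = "pooled-axis",
) -> FeatureMatrix:
    """Min-max normalize subset coordinates into [0, 1] per snippet.

    min/max are taken per axis over all non-zero values of all subset
    keypoints (``norm="pooled-axis"``, the default) or per channel
    (``norm="per-channel"``). Zeros are sentinels for missing boundary
    frames: they neither enter the min/max nor get rescaled. A
    degenerate axis (max == min) maps to all 0 with a warning.
    """
    sub = select_subset(seq, subset)
    n_frames, n_kp = sub.n_frames, sub.n_keypoints
    values = np.zeros((n_frames, 2 * n_kp))
    coords = sub.data[:, :, :2]  # (frames, kp, 2)
    missing = sub.missing_mask()

    def _rescale(block: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.zeros_like(block)
        valid = ~mask & (block != 0)
        if not valid.any():
            return out
        lo, hi = block[valid].min(), block[valid].max()
        if hi == lo:
            warnings.warn("degenerate static axis: max == min, values set to 0")
            return out
        out[valid] = (block[valid] - lo) / (hi - lo)
        return out

    if norm == "pooled-axis":
        for axis in (0, 1):
            scaled = _rescale(coords[:, :, axis], missing)
            values[:, axis::2] = scaled
    elif norm == "per-channel":
        for k in range(n_kp):
            for axis in (0, 1):
                values[:, 2 * k + axis] = _rescale(
                    coords[:, k, axis][:, None], missing[:, k][:, None]
                )[:, 0]
    else:
        raise ValueError(f"unknown norm mode {norm!r}")

    names = []
    for idx in sub.indices:
        names += [f"kp{idx}_x", f"kp{idx}_y"]
    return FeatureMatrix(
        values=values, channel_names=tuple(names), with_head=subset.with_head
    )


def build_feature_matrix(
    seq: KeypointSequence,
    with_head: bool,
    n_frames: int = 250,
    norm: str = "pooled-axis",
) -> FeatureMatrix:
    """Interpolate, select the head condition's subset, and normalize.

    For the standard 5-s, 50-fps snippet (250 frames) the result is
    250x42 with head keypoints or 250x32 without.
    """
    if seq.n_frames != n_frames:
        raise ShapeError(
            f"expected a {n_frames}-frame snippet, got {seq.n_frames} frames"
        )
    filled = interpolate_missing(seq)
    return minmax_normalize(filled, subset_for(with_head), norm=norm)


class KeypointFeaturizer:
    """scikit-learn-style transformer: sequences -> stacked feature array.

    ``transform`` maps a list of :class:`KeypointSequence` to an array
    of shape (n_snippets, n_frames, n_channels) ready for the
    classifier. Stateless (each snippet is normalized within itself),
    so ``fit`` only validates and records channel metadata.
    """

    def __init__(self, with_head: bool = True, n_frames: int = 250,
                 norm: str = "pooled-axis"):
        self.with_head = with_head
        self.n_frames = n_frames
        self.norm = norm

    def get_params(self, deep: bool = True) -> dict:
        return {"with_head": self.with_head, "n_frames": self.n_frames,
                "norm": self.norm}

    def set_params(self, **params) -> "KeypointFeaturizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "KeypointFeaturizer":
        first = build_feature_matrix(X[0], self.with_head, self.n_frames, self.norm)
        self.channel_names_ = first.channel_names
        self.n_channels_ = len(first.channel_names)
        return self

    def transform(self, X) -> np.ndarray:
        mats = [
            build_feature_matrix(seq, self.with_head, self.n_frames, self.norm).values
            for seq in X
        ]
        return np.stack(mats)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
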