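"""Readers and writers for keypoint streams.

Two on-disk dialects are supported:

* the one-JSON-per-frame pose-estimator dialect: each file carries a
  ``"people"`` list whose entries hold ``"pose_keypoints_2d"``, a flat
  array of 75 floats (x1, y1, r1, ..., x25, y25, r25) in the native
  BODY_25 order;
* a flat CSV dialect with columns ``snippet_id, frame`` followed by
  ``x_i, y_i, r_i`` for canonical keypoints i = 1..25.

JSON frames are re-ordered into the canonical skeleton numbering at
read time (see :mod:`fidgetkit.skeleton`); the CSV dialect is already
canonical.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .skeleton import BODY25_TO_CANONICAL, N_KEYPOINTS, KeypointSequence


class PoseFormatError(ValueError):
    """Raised for malformed or schema-violating keypoint files."""


_FRAME_NUM = re.compile(r"(\d+)(?!.*\d)")


def _frame_number(path: Path) -> int:
    m = _FRAME_NUM.search(path.stem)
    if m is None:
        raise PoseFormatError(f"cannot find a frame number in filename {path.name!r}")
    return int(m.group(1))


def _person_to_canonical(flat: np.ndarray) -> np.ndarray:
    """(75,) native-order floats -> (25, 3) canonical-order array."""
    native = flat.reshape(N_KEYPOINTS, 3)
    out = np.empty_like(native)
    for native_slot, canon in enumerate(BODY25_TO_CANONICAL):
        out[canon - 1] = native[native_slot]
    return out


def read_openpose_dir(path: str | Path, fps: float = 50.0) -> KeypointSequence:
    """Read a directory of one-JSON-per-frame keypoint files.

    Frames are ordered by the trailing number in each filename. A frame
    with no detected people becomes an all-missing frame (all zeros);
    with several people, the one with the highest mean reliability is
    kept — the recordings have a single supine infant, so extra
    detections are spurious.
    """
    path = Path(path)
    files = sorted(path.glob("*.json"), key=_frame_number)
    if not files:
        raise PoseFormatError(f"no .json frame files in {path}")
    frames = np.zeros((len(files), N_KEYPOINTS, 3))
    for fi, f in enumerate(files):
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as e:
            raise PoseFormatError(f"malformed JSON in {f.name}: {e}") from e
        people = doc.get("people", [])
        best, best_score = None, -1.0
        for person in people:
            flat = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
            if flat.size != 3 * N_KEYPOINTS:
                raise PoseFormatError(
                    f"{f.name}: pose_keypoints_2d has {flat.size} values, expected {3 * N_KEYPOINTS}"
                )
            score = float(flat.reshape(-1, 3)[:, 2].mean())
            if score > best_score:
                best, best_score = flat, score
        if best is not None:
            frames[fi] = _person_to_canonical(best)
    return KeypointSequence(data=frames, fps=fps, snippet_id=path.name)


def _csv_columns() -> list[str]:
    cols = ["snippet_id", "frame"]
    for i in range(1, N_KEYPOINTS + 1):
        cols += [f"x_{i}", f"y_{i}", f"r_{i}"]
    return cols


def read_keypoint_csv(path: str | Path, fps: float = 50.0) -> KeypointSequence:
    """Read the flat CSV dialect into a sequence (frames sorted by number)."""
    df = pd.read_csv(path)
    expected = _csv_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise PoseFormatError(f"{path}: missing columns {missing[:6]}{'...' if len(missing) > 6 else ''}")
    df = df.sort_values("frame", kind="stable")
    coords = df[expected[2:]].to_numpy(dtype=float)
    data = coords.reshape(len(df), N_KEYPOINTS, 3)
    snippet_id = str(df["snippet_id"].iloc[0]) if len(df) else ""
    return KeypointSequence(data=data, fps=fps, snippet_id=snippet_id)


def write_keypoint_csv(seq: KeypointSequence, path: str | Path) -> None:
    """Write a full 25-keypoint sequence to the flat CSV dialect."""
    if seq.n_keypoints != N_KEYPOINTS:
        raise PoseFormatError(
            f"CSV dialect stores full 25-keypoint frames, got {seq.n_keypoints}"
        )
    flat = seq.data.reshape(seq.n_frames, 3 * N_KEYPOINTS)
    df = pd.DataFrame(flat, columns=_csv_columns()[2:])
    df.insert(0, "frame", np.arange(1, seq.n_frames + 1))
    df.insert(0, "snippet_id", seq.snippet_id)
    df.to_csv(path, index=False, float_format="%.6f")


def read_keypoints(path: str | Path, fps: float = 50.0) -> KeypointSequence:
    """Dispatch on path type: directory -> JSON dialect, file -> CSV."""
    p = Path(path)
    if p.is_dir():
        return read_openpose_dir(p, fps=fps)
    return read_keypoint_csv(p, fps=fps)
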