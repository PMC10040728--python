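import json

import numpy as np
import pytest

from fidgetkit import KeypointSequence
from fidgetkit.skeleton import N_KEYPOINTS


@pytest.fixture
def head_track_sequence():
    """3-frame sequence whose head keypoints produce raw x-centers [0, 10, 10]."""
    data = np.zeros((3, N_KEYPOINTS, 3))
    for f, xc in enumerate([0.0, 10.0, 10.0]):
        data[f, :5, 0] = xc
        data[f, :5, 1] = xc
        data[f, :5, 2] = 0.9
    return KeypointSequence(data=data)


@pytest.fixture
def random_sequence():
    """250-frame full-skeleton sequence with smooth random motion, no missing."""
    rng = np.random.default_rng(42)
    t = np.arange(250) / 50.0
    data = np.zeros((250, N_KEYPOINTS, 3))
    for k in range(N_KEYPOINTS):
        for axis in range(2):
            base = rng.uniform(100, 900)
            data[:, k, axis] = base + rng.uniform(5, 30) * np.sin(
                2 * np.pi * rng.uniform(0.2, 2.0) * t + rng.uniform(0, 6.28)
            )
    data[:, :, 2] = rng.uniform(0.3, 1.0, size=(250, N_KEYPOINTS))
    return KeypointSequence(data=data, snippet_id="fixture")


def write_openpose_frame(path, people_keypoints):
    """Write one pose-estimator JSON frame; each entry is a 75-float list."""
    doc = {"people": [{"pose_keypoints_2d": list(map(float, kp))}
                      for kp in people_keypoints]}
    path.write_text(json.dumps(doc))
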