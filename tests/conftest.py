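import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gibbonascr import (AscrData, CaptureHistory, DetectionParams, HabitatMask,
                        ListeningPost)

#: detection-function scale reported for this study system
FITTED_DETECTION = DetectionParams(lambda0=54.55, sigma=507.29)


@pytest.fixture
def three_posts():
    """One site, three collinear posts 500 m apart, three survey days."""
    days = frozenset({1, 2, 3})
    return [ListeningPost("A", i + 1, 500.0 * i, 0.0, days) for i in range(3)]


def random_micro_instance(rng):
    """Tiny random ASCR instance (<= 3 posts, <= 16 mask points,
    <= 4 histories) for likelihood oracle comparisons."""
    L = int(rng.integers(1, 4))
    M = int(rng.integers(2, 17))
    K = int(rng.integers(1, 5))
    posts = [ListeningPost("A", l + 1, float(rng.uniform(0, 1500)),
                           float(rng.uniform(0, 1500)), frozenset({1, 2}))
             for l in range(L)]
    mask = HabitatMask(
        rng.uniform(-500, 2000, M), rng.uniform(-500, 2000, M), 0.04,
        {"cv": rng.normal(0, 1, M),
         "forest_class": rng.choice(
             ["F1_evergreen", "F2_semi_evergreen", "F3_other"], M)})
    hists = []
    for k in range(K):
        omega = np.zeros(L, int)
        omega[rng.integers(0, L)] = 1
        omega = np.maximum(omega, (rng.uniform(0, 1, L) < 0.4).astype(int))
        bearings = {posts[i].post_index: float(rng.uniform(0, 360))
                    for i in np.flatnonzero(omega)}
        hists.append(CaptureHistory("A", int(rng.integers(1, 3)), f"G{k}",
                                    tuple(p.post_index for p in posts),
                                    omega, bearings))
    return AscrData(hists, {"A": posts}, {"A": mask})
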