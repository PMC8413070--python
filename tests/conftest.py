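import numpy as np
import pytest

import facebeauty as fb


@pytest.fixture(scope="session")
def template():
    return fb.make_landmark_template()


@pytest.fixture(scope="session")
def fusion_tables_500():
    """The standard fusion study cohort: 500 faces, rater noise sd 0.2."""
    ds = fb.make_dataset(500, "fusion", noise_sd=0.2, seed=1)
    return fb.extract_features(ds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_landmarks(rng, n_sets=1, low=10.0, high=340.0):
    """Generic random landmark sets (no degeneracy in practice)."""
    sets = []
    for _ in range(n_sets):
        pts = rng.uniform(low, high, size=(86, 2))
        sets.append(fb.LandmarkSet.from_array(pts))
    return sets if n_sets > 1 else sets[0]


def mirrored_landmarks(rng, sd=4.0):
    """A random bilaterally mirror-symmetric landmark set.

    Starts from the symmetric template and perturbs each mirror pair by a
    shared reflected jitter (midline points move only vertically), so the
    result stays exactly mirror-symmetric about x = 175.

    One anatomical regularity of the schema is restored after jittering:
    the upper-brow ratio compares d(23, M) with d(35, M) about the
    inter-brow centre M = mid(23, 37), so landmark 35 (and its mirror 25)
    is re-projected onto the circle of radius d(23, M) around M — the
    configuration in which a symmetric face scores 1 on that ratio.
    """
    from facebeauty.synthetic import MIDLINE, MIRROR_PAIRS

    pts = fb.make_landmark_template().as_array()
    for left, right in MIRROR_PAIRS:
        d = rng.normal(0.0, sd, size=2)
        pts[left - 1] += d
        pts[right - 1] += np.array([-d[0], d[1]])
    for idx in MIDLINE:
        pts[idx - 1][1] += rng.normal(0.0, sd)
    m = (pts[22] + pts[36]) / 2.0  # mid(23, 37); on the midline
    radius = np.linalg.norm(pts[22] - m)
    pts[34] = m + (pts[34] - m) * (radius / np.linalg.norm(pts[34] - m))
    pts[24] = np.array([350.0 - pts[34][0], pts[34][1]])
    return fb.LandmarkSet.from_array(pts)
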