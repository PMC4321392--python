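import numpy as np
import pytest
from scipy.spatial.distance import cdist

from assemblyscope.synth import SceneConfig, generate_cell_scene


@pytest.fixture(scope="session")
def default_scene():
    """Noiseless 20-neuron/10-glia poisson scene with ground truth."""
    return generate_cell_scene(SceneConfig(seed=7))


def match_detections(records, truth_centroids, max_dist=5.0):
    """Greedy one-to-one matching of detections to ground-truth centroids.

    Returns (pairs, n_unmatched_detections, n_missed_truth); pairs are
    (record_index, truth_index) with centroid distance <= max_dist.
    """
    if not records or len(truth_centroids) == 0:
        return [], len(records), len(truth_centroids)
    d = cdist([r.centroid for r in records], truth_centroids)
    pairs = []
    used_r, used_t = set(), set()
    for flat in np.argsort(d, axis=None):
        i, j = np.unravel_index(flat, d.shape)
        if i in used_r or j in used_t or d[i, j] > max_dist:
            continue
        pairs.append((int(i), int(j)))
        used_r.add(i)
        used_t.add(j)
    return pairs, len(records) - len(used_r), len(truth_centroids) - len(used_t)
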