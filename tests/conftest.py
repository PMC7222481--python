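import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardioseg.pipeline import segment_pair
from cardioseg.preprocess import preprocess_pair
from cardioseg.synthetic import SceneParams, generate_scene

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_scene():
    """One default spread-regime scene shared by read-only tests."""
    return generate_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def preprocessed_scene(default_scene):
    pair, _truth = default_scene
    return preprocess_pair(pair)


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    pair, _truth = default_scene
    seeds, cells, log = segment_pair(pair)
    return seeds, cells, log


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def best_iou_fraction(pred_labels, truth, min_iou=0.6):
    """Fraction of planted cells recovered at IoU >= min_iou by some predicted cell."""
    gt = truth.cell_labels.pixels
    pred = pred_labels.pixels
    n = truth.cell_labels.n_objects
    hit = 0
    for gid in range(1, n + 1):
        g = gt == gid
        ids, counts = np.unique(pred[g][pred[g] > 0], return_counts=True)
        best = 0.0
        for i, c in zip(ids, counts):
            best = max(best, c / (g.sum() + (pred == i).sum() - c))
        hit += best >= min_iou
    return hit / n if n else 1.0
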