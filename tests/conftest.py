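import colorsys
import math

import numpy as np
import pytest

from fibroquant.classifier import ClassifierModel, SubCluster, TissueClass
from fibroquant.colorspace import HSVColor


@pytest.fixture
def rng():
    return np.random.default_rng(20230316)


@pytest.fixture
def basic_model():
    """One sub-cluster per class: white background, red healthy, blue fibrotic."""
    return ClassifierModel(
        subclusters=(
            SubCluster(TissueClass.BACKGROUND, HSVColor(0.0, 0.0, 1.0)),
            SubCluster(TissueClass.HEALTHY, HSVColor(0.0, 1.0, 1.0)),
            SubCluster(TissueClass.FIBROTIC, HSVColor(240.0, 1.0, 1.0)),
        )
    )


def brute_force_nearest_center(image, model):
    """Independent per-pixel nearest-center classifier (pure-Python oracle).

    Loops over pixels, converts each through colorsys, and evaluates the
    circular-hue weighted metric against every sub-cluster with scalar math.
    """
    h, w = image.shape[:2]
    out = np.zeros((h, w), dtype=np.uint8)
    centers = [(sc.center, int(sc.parent)) for sc in model.subclusters]
    wh, ws, wv = model.weights
    for r in range(h):
        for c in range(w):
            ph, ps, pv = colorsys.rgb_to_hsv(*(image[r, c] / 255.0))
            if ps == 0.0:
                ph = 0.0
            best, best_d = None, None
            for center, parent in centers:
                dh = abs(ph - center.hue / 360.0)
                dh = min(dh, 1.0 - dh)
                d = math.sqrt(
                    wh * dh**2
                    + ws * (ps - center.saturation) ** 2
                    + wv * (pv - center.value) ** 2
                )
                if best_d is None or d < best_d:  # strict <: first wins ties
                    best, best_d = parent, d
            out[r, c] = best
    return out
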