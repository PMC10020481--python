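"""HSV color representation and the pixel-color metric used by the classifier.

Stained brightfield tissue separates far better by hue (the stain color) and
value (background is bright, tissue darker) than by raw RGB intensities, so
all classification happens in HSV. Hue is an angle: its distance is circular,
otherwise near-red colors on either side of 0°/360° would look maximally far
apart.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv as _rgb2hsv

__all__ = [
    "HSVColor",
    "rgb_to_hsv",
    "color_distance",
    "image_to_hsv_features",
    "distances_to_centers",
    "DEFAULT_WEIGHTS",
]

#: Default channel weights (hue, saturation, value) of the color metric.
#: Background/tissue separation leans on value, tissue/tissue separation on
#: hue; equal weights are the neutral starting point and are configurable
#: everywhere a model is built.
DEFAULT_WEIGHTS: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class HSVColor:
    """A pixel color in HSV space: the classifier's feature vector.

    ``hue`` is in degrees in [0, 360); ``saturation`` and ``value`` are
    unitless in [0, 1]. Achromatic colors (saturation 0) are canonicalized
    to hue 0 so that distances involving white/gray backgrounds are well
    defined.
    """

    hue: float
    saturation: float
    value: float

    def __post_init__(self) -> None:
        for name in ("hue", "saturation", "value"):
            x = getattr(self, name)
            if not math.isfinite(x):
                raise ValueError(f"{name} must be finite, got {x!r}")
        if not 0.0 <= self.hue < 360.0:
            raise ValueError(f"hue must lie in [0, 360), got {self.hue!r}")
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError(f"saturation must lie in [0, 1], got {self.saturation!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"value must lie in [0, 1], got {self.value!r}")
        if self.saturation == 0.0 and self.hue != 0.0:
            object.__setattr__(self, "hue", 0.0)  # canonical achromatic form

    def normalized(self) -> tuple[float, float, float]:
        """Feature triple with hue rescaled to [0, 1)."""
        return (self.hue / 360.0, self.saturation, self.value)


def rgb_to_hsv(r: float, g: float, b: float) -> HSVColor:
    """Convert one 8-bit RGB triple to :class:`HSVColor`.

    Standard hexcone conversion. Channels must lie in [0, 255]; achromatic
    inputs come out with hue 0 and saturation 0.
    """
    for name, c in (("r", r), ("g", g), ("b", b)):
        if not (isinstance(c, (int, float, np.integer, np.floating)) and 0 <= c <= 255):
            raise ValueError(f"channel {name} out of range [0, 255]: {c!r}")
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return HSVColor(h * 360.0 % 360.0, s, v)


def _check_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError(f"weights must be 3 reals, got shape {w.shape}")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    return w


def color_distance(
    a: HSVColor, b: HSVColor, weights: Sequence[float] = DEFAULT_WEIGHTS
) -> float:
    """Weighted Euclidean distance between two colors with circular hue.

    Hue is rescaled to [0, 1) and its difference taken around the circle:
    ``min(|dh|, 1 - |dh|)``. The result is symmetric, satisfies the triangle
    inequality for any fixed non-negative weights, and is zero iff the two
    colors agree channel-wise in canonical achromatic form.
    """
    w = _check_weights(weights)
    dh = abs(a.hue - b.hue) / 360.0
    dh = min(dh, 1.0 - dh)
    ds = a.saturation - b.saturation
    dv = a.value - b.value
    return math.sqrt(w[0] * dh * dh + w[1] * ds * ds + w[2] * dv * dv)


def image_to_hsv_features(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to an (H, W, 3) float array of HSV features.

    Channel 0 is hue normalized to [0, 1), channels 1-2 saturation and value
    in [0, 1]. Achromatic pixels get hue 0 (same canonical form as
    :class:`HSVColor`).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    feats = _rgb2hsv(arr)
    # enforce canonical achromatic hue regardless of library internals
    feats[..., 0] = np.where(feats[..., 1] == 0.0, 0.0, feats[..., 0])
    return feats


def distances_to_centers(
    features: np.ndarray,
    centers: np.ndarray,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> np.ndarray:
    """Squared metric from each feature row to each center.

    ``features`` is (N, 3) normalized HSV, ``centers`` is (K, 3) normalized
    HSV; returns (N, K) squared distances under the circular-hue weighted
    metric. Squared distances preserve the argmin, which is all the
    classifier needs.
    """
    w = _check_weights(weights)
    f = np.asarray(features, dtype=float)
    c = np.asarray(centers, dtype=float)
    dh = np.abs(f[:, None, 0] - c[None, :, 0])
    dh = np.minimum(dh, 1.0 - dh)
    ds = f[:, None, 1] - c[None, :, 1]
    dv = f[:, None, 2] - c[None, :, 2]
    return w[0] * dh * dh + w[1] * ds * ds + w[2] * dv * dv
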