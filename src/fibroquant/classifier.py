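"""Single-step supervised k-means with sub-classes.

The core algorithm: every user-selected sample color becomes a fixed
sub-cluster center; each pixel is assigned to its nearest sub-cluster in one
pass (no center recomputation), and all sub-clusters of a tissue class are
then unioned into that class. Keeping each sample as its own center, rather
than averaging samples per class, lets a class cover several distinct color
modes (pale and saturated collagen, say) without the centers drifting the
way iterative k-means centers do.

A conventional iterative (Lloyd) k-means baseline is included for
comparison; its centers move with the data, so on images where stain color
ranges overlap it can settle on partitions that mix tissue types.
"""

from __future__ import annotations

import csv
import hashlib
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .colorspace import (
    DEFAULT_WEIGHTS,
    HSVColor,
    distances_to_centers,
    image_to_hsv_features,
    rgb_to_hsv,
)

__all__ = [
    "TissueClass",
    "SubCluster",
    "ClassifierModel",
    "build_model_from_points",
    "subcluster_from_point",
    "classify_pixel",
    "segment_image",
    "standard_kmeans",
    "load_preset",
    "preset_palette",
    "model_from_palette",
    "model_from_colors_file",
    "PRESET_PALETTES",
]


class TissueClass(IntEnum):
    """The three tissue classes of the quantification workflow.

    Codes are fixed: background 0, healthy 1, fibrotic 2. Label masks and
    mask files use these integer codes everywhere.
    """

    BACKGROUND = 0
    HEALTHY = 1
    FIBROTIC = 2

    @classmethod
    def from_name(cls, name: "str | int | TissueClass") -> "TissueClass":
        if isinstance(name, TissueClass):
            return name
        if isinstance(name, (int, np.integer)):
            return cls(int(name))
        try:
            return cls[str(name).strip().upper()]
        except KeyError:
            valid = ", ".join(m.name.lower() for m in cls)
            raise ValueError(f"unknown tissue class {name!r}; expected one of: {valid}")


@dataclass(frozen=True)
class SubCluster:
    """One fixed cluster center with its parent tissue class.

    ``origin`` is free-text provenance: an image id plus pixel coordinate,
    a preset name, or "manual".
    """

    parent: TissueClass
    center: HSVColor
    origin: str = "manual"


@dataclass(frozen=True)
class ClassifierModel:
    """The entire trained state: an ordered list of sub-clusters plus metric weights.

    Insertion order matters — at exact distance ties the earliest sub-cluster
    wins, which makes segmentation deterministic. ``classes`` lists the class
    codes the model must cover (each needs at least one sub-cluster before
    segmentation); the default is the standard three-class set, but any set
    of two or more labels is accepted by the classifier core.
    """

    subclusters: tuple[SubCluster, ...]
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    classes: tuple[int, ...] = (
        TissueClass.BACKGROUND,
        TissueClass.HEALTHY,
        TissueClass.FIBROTIC,
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "subclusters", tuple(self.subclusters))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "classes", tuple(int(c) for c in self.classes))
        if len(self.classes) < 2:
            raise ValueError("a classifier needs at least two classes")

    def validate(self) -> None:
        """Check the pre-segmentation invariant: every class has >= 1 sub-cluster."""
        present = {int(sc.parent) for sc in self.subclusters}
        missing = [c for c in self.classes if c not in present]
        if missing:
            names = ", ".join(
                TissueClass(c).name.lower() if c in set(TissueClass) else str(c)
                for c in missing
            )
            raise ValueError(f"no sub-cluster for class(es): {names}")

    def centers_array(self) -> np.ndarray:
        """(K, 3) normalized-HSV sub-cluster centers in insertion order."""
        return np.array([sc.center.normalized() for sc in self.subclusters], dtype=float)

    def parents_array(self) -> np.ndarray:
        """(K,) parent class code of each sub-cluster."""
        return np.array([int(sc.parent) for sc in self.subclusters], dtype=np.int64)

    def add_subcluster(self, sub: SubCluster) -> "ClassifierModel":
        """Return a new model with ``sub`` appended (insertion order preserved)."""
        return replace(self, subclusters=self.subclusters + (sub,))

    def fingerprint(self) -> str:
        """Short stable digest of the trained state, for result traceability."""
        h = hashlib.sha256()
        h.update(repr(self.weights).encode())
        h.update(repr(self.classes).encode())
        for sc in self.subclusters:
            h.update(
                f"{int(sc.parent)}:{sc.center.hue!r}:{sc.center.saturation!r}:{sc.center.value!r}".encode()
            )
        return h.hexdigest()[:16]


def _check_rgb_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


def subcluster_from_point(
    image: np.ndarray,
    row: int,
    col: int,
    label: "TissueClass | str | int",
    *,
    patch: int = 1,
    image_id: str = "image",
) -> SubCluster:
    """One sub-cluster from one sample point on a reference image.

    The center is the HSV color of the pixel at ``(row, col)``; with
    ``patch`` set to an odd size > 1 it is the per-channel RGB median of the
    surrounding patch (clipped at the image border), which damps
    single-pixel noise.
    """
    arr = _check_rgb_image(image)
    if patch < 1 or patch % 2 == 0:
        raise ValueError(f"patch must be an odd positive size, got {patch}")
    rows, cols = arr.shape[:2]
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(
            f"sample point ({row}, {col}) outside image of shape {rows}x{cols}"
        )
    cls = TissueClass.from_name(label)
    if patch == 1:
        rgb = arr[row, col]
    else:
        half = patch // 2
        block = arr[
            max(0, row - half) : row + half + 1, max(0, col - half) : col + half + 1
        ]
        rgb = np.median(block.reshape(-1, 3), axis=0)
    center = rgb_to_hsv(float(rgb[0]), float(rgb[1]), float(rgb[2]))
    return SubCluster(parent=cls, center=center, origin=f"{image_id}@({row},{col})")


def build_model_from_points(
    image: np.ndarray,
    points: Iterable[tuple[int, int, "TissueClass | str | int"]],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    *,
    patch: int = 1,
    image_id: str = "image",
) -> ClassifierModel:
    """Build a model from sample points picked on a reference image.

    Each point ``(row, col, class)`` becomes one sub-cluster whose center is
    the HSV color of that pixel, in input order; every class needs at least
    one point. See :func:`subcluster_from_point` for the ``patch`` option.
    """
    subclusters: list[SubCluster] = []
    for idx, (r, c, label) in enumerate(points):
        try:
            subclusters.append(
                subcluster_from_point(
                    image, r, c, label, patch=patch, image_id=image_id
                )
            )
        except ValueError as exc:
            raise ValueError(f"sample point #{idx}: {exc}") from None
    model = ClassifierModel(subclusters=tuple(subclusters), weights=tuple(weights))
    model.validate()
    # identical colors under different classes are legal but resolved by
    # insertion-order tie-breaking; warn so the user knows the selection is
    # degenerate
    seen: dict[tuple[float, float, float], TissueClass] = {}
    for sc in model.subclusters:
        key = sc.center.normalized()
        if key in seen and seen[key] != sc.parent:
            warnings.warn(
                f"identical sample color assigned to both {seen[key].name.lower()} "
                f"and {sc.parent.name.lower()}; tie-breaking by insertion order",
                stacklevel=2,
            )
        seen.setdefault(key, sc.parent)
    return model


def classify_pixel(model: ClassifierModel, color: HSVColor) -> TissueClass:
    """Assign one color to the parent class of its nearest sub-cluster.

    Exact distance ties go to the earliest sub-cluster in insertion order.
    """
    model.validate()
    feats = np.array([color.normalized()], dtype=float)
    d2 = distances_to_centers(feats, model.centers_array(), model.weights)
    best = int(np.argmin(d2[0]))  # argmin returns the first minimum: tie-break
    return TissueClass(int(model.parents_array()[best]))


def segment_image(model: ClassifierModel, image: np.ndarray) -> np.ndarray:
    """Segment an RGB image into a label mask in a single assignment pass.

    Every pixel goes to the parent class of its nearest sub-cluster; centers
    are never recomputed, so the result depends only on the model and each
    pixel's own color. Returns a (H, W) uint8 mask of class codes.
    """
    model.validate()
    arr = _check_rgb_image(image)
    feats = image_to_hsv_features(arr).reshape(-1, 3)
    d2 = distances_to_centers(feats, model.centers_array(), model.weights)
    nearest = np.argmin(d2, axis=1)
    labels = model.parents_array()[nearest].astype(np.uint8)
    return labels.reshape(arr.shape[:2])


def standard_kmeans(
    image: np.ndarray,
    k: int,
    max_iters: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Conventional iterative k-means over the image's HSV features.

    Lloyd iterations from a seeded k-means++ start, until the center shift
    drops below ``tol`` or ``max_iters`` is reached. Returns ``(labels,
    centers)`` where ``labels`` is a (H, W) array of cluster indices (NOT
    tissue classes — the clusters are unsupervised) and ``centers`` the final
    (k, 3) normalized-HSV centers. This is the baseline whose moving centers
    the supervised single-pass method is designed to avoid.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    arr = _check_rgb_image(image)
    n_distinct = np.unique(arr.reshape(-1, 3), axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"image has {n_distinct} distinct colors, fewer than k={k}")
    feats = image_to_hsv_features(arr).reshape(-1, 3)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iters,
        tol=tol,
        random_state=int(seed),
        algorithm="lloyd",
    ).fit(feats)
    return km.labels_.reshape(arr.shape[:2]), km.cluster_centers_


# ---------------------------------------------------------------------------
# Staining presets
# ---------------------------------------------------------------------------

#: Default per-class RGB sample colors per staining protocol. Masson's
#: Trichrome colors collagen/ECM blue and muscle red; Picosirius Red colors
#: collagen red against yellow cytoplasm; both are imaged over a near-white
#: brightfield background. Two sub-clusters per class cover a lighter and a
#: darker variant of each stain. Users with differently calibrated stains
#: should sample their own reference image instead.
PRESET_PALETTES: dict[str, dict[TissueClass, list[tuple[int, int, int]]]] = {
    "masson": {
        TissueClass.BACKGROUND: [(245, 245, 245), (231, 233, 236)],
        TissueClass.HEALTHY: [(190, 60, 80), (210, 90, 110)],
        TissueClass.FIBROTIC: [(70, 90, 180), (100, 130, 200)],
    },
    "picosirius": {
        TissueClass.BACKGROUND: [(250, 250, 250), (238, 240, 242)],
        TissueClass.HEALTHY: [(230, 200, 90), (235, 210, 120)],
        TissueClass.FIBROTIC: [(200, 40, 50), (180, 50, 60)],
    },
}


def preset_palette(staining: str) -> dict[TissueClass, list[tuple[int, int, int]]]:
    """The shipped per-class RGB palette for a staining protocol."""
    key = staining.strip().lower()
    if key not in PRESET_PALETTES:
        avail = ", ".join(sorted(PRESET_PALETTES))
        raise ValueError(f"unknown staining preset {staining!r}; available: {avail}")
    return {cls: list(colors) for cls, colors in PRESET_PALETTES[key].items()}


def model_from_palette(
    palette: dict[TissueClass, Sequence[tuple[int, int, int]]],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    origin: str = "palette",
) -> ClassifierModel:
    """Build a model whose sub-cluster centers are exactly the palette colors."""
    subclusters = [
        SubCluster(
            parent=TissueClass.from_name(cls),
            center=rgb_to_hsv(*map(float, rgb)),
            origin=origin,
        )
        for cls in sorted(palette, key=int)
        for rgb in palette[cls]
    ]
    model = ClassifierModel(subclusters=tuple(subclusters), weights=tuple(weights))
    model.validate()
    return model


def load_preset(
    staining: str, weights: Sequence[float] = DEFAULT_WEIGHTS
) -> ClassifierModel:
    """Model built from the shipped default center colors for a staining."""
    return model_from_palette(
        preset_palette(staining), weights=weights, origin=f"preset:{staining.lower()}"
    )


def model_from_colors_file(
    path: "str | Path", weights: Sequence[float] = DEFAULT_WEIGHTS
) -> ClassifierModel:
    """Build a model from a colors CSV giving one center color per row.

    Header must be either ``class,r,g,b`` (8-bit channels) or ``class,h,s,v``
    (degrees / unit saturation / unit value). Row order is sub-cluster
    insertion order.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty colors file")
        names = [n.strip().lower() for n in reader.fieldnames]
        subclusters: list[SubCluster] = []
        if {"class", "r", "g", "b"} <= set(names):
            for row in reader:
                row = {k.strip().lower(): v for k, v in row.items()}
                center = rgb_to_hsv(float(row["r"]), float(row["g"]), float(row["b"]))
                subclusters.append(
                    SubCluster(TissueClass.from_name(row["class"]), center, str(path))
                )
        elif {"class", "h", "s", "v"} <= set(names):
            for row in reader:
                row = {k.strip().lower(): v for k, v in row.items()}
                center = HSVColor(float(row["h"]), float(row["s"]), float(row["v"]))
                subclusters.append(
                    SubCluster(TissueClass.from_name(row["class"]), center, str(path))
                )
        else:
            raise ValueError(
                f"{path}: colors file header must contain class,r,g,b or class,h,s,v"
            )
    model = ClassifierModel(subclusters=tuple(subclusters), weights=tuple(weights))
    model.validate()
    return model
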