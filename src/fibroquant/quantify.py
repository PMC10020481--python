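"""Area statistics, the fibrosis-to-cell ratio, and segmentation accuracy metrics.

The quantity of interest is the fraction of the *cell* (tissue with
background removed, i.e. healthy + fibrotic pixels) occupied by fibrosis:

    fibrosis % = 100 * fibrotic / (fibrotic + healthy)

Background never enters the denominator — that is precisely why background
must be a class of its own in the segmentation. Accuracy against a
ground-truth mask is reported per class as defined (truth) and analyzed
(predicted) pixel counts plus the Dice coefficient 2|A∩B| / (|A| + |B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .classifier import TissueClass

__all__ = [
    "ClassCounts",
    "QuantRecord",
    "EvaluationResult",
    "ClassEvaluation",
    "count_labels",
    "fibrosis_ratio",
    "dice",
    "evaluate_against_reference",
    "match_clusters_to_classes",
]


@dataclass(frozen=True)
class ClassCounts:
    """Per-class pixel tallies of one mask."""

    background_px: int
    healthy_px: int
    fibrotic_px: int

    def __post_init__(self) -> None:
        for name in ("background_px", "healthy_px", "fibrotic_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_px(self) -> int:
        return self.background_px + self.healthy_px + self.fibrotic_px

    @property
    def cell_px(self) -> int:
        """Reference (cell) area: everything that is not background."""
        return self.healthy_px + self.fibrotic_px


@dataclass(frozen=True)
class QuantRecord:
    """One CSV row: per-image counts plus the fibrosis percentage."""

    image_id: str
    counts: ClassCounts
    cell_px: int
    fibrosis_percent: float

    @classmethod
    def from_mask(cls, image_id: str, mask: np.ndarray) -> "QuantRecord":
        counts = count_labels(mask)
        return cls(
            image_id=image_id,
            counts=counts,
            cell_px=counts.cell_px,
            fibrosis_percent=fibrosis_ratio(counts),
        )


def _check_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D label mask, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty mask")
    return arr


def count_labels(mask: np.ndarray) -> ClassCounts:
    """Exact per-class pixel tally of a label mask."""
    arr = _check_mask(mask)
    if arr.min() < 0 or arr.max() > 2:
        raise ValueError("mask contains codes outside the three-class set {0, 1, 2}")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=3)
    return ClassCounts(int(counts[0]), int(counts[1]), int(counts[2]))


def fibrosis_ratio(counts: ClassCounts) -> float:
    """Fibrotic area as a percentage of the cell (healthy + fibrotic) area.

    Raises on an empty cell area rather than returning 0 or NaN: a mask with
    no tissue has no meaningful fibrosis fraction.
    """
    if counts.cell_px <= 0:
        raise ValueError("cell area (healthy + fibrotic) is empty; ratio undefined")
    return 100.0 * counts.fibrotic_px / counts.cell_px


def dice(mask_a: np.ndarray, mask_b: np.ndarray, tissue: TissueClass) -> float:
    """Dice coefficient of one class between two masks.

    ``2|A∩B| / (|A| + |B|)`` over the pixel sets labeled ``tissue``. When the
    class is absent from both masks the score is 1.0 (perfect-agreement
    convention for empty sets).
    """
    a = _check_mask(mask_a)
    b = _check_mask(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    code = int(tissue)
    in_a = a == code
    in_b = b == code
    denom = int(in_a.sum()) + int(in_b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((in_a & in_b).sum()) / denom


@dataclass(frozen=True)
class ClassEvaluation:
    """Defined (truth) vs analyzed (predicted) area of one class plus Dice."""

    defined_px: int
    analyzed_px: int
    dice: float


@dataclass(frozen=True)
class EvaluationResult:
    """Per-class accuracy of a predicted mask against a reference mask."""

    per_class: dict[TissueClass, ClassEvaluation]

    @property
    def defined_counts(self) -> ClassCounts:
        return ClassCounts(*(self.per_class[c].defined_px for c in TissueClass))

    @property
    def analyzed_counts(self) -> ClassCounts:
        return ClassCounts(*(self.per_class[c].analyzed_px for c in TissueClass))


def evaluate_against_reference(
    predicted: np.ndarray, truth: np.ndarray
) -> EvaluationResult:
    """Score a segmentation against a ground-truth mask, class by class."""
    p = _check_mask(predicted)
    t = _check_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    per_class = {
        cls: ClassEvaluation(
            defined_px=int((t == int(cls)).sum()),
            analyzed_px=int((p == int(cls)).sum()),
            dice=dice(p, t, cls),
        )
        for cls in TissueClass
    }
    return EvaluationResult(per_class=per_class)


def match_clusters_to_classes(
    cluster_labels: np.ndarray, truth: np.ndarray, n_classes: int = 3
) -> np.ndarray:
    """Post-hoc best matching of unsupervised cluster indices to class codes.

    Used to score the iterative k-means baseline as generously as possible:
    clusters are assigned to classes by maximizing total pixel agreement
    (Hungarian algorithm on the contingency table). Returns the remapped
    mask; clusters beyond ``n_classes`` (if any) keep no class and are mapped
    to the class they overlap most.
    """
    labels = _check_mask(cluster_labels)
    t = _check_mask(truth)
    if labels.shape != t.shape:
        raise ValueError(f"mask shapes differ: {labels.shape} vs {t.shape}")
    k = int(labels.max()) + 1
    contingency = np.zeros((k, n_classes), dtype=np.int64)
    for ci in range(k):
        sel = labels == ci
        contingency[ci] = np.bincount(t[sel].astype(np.int64), minlength=n_classes)[
            :n_classes
        ]
    rows, cols = linear_sum_assignment(contingency, maximize=True)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    for ci in range(k):  # unmatched clusters: majority class
        if ci not in mapping:
            mapping[ci] = int(np.argmax(contingency[ci]))
    lut = np.array([mapping[ci] for ci in range(k)], dtype=np.uint8)
    return lut[labels]
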