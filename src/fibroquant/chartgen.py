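"""Synthetic reference charts with exactly known per-class areas.

A reference chart is an image of rectangular per-class sample regions whose
ground-truth areas follow from the rectangle geometry, so segmentation
accuracy can be scored without any manual annotation. Region pixels are
drawn uniformly from a per-class color palette and optionally degraded with
i.i.d. Gaussian RGB noise (sensor-style noise, applied before any HSV
conversion). Only color-class structure is modeled — tissue morphology is
irrelevant to a purely per-pixel classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .classifier import TissueClass, preset_palette

__all__ = [
    "Rect",
    "ChartSpec",
    "generate_chart",
    "default_table3_spec",
    "multimodal_demo_spec",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: Defined per-class areas (background, healthy, fibrotic) of the standard
#: accuracy-benchmark chart, in px².
BENCHMARK_AREAS = (21336, 107188, 21336)


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


@dataclass(frozen=True)
class ChartSpec:
    """Full recipe for one synthetic chart.

    ``regions`` pairs rectangles with tissue classes; pixels outside every
    rectangle are background. ``palette`` maps each class to its candidate
    RGB colors; ``noise_sigma`` is the per-channel Gaussian standard
    deviation in 8-bit units.
    """

    canvas: tuple[int, int]
    regions: tuple[tuple[Rect, TissueClass], ...]
    palette: dict[TissueClass, list[tuple[int, int, int]]]
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.canvas
        if rows <= 0 or cols <= 0:
            raise ValueError(f"invalid canvas {self.canvas}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        rects = [r for r, _ in self.regions]
        for i, (rect, cls) in enumerate(self.regions):
            if rect.row0 < 0 or rect.col0 < 0 or rect.row1 > rows or rect.col1 > cols:
                raise ValueError(f"region #{i} {rect} outside canvas {self.canvas}")
            if not self.palette.get(TissueClass.from_name(cls)):
                raise ValueError(
                    f"region #{i} references class {TissueClass(cls).name.lower()} "
                    "with no palette color"
                )
        if not self.palette.get(TissueClass.BACKGROUND):
            raise ValueError("background class has no palette color")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if rects[i].overlaps(rects[j]):
                    raise ValueError(f"regions #{i} and #{j} overlap: {rects[i]} / {rects[j]}")

    def class_areas(self) -> dict[TissueClass, int]:
        """Exact per-class ground-truth areas from rectangle arithmetic."""
        self.validate()
        areas = {cls: 0 for cls in TissueClass}
        covered = 0
        for rect, cls in self.regions:
            areas[TissueClass.from_name(cls)] += rect.area
            covered += rect.area
        areas[TissueClass.BACKGROUND] += self.canvas[0] * self.canvas[1] - covered
        return areas


def _fill_from_palette(
    rng: np.random.Generator,
    colors: Sequence[tuple[int, int, int]],
    shape: tuple[int, int],
) -> np.ndarray:
    pal = np.asarray(colors, dtype=np.uint8)
    idx = rng.integers(0, len(pal), size=shape)
    return pal[idx]


def generate_chart(spec: ChartSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a spec into ``(rgb_image, ground_truth_mask)``.

    Deterministic for a given spec and seed. Noise is added after the
    palette fill and clipped to [0, 255], so the mask always matches the
    rectangles exactly regardless of noise level.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.canvas
    image = _fill_from_palette(rng, spec.palette[TissueClass.BACKGROUND], (rows, cols))
    mask = np.full((rows, cols), int(TissueClass.BACKGROUND), dtype=np.uint8)
    for rect, cls in spec.regions:
        cls = TissueClass.from_name(cls)
        block = _fill_from_palette(
            rng, spec.palette[cls], (rect.row1 - rect.row0, rect.col1 - rect.col0)
        )
        image[rect.row0 : rect.row1, rect.col0 : rect.col1] = block
        mask[rect.row0 : rect.row1, rect.col0 : rect.col1] = int(cls)
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=image.shape)
        image = np.clip(np.rint(image.astype(float) + noise), 0, 255).astype(np.uint8)
    return image, mask


def default_table3_spec(
    staining: str, noise_sigma: float = 0.0, seed: int = 0
) -> ChartSpec:
    """The standard accuracy-benchmark chart for a staining preset.

    A 590x254 canvas tiled by a 422x254 healthy band (107,188 px²) over a
    168x127 fibrotic and a 168x127 background block (21,336 px² each), using
    the preset palette of the staining. The per-class areas are the fixed
    benchmark values in :data:`BENCHMARK_AREAS`; the exact rectangle layout
    is immaterial to a per-pixel classifier.
    """
    palette = preset_palette(staining)  # raises on unknown staining
    regions = (
        (Rect(0, 0, 422, 254), TissueClass.HEALTHY),
        (Rect(422, 0, 590, 127), TissueClass.FIBROTIC),
        (Rect(422, 127, 590, 254), TissueClass.BACKGROUND),
    )
    spec = ChartSpec(
        canvas=(590, 254),
        regions=regions,
        palette=palette,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    spec.validate()
    return spec


def multimodal_demo_spec(noise_sigma: float = 8.0, seed: int = 0) -> ChartSpec:
    """A chart on which iterative k-means characteristically fails.

    The healthy class has two widely separated color modes (pale pink and
    dark red). A three-cluster iterative k-means must either split the
    bimodal class or merge it with a neighbor, whereas fixed per-mode
    sub-cluster centers cover both modes under one class label.
    """
    palette = {
        TissueClass.BACKGROUND: [(245, 245, 245)],
        TissueClass.HEALTHY: [(235, 170, 180), (130, 25, 45)],
        TissueClass.FIBROTIC: [(70, 90, 180)],
    }
    regions = (
        (Rect(0, 0, 200, 100), TissueClass.HEALTHY),
        (Rect(0, 100, 100, 200), TissueClass.FIBROTIC),
        (Rect(100, 100, 200, 200), TissueClass.BACKGROUND),
    )
    spec = ChartSpec(
        canvas=(200, 200),
        regions=regions,
        palette=palette,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# YAML serialization (documented schema, version 1)
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: ChartSpec, path: "str | Path") -> None:
    """Write a spec as a human-editable YAML file.

    Schema (version 1)::

        version: 1
        canvas: [rows, cols]
        noise_sigma: float
        seed: int
        regions:                      # row/col bounds are half-open
          - {row0: 0, col0: 0, row1: 422, col1: 254, class: healthy}
        palette:
          background: [[245, 245, 245]]
          healthy: [[190, 60, 80]]
          fibrotic: [[70, 90, 180]]
    """
    doc = {
        "version": 1,
        "canvas": [int(x) for x in spec.canvas],
        "noise_sigma": float(spec.noise_sigma),
        "seed": int(spec.seed),
        "regions": [
            {
                "row0": r.row0,
                "col0": r.col0,
                "row1": r.row1,
                "col1": r.col1,
                "class": TissueClass.from_name(c).name.lower(),
            }
            for r, c in spec.regions
        ],
        "palette": {
            TissueClass.from_name(cls).name.lower(): [
                [int(ch) for ch in rgb] for rgb in colors
            ]
            for cls, colors in spec.palette.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: "str | Path") -> ChartSpec:
    """Load a spec written by :func:`spec_to_yaml`; validates on load."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or int(doc.get("version", 1)) != 1:
        raise ValueError(f"{path}: unsupported chart spec document")
    regions = tuple(
        (
            Rect(int(r["row0"]), int(r["col0"]), int(r["row1"]), int(r["col1"])),
            TissueClass.from_name(r["class"]),
        )
        for r in doc.get("regions", [])
    )
    palette = {
        TissueClass.from_name(name): [tuple(int(c) for c in rgb) for rgb in colors]
        for name, colors in doc.get("palette", {}).items()
    }
    spec = ChartSpec(
        canvas=tuple(int(x) for x in doc["canvas"]),
        regions=regions,
        palette=palette,
        noise_sigma=float(doc.get("noise_sigma", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
    spec.validate()
    return spec
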