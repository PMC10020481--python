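"""Folder-level batch processing: image IO, segmentation of whole datasets, CSV export.

All images in a batch are segmented with the SAME model, which is what makes
fibrosis percentages comparable across slices of one experiment. Files are
processed in natural-sort filename order (filesystem enumeration order is
nondeterministic); per-file decode errors are collected as failures without
aborting the batch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .classifier import ClassifierModel, TissueClass, segment_image
from .quantify import QuantRecord

__all__ = [
    "BatchResult",
    "read_image",
    "batch_process",
    "export_csv",
    "write_mask",
    "read_mask",
    "model_from_sample_file",
    "CSV_COLUMNS",
]

#: Fixed CSV column order of :func:`export_csv`.
CSV_COLUMNS = (
    "image",
    "background_px",
    "healthy_px",
    "fibrotic_px",
    "cell_px",
    "fibrosis_percent",
)

IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

#: Per-class RGB tint of overlay masks: background gray, healthy red,
#: fibrotic blue.
OVERLAY_COLORS = {
    TissueClass.BACKGROUND: (150, 150, 150),
    TissueClass.HEALTHY: (220, 60, 60),
    TissueClass.FIBROTIC: (60, 60, 220),
}


@dataclass(frozen=True)
class BatchResult:
    """Outcome of one batch run: records, the model digest, and failures."""

    records: tuple[QuantRecord, ...]
    model_fingerprint: str
    failures: tuple[tuple[str, str], ...] = ()


def _natural_key(name: str) -> tuple:
    return tuple(
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", name)
    )


def read_image(path: "str | Path") -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB array.

    Grayscale is promoted to three channels, an alpha channel is dropped,
    and 16-bit data are rescaled to 8-bit (divide by 257, round). TIFF goes
    through tifffile, PNG through imageio.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = np.rint(arr / 257.0).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path.name}: unsupported pixel dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ValueError(f"{path.name}: unsupported image shape {arr.shape}")
    return np.ascontiguousarray(arr)


def batch_process(
    model: ClassifierModel,
    folder: "str | Path",
    *,
    masks_dir: "str | Path | None" = None,
    mask_mode: str = "labels",
    suffixes: Sequence[str] = tuple(sorted(IMAGE_SUFFIXES)),
) -> BatchResult:
    """Segment and quantify every image of a folder with one shared model.

    Returns one :class:`~fibroquant.quantify.QuantRecord` per successfully
    processed image, in natural-sort filename order, plus a
    ``(filename, reason)`` failure entry for each unreadable file. With
    ``masks_dir`` set, the label (or overlay) mask of each image is written
    there as ``<stem>_mask.png``.
    """
    model.validate()
    folder = Path(folder)
    if not folder.is_dir():
        raise NotADirectoryError(f"not a folder: {folder}")
    suffix_set = {s.lower() for s in suffixes}
    files = sorted(
        (p for p in folder.iterdir() if p.is_file() and p.suffix.lower() in suffix_set),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise ValueError(f"no image files ({', '.join(sorted(suffix_set))}) in {folder}")
    if masks_dir is not None:
        masks_dir = Path(masks_dir)
        masks_dir.mkdir(parents=True, exist_ok=True)
    records: list[QuantRecord] = []
    failures: list[tuple[str, str]] = []
    for path in files:
        try:
            image = read_image(path)
            mask = segment_image(model, image)
            records.append(QuantRecord.from_mask(path.name, mask))
        except Exception as exc:  # failure isolation: the batch continues
            failures.append((path.name, f"decode error: {exc}"))
            continue
        if masks_dir is not None:
            write_mask(
                mask,
                masks_dir / f"{path.stem}_mask.png",
                mode=mask_mode,
                source=image if mask_mode == "overlay" else None,
            )
    return BatchResult(
        records=tuple(records),
        model_fingerprint=model.fingerprint(),
        failures=tuple(failures),
    )


def export_csv(result: BatchResult, path: "str | Path", delimiter: str = ",") -> None:
    """Write batch records as CSV (UTF-8, dot decimal, newline-terminated).

    The first line is a comment carrying the model fingerprint so every
    results table is traceable to the sample selection that produced it.
    Floats are written with full round-trip precision; rounding is a display
    concern.
    """
    if not result.records:
        raise ValueError("refusing to export an empty batch result")
    path = Path(path)
    lines = [f"# model={result.model_fingerprint}", delimiter.join(CSV_COLUMNS)]
    for rec in result.records:
        c = rec.counts
        lines.append(
            delimiter.join(
                [
                    rec.image_id,
                    str(c.background_px),
                    str(c.healthy_px),
                    str(c.fibrotic_px),
                    str(rec.cell_px),
                    repr(float(rec.fibrosis_percent)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_mask(
    mask: np.ndarray,
    path: "str | Path",
    mode: str = "labels",
    source: "np.ndarray | None" = None,
) -> None:
    """Write a label mask as an image file.

    ``labels`` mode stores the raw 0/1/2 codes in a single-channel 8-bit
    image (lossless round trip via :func:`read_mask`); ``overlay`` mode
    blends the source image with fixed per-class colors for visual review.
    """
    path = Path(path)
    mask = np.asarray(mask, dtype=np.uint8)
    if mode == "labels":
        out = mask
    elif mode == "overlay":
        if source is None:
            raise ValueError("overlay mode requires the source image")
        src = np.asarray(source)
        if src.shape[:2] != mask.shape:
            raise ValueError(f"source shape {src.shape[:2]} != mask shape {mask.shape}")
        tint = np.zeros((*mask.shape, 3), dtype=float)
        for cls, rgb in OVERLAY_COLORS.items():
            tint[mask == int(cls)] = rgb
        out = np.clip(np.rint(0.5 * src.astype(float) + 0.5 * tint), 0, 255).astype(
            np.uint8
        )
    else:
        raise ValueError(f"unknown mask mode {mode!r}; use 'labels' or 'overlay'")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path: "str | Path") -> np.ndarray:
    """Read back a labels-mode mask written by :func:`write_mask`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: not a single-channel label mask")
    return arr.astype(np.uint8)


def model_from_sample_file(
    path: "str | Path",
    images_dir: "str | Path",
    weights: Sequence[float] = (1.0, 1.0, 1.0),
    patch: int = 1,
) -> ClassifierModel:
    """Build a model from a sample-point CSV referencing reference images.

    Schema (version 1, header required): ``image,row,col,class`` — one
    sample point per row, image filenames resolved inside ``images_dir``,
    class one of background/healthy/fibrotic. Row order is sub-cluster
    insertion order, which fixes tie-breaking.
    """
    import csv

    from .classifier import ClassifierModel, subcluster_from_point

    path = Path(path)
    images_dir = Path(images_dir)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not (
            {"image", "row", "col", "class"}
            <= {n.strip().lower() for n in reader.fieldnames}
        ):
            raise ValueError(f"{path}: sample file header must be image,row,col,class")
        rows = [{k.strip().lower(): v for k, v in r.items()} for r in reader]
    if not rows:
        raise ValueError(f"{path}: no sample points")
    subclusters = []
    cache: dict[str, np.ndarray] = {}
    for r in rows:
        name = r["image"].strip()
        if name not in cache:
            cache[name] = read_image(images_dir / name)
        subclusters.append(
            subcluster_from_point(
                cache[name],
                int(r["row"]),
                int(r["col"]),
                r["class"],
                patch=patch,
                image_id=name,
            )
        )
    model = ClassifierModel(subclusters=tuple(subclusters), weights=tuple(weights))
    model.validate()
    return model
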