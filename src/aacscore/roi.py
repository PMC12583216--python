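"""Anatomical ROI extraction: vertebra mask -> standardized regressor patch.

The regressor input is a crop of the radiograph covering the lumbar spine
and the abdominal aorta: vertically from the inferior border of T12 down to
the inferior border of L5, horizontally from the posterior-most vertebral
extent to the anterior-most vertebral extent extended anteriorly by 3/4 of
the mean anteroposterior vertebral length (to include the aorta, which runs
anterior to the spine).  Because the segmenter labels only L1-L5, the T12
inferior border is estimated as L1's superior extent minus half the mean
intervertebral gap — anatomically the T12-L1 gap resembles the lumbar gaps.

The crop is Z-score normalised and resized (bilinear) to a fixed target,
500 columns x 1000 rows at full scale, 125 x 250 at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .segmentation import CoverageReport, VertebraMask, check_roi_coverage

__all__ = ["CropBox", "Patch", "compute_crop_box", "compute_crop_box_from_labels",
           "extract_patch", "transform_mask", "TARGET_FULL", "TARGET_DESK"]

#: Full-scale patch target as (cols, rows).
TARGET_FULL: tuple[int, int] = (500, 1000)
#: Desk-scale patch target as (cols, rows).
TARGET_DESK: tuple[int, int] = (125, 250)


@dataclass(frozen=True)
class CropBox:
    """Half-open crop rectangle [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_start >= self.row_end or self.col_start >= self.col_end:
            raise ValueError(f"degenerate crop box {self}")

    def clamp(self, shape: tuple[int, int]) -> "CropBox":
        H, W = shape
        return CropBox(
            max(0, self.row_start), min(H, self.row_end),
            max(0, self.col_start), min(W, self.col_end),
        )


@dataclass(frozen=True)
class Patch:
    """Normalised, resized regressor input with its provenance."""

    pixels: np.ndarray
    normalization: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class RoiCoverageError(ValueError):
    """Raised when a mask fails the ROI-coverage check; carries the report."""

    def __init__(self, report: CoverageReport):
        super().__init__("mask failed ROI coverage check: " + "; ".join(report.reasons))
        self.report = report


def _extents(labels: np.ndarray, lab: int) -> tuple[int, int, int, int]:
    """(r0, r1, c0, c1) half-open extents of one label."""
    m = labels == lab
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def compute_crop_box(mask: VertebraMask, anterior_factor: float = 0.75,
                     t12_gap_factor: float = 0.5) -> CropBox:
    """Compute the anatomical crop rectangle from a vertebra mask.

    * ``row_end``: inferior extent of L5.
    * ``row_start``: estimated T12 inferior border = L1 superior extent minus
      ``t12_gap_factor`` x the mean of the four L1-L5 intervertebral gaps
      (rounded to the nearest row).
    * Columns: from the posterior-most to the anterior-most vertebral extent,
      the latter extended anteriorly by ``anterior_factor`` x the mean
      anteroposterior vertebral (column) extent over L1-L5.

    The box is clamped to the image bounds.
    """
    report = check_roi_coverage(mask)
    if not report.passed:
        raise RoiCoverageError(report)
    labels = mask.labels
    ext = {lab: _extents(labels, lab) for lab in range(1, 6)}

    gaps = [ext[lab + 1][0] - ext[lab][1] for lab in range(1, 5)]
    mean_gap = float(np.mean(gaps))
    row_start = ext[1][0] - int(round(t12_gap_factor * mean_gap))
    row_end = ext[5][1]

    ap_lengths = [ext[lab][3] - ext[lab][2] for lab in range(1, 6)]
    mean_ap = float(np.mean(ap_lengths))
    extension = int(round(anterior_factor * mean_ap))
    c_min = min(ext[lab][2] for lab in range(1, 6))
    c_max = max(ext[lab][3] for lab in range(1, 6))
    if mask.anterior_side == "left":
        col_start, col_end = c_min - extension, c_max
    else:
        col_start, col_end = c_min, c_max + extension
    return CropBox(row_start, row_end, col_start, col_end).clamp(labels.shape)


def compute_crop_box_from_labels(labels: np.ndarray, anterior_side: str = "left", **kwargs) -> CropBox:
    """Convenience wrapper: crop box directly from a raw label array."""
    return compute_crop_box(VertebraMask(labels=np.asarray(labels), anterior_side=anterior_side), **kwargs)


def extract_patch(
    image: np.ndarray, box: CropBox, target: tuple[int, int] = TARGET_FULL,
    source_id: str = "",
) -> Patch:
    """Crop, Z-score normalise, and bilinearly resize to ``target`` (cols, rows).

    Normalisation happens on the crop before resizing (mean 0, sd 1 over the
    crop; an all-constant crop maps to all zeros).
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    box = box.clamp(image.shape)
    crop = image[box.row_start : box.row_end, box.col_start : box.col_end]
    if crop.size == 0:
        raise ValueError(f"empty crop for box {box}")
    sd = float(crop.astype(np.float64).std())
    mean = float(crop.astype(np.float64).mean())
    norm = np.zeros_like(crop) if sd == 0 else (crop - mean) / sd
    cols, rows = target
    pixels = _sk_resize(norm, (rows, cols), order=1, anti_aliasing=False, preserve_range=True)
    return Patch(
        pixels=pixels.astype(np.float32),
        normalization={"method": "zscore_then_bilinear_resize", "mean": mean, "sd": sd,
                       "target_cols_rows": tuple(target)},
        provenance={"source_id": source_id, "box": (box.row_start, box.row_end, box.col_start, box.col_end)},
    )


def transform_mask(mask: np.ndarray, box: CropBox, target: tuple[int, int] = TARGET_FULL) -> np.ndarray:
    """Map a binary mask through the same crop/resize as a patch (nearest)."""
    mask = np.asarray(mask).astype(bool)
    box = box.clamp(mask.shape)
    crop = mask[box.row_start : box.row_end, box.col_start : box.col_end].astype(np.float32)
    cols, rows = target
    out = _sk_resize(crop, (rows, cols), order=0, anti_aliasing=False, preserve_range=True)
    return out > 0.5
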