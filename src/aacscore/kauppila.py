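"""Kauppila semi-quantitative AAC-24 scoring.

The Kauppila system grades abdominal aortic calcification on a lateral
radiograph over four aortic segments (at vertebral levels L1-L4), each split
into an anterior and a posterior wall.  Every one of the eight (level, wall)
segments receives a grade 0-3 from the craniocaudal length of calcification
relative to the segment length:

* 0 - no detectable calcification,
* 1 - calcified length < 1/3 of the segment,
* 2 - calcified length >= 1/3 and <= 2/3,
* 3 - calcified length > 2/3.

The total score (0-24) is the sum of the eight grades, and severity is
categorised as no/mild (0-4), moderate (5-15) or severe (16-24).

Segment boundaries along the craniocaudal axis sit at the midpoints of the
intervertebral spaces adjacent to each vertebral body, so each segment span
can be derived from a vertebra label mask alone.  :func:`score_from_masks`
applies the full grading procedure automatically to a binary calcification
mask plus a vertebra mask and serves as the reference oracle for the learned
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

LEVELS = ("L1", "L2", "L3", "L4")
WALLS = ("anterior", "posterior")

__all__ = [
    "LEVELS",
    "WALLS",
    "Severity",
    "SegmentKey",
    "KauppilaScore",
    "SegmentSpans",
    "SEGMENT_KEYS",
    "grade_segment",
    "total_score",
    "classify_severity",
    "segment_spans",
    "score_from_masks",
]


class Severity(str, Enum):
    """Severity tier of the total AAC-24 score."""

    no_mild = "no_mild"
    moderate = "moderate"
    severe = "severe"


@dataclass(frozen=True, order=True)
class SegmentKey:
    """One of the eight scored aortic wall segments."""

    level: str
    wall: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.wall not in WALLS:
            raise ValueError(f"wall must be one of {WALLS}, got {self.wall!r}")

    @property
    def short(self) -> str:
        """Compact manifest column name, e.g. ``g_L1a``."""
        return f"g_{self.level}{self.wall[0]}"


#: The eight segment keys in canonical (level-major, anterior-first) order.
SEGMENT_KEYS: tuple[SegmentKey, ...] = tuple(
    SegmentKey(level, wall) for level in LEVELS for wall in WALLS
)


def grade_segment(calcified_fraction: float) -> int:
    """Grade one aortic wall segment from its calcified length fraction.

    Parameters
    ----------
    calcified_fraction
        Craniocaudal calcified length divided by segment length, in [0, 1].

    Returns
    -------
    int
        0 if no calcification; 1 if the fraction is below 1/3; 2 if it is
        between 1/3 and 2/3 inclusive; 3 if it exceeds 2/3.
    """
    f = float(calcified_fraction)
    if not np.isfinite(f) or f < 0.0 or f > 1.0:
        raise ValueError(f"calcified_fraction must be in [0, 1], got {calcified_fraction!r}")
    if f == 0.0:
        return 0
    if f < 1.0 / 3.0:
        return 1
    if f <= 2.0 / 3.0:
        return 2
    return 3


def total_score(grades: Mapping[SegmentKey, int]) -> int:
    """Sum the eight per-segment grades into the AAC-24 total."""
    missing = [k.short for k in SEGMENT_KEYS if k not in grades]
    if missing:
        raise ValueError(f"missing segment grades: {missing}")
    for key in SEGMENT_KEYS:
        g = grades[key]
        if not isinstance(g, (int, np.integer)) or g not in (0, 1, 2, 3):
            raise ValueError(f"grade for {key.short} must be an integer in 0..3, got {g!r}")
    return int(sum(int(grades[k]) for k in SEGMENT_KEYS))


def classify_severity(total: int) -> Severity:
    """Map a total score 0-24 to its severity tier (no/mild, moderate, severe)."""
    if not isinstance(total, (int, np.integer)):
        raise ValueError(f"total must be an integer, got {total!r}")
    t = int(total)
    if t < 0 or t > 24:
        raise ValueError(f"total must be in [0, 24], got {t}")
    if t <= 4:
        return Severity.no_mild
    if t <= 15:
        return Severity.moderate
    return Severity.severe


@dataclass(frozen=True)
class KauppilaScore:
    """Complete AAC-24 score: eight grades, total, severity category."""

    grades: Mapping[SegmentKey, int]
    total: int = field(default=-1)
    category: Severity = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = total_score(self.grades)
        if self.total == -1:
            object.__setattr__(self, "total", t)
        elif int(self.total) != t:
            raise ValueError(f"total {self.total} inconsistent with grade sum {t}")
        cat = classify_severity(self.total)
        if self.category is None:
            object.__setattr__(self, "category", cat)
        elif Severity(self.category) is not cat:
            raise ValueError(f"category {self.category} inconsistent with total {self.total}")

    @classmethod
    def from_grades(cls, grades: Mapping[SegmentKey, int]) -> "KauppilaScore":
        return cls(grades=dict(grades))

    @classmethod
    def from_fractions(cls, fractions: Mapping[SegmentKey, float]) -> "KauppilaScore":
        """Analytic score from per-segment calcified length fractions."""
        return cls.from_grades({k: grade_segment(fractions.get(k, 0.0)) for k in SEGMENT_KEYS})

    def as_row(self) -> dict:
        """Flat dict using the manifest column names."""
        row = {k.short: int(self.grades[k]) for k in SEGMENT_KEYS}
        row["total"] = int(self.total)
        row["category"] = self.category.value
        return row

    @classmethod
    def from_row(cls, row: Mapping) -> "KauppilaScore":
        grades = {k: int(row[k.short]) for k in SEGMENT_KEYS}
        return cls.from_grades(grades)


@dataclass(frozen=True)
class SegmentSpans:
    """Half-open craniocaudal row intervals of the four scored segments.

    Row 0 is superior; rows increase inferiorly.  The L1 segment starts at
    L1's superior extent; boundaries between consecutive segments sit at the
    midpoint of the intervertebral gap; the L4 segment ends at the midpoint
    of the L4-L5 gap.
    """

    spans: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = None
        for level in LEVELS:
            if level not in self.spans:
                raise ValueError(f"missing span for {level}")
            r0, r1 = self.spans[level]
            if r0 >= r1:
                raise ValueError(f"empty span for {level}: [{r0}, {r1})")
            if prev_end is not None and r0 != prev_end:
                raise ValueError(f"spans not contiguous at {level}: expected start {prev_end}, got {r0}")
            prev_end = r1

    def __getitem__(self, level: str) -> tuple[int, int]:
        return tuple(self.spans[level])

    def length(self, level: str) -> int:
        r0, r1 = self.spans[level]
        return r1 - r0


def _label_row_extents(labels: np.ndarray) -> dict[int, tuple[int, int]]:
    """Half-open row extent [r0, r1) of each vertebra label 1..5."""
    extents: dict[int, tuple[int, int]] = {}
    for lab in range(1, 6):
        rows = np.flatnonzero((labels == lab).any(axis=1))
        if rows.size:
            extents[lab] = (int(rows[0]), int(rows[-1]) + 1)
    return extents


def segment_spans(mask) -> SegmentSpans:
    """Derive the L1-L4 aortic segment row spans from a vertebra label mask.

    Parameters
    ----------
    mask
        A :class:`~aacscore.segmentation.VertebraMask` or a plain 2-D integer
        label array with labels 1..5 for L1..L5 ordered superior to inferior.

    Raises
    ------
    ValueError
        With a message listing every structural failure (missing labels,
        wrong ordering, fragmented labels).
    """
    labels = np.asarray(getattr(mask, "labels", mask))
    if labels.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {labels.shape}")

    from scipy import ndimage

    failures: list[str] = []
    extents = _label_row_extents(labels)
    for lab, name in enumerate(("L1", "L2", "L3", "L4", "L5"), start=1):
        if lab not in extents:
            failures.append(f"missing {name}")
            continue
        _, n_comp = ndimage.label(labels == lab)
        if n_comp != 1:
            failures.append(f"{name} split into {n_comp} components")
    if not failures:
        order = sorted(extents, key=lambda lab: extents[lab][0])
        if order != [1, 2, 3, 4, 5]:
            failures.append(f"vertebrae not ordered superior to inferior: {order}")
        else:
            for lab in range(1, 5):
                if extents[lab][1] > extents[lab + 1][0]:
                    failures.append(f"L{lab} and L{lab + 1} overlap in rows")
    if failures:
        raise ValueError("invalid vertebra mask: " + "; ".join(failures))

    # Boundary between consecutive segments = midpoint of the intervertebral gap.
    def mid(gap_start: int, gap_end: int) -> int:
        return (gap_start + gap_end) // 2

    bounds = [extents[1][0]]
    for lab in range(1, 5):
        bounds.append(mid(extents[lab][1], extents[lab + 1][0]))
    spans = {level: (bounds[i], bounds[i + 1]) for i, level in enumerate(LEVELS)}
    return SegmentSpans(spans=spans)


def score_from_masks(
    calc_mask: np.ndarray,
    mask,
    anterior_side: str = "left",
    aorta_midline: float | None = None,
) -> KauppilaScore:
    """Score a case automatically from its calcification and vertebra masks.

    Calcified pixels are assigned to the anterior or posterior aortic wall by
    their column relative to a vertical midline through the aortic band.  By
    default the midline is estimated as the centre of the calcification-
    bearing column range; pass ``aorta_midline`` to use a known band centre
    instead (exact on phantoms, where the band geometry is known).  Within
    each (level, wall) segment the calcified fraction is the number of
    distinct rows containing assigned calcified pixels divided by the segment
    span length — i.e. craniocaudal calcified length over segment length.
    """
    if anterior_side not in ("left", "right"):
        raise ValueError(f"anterior_side must be 'left' or 'right', got {anterior_side!r}")
    calc = np.asarray(calc_mask).astype(bool)
    labels = np.asarray(getattr(mask, "labels", mask))
    if calc.shape != labels.shape:
        raise ValueError(f"calcification mask shape {calc.shape} != vertebra mask shape {labels.shape}")

    spans = segment_spans(mask)

    rows, cols = np.nonzero(calc)
    if rows.size == 0:
        return KauppilaScore.from_fractions({})

    if aorta_midline is None:
        aorta_midline = (cols.min() + cols.max() + 1) / 2.0

    # anterior = smaller columns when the patient's front faces left.
    if anterior_side == "left":
        anterior_px = cols < aorta_midline
    else:
        anterior_px = cols >= aorta_midline

    fractions: dict[SegmentKey, float] = {}
    for level in LEVELS:
        r0, r1 = spans[level]
        in_span = (rows >= r0) & (rows < r1)
        span_len = r1 - r0
        for wall, sel in (("anterior", anterior_px), ("posterior", ~anterior_px)):
            covered = np.unique(rows[in_span & sel]).size
            fractions[SegmentKey(level, wall)] = covered / span_len
    return KauppilaScore.from_fractions(fractions)
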