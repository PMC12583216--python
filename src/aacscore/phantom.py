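"""Synthetic lateral-radiograph phantoms with known AAC ground truth.

Real lateral lumbar/abdominal radiographs carry five stacked vertebral
bodies, intervertebral gaps, and the abdominal aorta running just anterior
to the spine; calcified plaque appears as high-intensity deposits along the
anterior and posterior aortic walls.  This module renders a simplified 2-D
phantom with exactly those elements — rectangular vertebral bodies, an
anterior aortic band, and per-segment calcified strips of known length
fraction — plus soft-tissue background and multicenter-style photometric
heterogeneity (brightness/contrast/noise strata).

Because every strip length fraction is known, each phantom comes with an
analytic Kauppila score, giving every downstream stage (segmentation, ROI
extraction, score regression, explanation) labelled, licence-free test data.
The strip model is a stand-in for real calcification morphology (punctate or
arc-shaped deposits); it preserves the quantity the Kauppila score actually
measures, the craniocaudal calcified length per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import kauppila
from .kauppila import SEGMENT_KEYS, KauppilaScore, SegmentKey, Severity
from .segmentation import VertebraMask

__all__ = [
    "IntensityParams",
    "PhantomSpec",
    "PhantomSample",
    "Heterogeneity",
    "CohortSpec",
    "GRADE_FRACTION_BANDS",
    "make_phantom",
    "score_sample",
    "sample_cohort",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class IntensityParams:
    """Mean intensities (on a 0-1 scale) and photometric parameters."""

    background: float = 0.30
    aorta_band: float = 0.36
    bone: float = 0.80
    calcification: float = 0.62
    noise_sigma: float = 0.02
    brightness: float = 0.0   # additive offset applied after rendering
    contrast: float = 1.0     # multiplicative contrast about mid-grey


@dataclass(frozen=True)
class PhantomSpec:
    """Full geometric and photometric description of one phantom.

    Coordinates: row 0 is superior, rows increase inferiorly; columns are
    anatomical left-right with ``anterior_side`` naming the direction of the
    patient's front.  All boxes are half-open ``[r0, r1) x [c0, c1)``.
    """

    image_height: int = 256
    image_width: int = 128
    vertebra_heights: tuple[int, ...] = (36, 36, 36, 36, 36)
    vertebra_ap_lengths: tuple[int, ...] = (40, 40, 40, 40, 40)
    gap_heights: tuple[int, ...] = (10, 10, 10, 10)
    posterior_margin: int = 8
    aorta_offset: int = 6
    aorta_width: int = 18
    calcified_fractions: dict[SegmentKey, float] = field(default_factory=dict)
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    anterior_side: str = "left"
    random_strip_placement: bool = False

    def validate(self) -> None:
        for name in ("image_height", "image_width", "posterior_margin", "aorta_offset", "aorta_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if len(self.vertebra_heights) != 5 or len(self.vertebra_ap_lengths) != 5:
            raise ValueError("vertebra_heights and vertebra_ap_lengths must have 5 entries")
        if len(self.gap_heights) != 4:
            raise ValueError("gap_heights must have 4 entries (between 5 vertebrae)")
        if any(h <= 0 for h in self.vertebra_heights) or any(g <= 0 for g in self.gap_heights):
            raise ValueError("vertebra_heights and gap_heights must all be positive")
        if any(a <= 0 for a in self.vertebra_ap_lengths):
            raise ValueError("vertebra_ap_lengths must all be positive")
        column = sum(self.vertebra_heights) + sum(self.gap_heights)
        if column > self.image_height:
            raise ValueError(
                f"vertebra_heights + gap_heights = {column} rows do not fit image_height {self.image_height}"
            )
        band0, _ = self._aorta_band_canonical()
        if band0 < 0:
            raise ValueError(
                "aorta_offset + aorta_width push the aortic band outside the image "
                f"(band would start at column {band0})"
            )
        if self.anterior_side not in ("left", "right"):
            raise ValueError(f"anterior_side must be 'left' or 'right', got {self.anterior_side!r}")
        for key, f in self.calcified_fractions.items():
            if not isinstance(key, SegmentKey):
                raise ValueError(f"calcified_fractions keys must be SegmentKey, got {key!r}")
            if not (0.0 <= float(f) <= 1.0):
                raise ValueError(f"calcified_fraction for {key.short} must be in [0,1], got {f}")

    # --- canonical (anterior = left) geometry -------------------------------
    def _spine_posterior_col(self) -> int:
        return self.image_width - self.posterior_margin

    def _aorta_band_canonical(self) -> tuple[int, int]:
        """Aortic band columns [c0, c1) in the canonical left-anterior frame."""
        anterior_vertebral_col = self._spine_posterior_col() - max(self.vertebra_ap_lengths)
        band1 = anterior_vertebral_col - self.aorta_offset
        return band1 - self.aorta_width, band1

    def aorta_band(self) -> tuple[int, int]:
        """Aortic band columns [c0, c1) in the spec's own orientation."""
        c0, c1 = self._aorta_band_canonical()
        if self.anterior_side == "right":
            return self.image_width - c1, self.image_width - c0
        return c0, c1

    def aorta_midline(self) -> float:
        """Column of the aortic band midline (anterior/posterior wall split)."""
        c0, c1 = self.aorta_band()
        return (c0 + c1) / 2.0

    def truth(self) -> KauppilaScore:
        return KauppilaScore.from_fractions(self.calcified_fractions)


@dataclass(frozen=True)
class PhantomSample:
    """One rendered phantom: image, masks, analytic ground truth."""

    image: np.ndarray            # float32 in [0, 1]
    vertebra_mask: VertebraMask
    calcification_mask: np.ndarray
    truth: KauppilaScore
    spec: PhantomSpec
    seed: int
    case_id: str = ""


def _render_canonical(spec: PhantomSpec, rng: np.random.Generator):
    """Render masks and noiseless structures in the left-anterior frame."""
    H, W = spec.image_height, spec.image_width
    labels = np.zeros((H, W), dtype=np.uint8)
    calc = np.zeros((H, W), dtype=bool)

    top = (H - sum(spec.vertebra_heights) - sum(spec.gap_heights)) // 2
    post_col = spec._spine_posterior_col()
    r = top
    for i in range(5):
        h, ap = spec.vertebra_heights[i], spec.vertebra_ap_lengths[i]
        labels[r : r + h, post_col - ap : post_col] = i + 1
        r += h
        if i < 4:
            r += spec.gap_heights[i]

    spans = kauppila.segment_spans(labels)
    band0, band1 = spec._aorta_band_canonical()
    mid = (band0 + band1) / 2.0
    wall_cols = {
        "anterior": (band0, int(np.floor(mid))),
        "posterior": (int(np.ceil(mid)), band1),
    }
    for key in SEGMENT_KEYS:
        f = float(spec.calcified_fractions.get(key, 0.0))
        if f <= 0.0:
            continue
        r0, r1 = spans[key.level]
        span = r1 - r0
        n = min(span, max(1, int(round(f * span))))
        start = r0 + (int(rng.integers(0, span - n + 1)) if spec.random_strip_placement else 0)
        c0, c1 = wall_cols[key.wall]
        calc[start : start + n, c0:c1] = True

    ip = spec.intensity_params
    img = np.full((H, W), ip.background, dtype=np.float32)
    img[band0:band1] = ip.background  # band columns handled below (column-wise)
    img[:, band0:band1] = ip.aorta_band
    img[labels > 0] = ip.bone
    img[calc] = ip.calcification
    return img, labels, calc


def make_phantom(spec: PhantomSpec, seed: int, case_id: str = "") -> PhantomSample:
    """Render one phantom deterministically from ``(spec, seed)``.

    The calcification strips are placed per (level, wall) segment with a
    craniocaudal extent of ``round(fraction * span)`` rows (at least one row
    for any nonzero fraction), flush with the anterior or posterior half of
    the aortic band.  The returned ground-truth score is computed
    analytically from the spec's fractions via the Kauppila grading rules.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    img, labels, calc = _render_canonical(spec, rng)

    ip = spec.intensity_params
    img = (img - 0.5) * ip.contrast + 0.5 + ip.brightness
    if ip.noise_sigma > 0:
        img = img + rng.normal(0.0, ip.noise_sigma, size=img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    if spec.anterior_side == "right":
        img = img[:, ::-1].copy()
        labels = labels[:, ::-1].copy()
        calc = calc[:, ::-1].copy()

    vmask = VertebraMask(labels=labels, anterior_side=spec.anterior_side)
    return PhantomSample(
        image=img,
        vertebra_mask=vmask,
        calcification_mask=calc,
        truth=spec.truth(),
        spec=spec,
        seed=int(seed),
        case_id=case_id,
    )


def score_sample(sample: PhantomSample) -> KauppilaScore:
    """Apply the automatic mask-based scorer to a phantom.

    Uses the phantom's known aortic-band midline for the anterior/posterior
    wall split (the generator records it in the spec), making the scorer an
    exact oracle up to strip rasterisation.
    """
    return kauppila.score_from_masks(
        sample.calcification_mask,
        sample.vertebra_mask,
        anterior_side=sample.spec.anterior_side,
        aorta_midline=sample.spec.aorta_midline(),
    )


#: Calcified-fraction sampling band for each grade.  Bands keep a safety
#: margin from the 1/3 and 2/3 grade boundaries so that rasterising a strip
#: to whole rows can never flip the analytic grade.
GRADE_FRACTION_BANDS: dict[int, tuple[float, float]] = {
    0: (0.0, 0.0),
    1: (0.05, 0.30),
    2: (0.37, 0.63),
    3: (0.70, 1.0),
}

#: Default severity mix (no/mild, moderate, severe) mirroring the proportions
#: of a large multicenter AAC training cohort (387 : 1,124 : 226).
DEFAULT_SEVERITY_MIX: tuple[float, float, float] = (387 / 1737, 1124 / 1737, 226 / 1737)

_SEVERITY_TOTAL_RANGE = {Severity.no_mild: (0, 4), Severity.moderate: (5, 15), Severity.severe: (16, 24)}


@dataclass(frozen=True)
class Heterogeneity:
    """Photometric parameter ranges across simulated acquisition centers."""

    brightness: tuple[float, float] = (-0.05, 0.05)
    contrast: tuple[float, float] = (0.85, 1.15)
    noise_sigma: tuple[float, float] = (0.01, 0.04)
    n_centers: int = 3


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a random phantom cohort."""

    n_cases: int
    severity_mix: tuple[float, float, float] = DEFAULT_SEVERITY_MIX
    heterogeneity: Heterogeneity = field(default_factory=Heterogeneity)
    seed: int = 0
    base: PhantomSpec = field(default_factory=PhantomSpec)
    geometry_jitter: float = 0.10  # relative jitter on heights/gaps/widths

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")
        mix = np.asarray(self.severity_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError(f"severity_mix must be 3 non-negative proportions summing to 1, got {self.severity_mix}")
        if self.heterogeneity.n_centers < 1:
            raise ValueError("n_centers must be >= 1")


def _random_grades(total: int, rng: np.random.Generator) -> dict[SegmentKey, int]:
    """Random distribution of ``total`` points over 8 segments, grades 0-3."""
    grades = {k: 0 for k in SEGMENT_KEYS}
    for _ in range(total):
        eligible = [k for k in SEGMENT_KEYS if grades[k] < 3]
        grades[eligible[int(rng.integers(len(eligible)))]] += 1
    return grades


def _jitter(value: int, rel: float, rng: np.random.Generator, lo: int = 1) -> int:
    span = max(1, int(round(value * rel)))
    return max(lo, value + int(rng.integers(-span, span + 1)))


def sample_cohort(cohort: CohortSpec) -> list[PhantomSample]:
    """Draw a reproducible cohort of phantoms.

    Per case: a severity category is drawn from ``severity_mix``, a total
    score uniformly within the category's range, grades by random allocation
    of that total, fractions uniformly within each grade's band, geometry by
    jittering the base spec, and photometric parameters from the simulated
    center the case is assigned to.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    het = cohort.heterogeneity
    centers = [
        IntensityParams(
            background=cohort.base.intensity_params.background,
            aorta_band=cohort.base.intensity_params.aorta_band,
            bone=cohort.base.intensity_params.bone,
            calcification=cohort.base.intensity_params.calcification,
            brightness=float(rng.uniform(*het.brightness)),
            contrast=float(rng.uniform(*het.contrast)),
            noise_sigma=float(rng.uniform(*het.noise_sigma)),
        )
        for _ in range(het.n_centers)
    ]

    samples = []
    categories = rng.choice(3, size=cohort.n_cases, p=np.asarray(cohort.severity_mix, dtype=float))
    for i in range(cohort.n_cases):
        cat = (Severity.no_mild, Severity.moderate, Severity.severe)[int(categories[i])]
        lo, hi = _SEVERITY_TOTAL_RANGE[cat]
        total = int(rng.integers(lo, hi + 1))
        grades = _random_grades(total, rng)
        fractions = {}
        for k, g in grades.items():
            if g:
                flo, fhi = GRADE_FRACTION_BANDS[g]
                fractions[k] = float(rng.uniform(flo, fhi))
        jr = cohort.geometry_jitter
        base = cohort.base
        spec = replace(
            base,
            vertebra_heights=tuple(_jitter(h, jr, rng, lo=8) for h in base.vertebra_heights),
            vertebra_ap_lengths=tuple(_jitter(a, jr, rng, lo=8) for a in base.vertebra_ap_lengths),
            gap_heights=tuple(_jitter(g, jr, rng, lo=3) for g in base.gap_heights),
            aorta_offset=_jitter(base.aorta_offset, jr, rng, lo=2),
            aorta_width=_jitter(base.aorta_width, jr, rng, lo=8),
            calcified_fractions=fractions,
            intensity_params=centers[int(rng.integers(het.n_centers))],
        )
        case_seed = int(rng.integers(2**31 - 1))
        samples.append(make_phantom(spec, seed=case_seed, case_id=f"case_{i:04d}"))
    return samples


MANIFEST_COLUMNS = ["id"] + [k.short for k in SEGMENT_KEYS] + ["total", "category", "seed"]


def write_dataset(samples: list[PhantomSample], directory: str | Path) -> pd.DataFrame:
    """Write images and masks as 16-bit PNG plus a CSV score manifest.

    Returns the manifest as a DataFrame with columns ``id, g_L1a..g_L4p,
    total, category, seed``.  Scores round-trip exactly through the CSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        cid = s.case_id or f"case_{i:04d}"
        iio.imwrite(directory / f"{cid}_image.png", (s.image * 65535).round().astype(np.uint16))
        iio.imwrite(directory / f"{cid}_vertebrae.png", s.vertebra_mask.labels.astype(np.uint16))
        iio.imwrite(directory / f"{cid}_calc.png", (s.calcification_mask.astype(np.uint16) * 65535))
        row = {"id": cid, **s.truth.as_row(), "seed": s.seed}
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_dataset(directory: str | Path) -> tuple[pd.DataFrame, list[dict]]:
    """Read back a written dataset: manifest plus per-case arrays.

    Returns ``(manifest, cases)`` where each case dict holds ``image`` (float
    in [0,1]), ``vertebra_labels``, ``calc_mask`` and ``truth``.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    cases = []
    for _, row in manifest.iterrows():
        cid = row["id"]
        image = iio.imread(directory / f"{cid}_image.png").astype(np.float32) / 65535.0
        labels = iio.imread(directory / f"{cid}_vertebrae.png").astype(np.uint8)
        calc = iio.imread(directory / f"{cid}_calc.png") > 0
        cases.append(
            {
                "id": cid,
                "image": image,
                "vertebra_labels": labels,
                "calc_mask": calc,
                "truth": KauppilaScore.from_row(row),
            }
        )
    return manifest, cases
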