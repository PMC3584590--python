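"""H-score quantification of immunohistochemistry spot images.

A DAB/hematoxylin-stained spot is scored in four steps: per-pixel class
(background / hematoxylin / DAB-positive, using the red-greater-than-blue
positivity rule), connected-component nucleus segmentation, per-object
intensity grading on the 0-255 gray scale of the red-minus-blue margin, and
the per-spot summary

    H-score = Σᵢ Pᵢ · i,   i = 0..3,

where Pᵢ is the percentage of scored objects (or tissue pixels, in pixel
mode) at intensity grade i. H ranges over [0, 300].

Two grading conventions are provided: object-intensity grading
(:func:`grade_objects`, the default) and percent-positive binning
(:func:`grade_from_percent`), in which the spot's intensity grade is read
off the fraction of positive cells (grade 1 ⇔ 10-25% positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.measure import label as _cc_label

__all__ = [
    "PixelClass",
    "SpotQuantification",
    "HScore",
    "DEFAULT_INTENSITY_THRESHOLDS",
    "BACKGROUND_BRIGHTNESS",
    "MIN_OBJECT_AREA",
    "classify_pixels",
    "segment_nuclei",
    "grade_objects",
    "grade_from_percent",
    "summarize_spot",
    "compute_h_score",
    "score_spot",
    "kruskal_wallis_concordance",
]

# Mean red-minus-blue margins separating intensity grades 0|1, 1|2, 2|3;
# midway between the synthetic stain margins so classes separate at default
# noise. Boundary values fall to the lower grade.
DEFAULT_INTENSITY_THRESHOLDS = (10.0, 55.0, 90.0)
BACKGROUND_BRIGHTNESS = 220.0  # mean channel above this is background
MIN_OBJECT_AREA = 20           # px; smaller components are debris


class PixelClass:
    BACKGROUND = 0
    HEMATOXYLIN = 1
    DAB_POSITIVE = 2


@dataclass
class SpotQuantification:
    """Percent of scored units at each intensity grade for one spot."""

    P: tuple[float, float, float, float]  # percentages, sum 100
    n_objects: int
    unit_mode: str = "nucleus"            # "nucleus" or "pixel"
    compartment: str = "Nuclear"

    def __post_init__(self) -> None:
        p = np.asarray(self.P, dtype=float)
        if self.n_objects > 0:
            if np.any(p < 0) or np.any(p > 100) or abs(p.sum() - 100.0) > 1e-6:
                raise ValueError("percentages must lie in [0,100] and sum to 100")
        if self.unit_mode not in ("nucleus", "pixel"):
            raise ValueError(f"unknown unit_mode {self.unit_mode!r}")


@dataclass
class HScore:
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 300.0 + 1e-9:
            raise ValueError("H-score must lie in [0, 300]")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")
    return image.astype(float)


def classify_pixels(image: np.ndarray, delta: float = 0.0) -> np.ndarray:
    """Classify each pixel as background, hematoxylin, or DAB-positive.

    Tissue pixels (mean channel at or below the brightness threshold) with
    red − blue > ``delta`` are DAB-positive; the rest of the tissue is
    hematoxylin. Bright pixels are background.
    """
    img = _check_rgb(image)
    brightness = img.mean(axis=2)
    rb = img[..., 0] - img[..., 2]
    out = np.full(img.shape[:2], PixelClass.HEMATOXYLIN, dtype=np.uint8)
    out[rb > delta] = PixelClass.DAB_POSITIVE
    out[brightness > BACKGROUND_BRIGHTNESS] = PixelClass.BACKGROUND
    return out


def segment_nuclei(image: np.ndarray, min_area: int = MIN_OBJECT_AREA) -> np.ndarray:
    """Label connected stained regions; components below ``min_area`` px drop.

    Returns an integer label map (0 = background); an empty map is allowed.
    """
    classes = classify_pixels(image)
    tissue = classes != PixelClass.BACKGROUND
    labels = _cc_label(tissue, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def grade_objects(
    objects: np.ndarray,
    image: np.ndarray,
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_THRESHOLDS,
) -> np.ndarray:
    """Per-object intensity grade from mean red-minus-blue staining margin.

    Grade 0 if the object's mean margin is ≤ t₁; grades 1-3 fill the
    successive half-open intervals (tᵢ, tᵢ₊₁] with the upper boundary
    belonging to the lower grade.
    """
    t1, t2, t3 = thresholds
    if not t1 < t2 < t3:
        raise ValueError("intensity thresholds must be strictly increasing")
    img = _check_rgb(image)
    objects = np.asarray(objects)
    n = int(objects.max())
    if n == 0:
        return np.zeros(0, dtype=int)
    rb = img[..., 0] - img[..., 2]
    flat_lab = objects.ravel()
    mask = flat_lab > 0
    sums = np.bincount(flat_lab[mask], weights=rb.ravel()[mask], minlength=n + 1)[1:]
    areas = np.bincount(flat_lab[mask], minlength=n + 1)[1:]
    means = sums / areas
    grades = np.digitize(means, [t1, t2, t3], right=True)
    return grades.astype(int)


def grade_from_percent(positive_percent: float) -> int:
    """Spot intensity grade from the percentage of positive cells.

    Bins: grade 0 for [0, 10), grade 1 for [10, 25), grade 2 for [25, 50),
    grade 3 for [50, 100]. The grade-1 interval follows the published
    convention; the flanking bins are this package's defaults.
    """
    p = float(positive_percent)
    if not 0.0 <= p <= 100.0:
        raise ValueError("positive_percent must lie in [0, 100]")
    if p < 10.0:
        return 0
    if p < 25.0:
        return 1
    if p < 50.0:
        return 2
    return 3


def summarize_spot(
    grades: np.ndarray,
    compartment: str = "Nuclear",
    unit_mode: str = "nucleus",
) -> SpotQuantification:
    """Per-grade percentages Pᵢ = 100 · #(grade i) / #objects."""
    grades = np.asarray(grades, dtype=int)
    if grades.size == 0:
        raise ValueError("no scoreable objects")
    counts = np.bincount(grades, minlength=4)[:4]
    p = 100.0 * counts / grades.size
    return SpotQuantification(tuple(p), int(grades.size), unit_mode, compartment)


def compute_h_score(q: SpotQuantification) -> HScore:
    """H = P₁·1 + P₂·2 + P₃·3, in [0, 300]."""
    value = float(np.dot(q.P, np.arange(4)))
    return HScore(min(value, 300.0))


def score_spot(
    image: np.ndarray,
    mode: str = "nucleus",
    thresholds: tuple[float, float, float] = DEFAULT_INTENSITY_THRESHOLDS,
    delta: float = 0.0,
    compartment: str = "Nuclear",
) -> tuple[SpotQuantification, HScore]:
    """Full spot quantification: segment (or pool pixels), grade, summarize.

    ``mode="nucleus"`` grades connected objects; ``mode="pixel"`` grades
    every tissue pixel individually by the same intensity thresholds.
    """
    if mode == "nucleus":
        objects = segment_nuclei(image)
        grades = grade_objects(objects, image, thresholds)
    elif mode == "pixel":
        classes = classify_pixels(image, delta)
        img = _check_rgb(image)
        rb = (img[..., 0] - img[..., 2])[classes != PixelClass.BACKGROUND]
        grades = np.digitize(rb, list(thresholds), right=True)
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    q = summarize_spot(grades, compartment=compartment, unit_mode=mode)
    return q, compute_h_score(q)


def kruskal_wallis_concordance(
    manual_grades, h_scores
) -> tuple[float, float]:
    """Kruskal-Wallis rank test of H-scores across manual-grade groups.

    Verifies that the automated continuous score tracks the ordinal manual
    reading. Returns (H statistic with tie correction, chi-square p-value).
    """
    manual = np.asarray(manual_grades)
    scores = np.asarray(h_scores, dtype=float)
    if manual.shape != scores.shape:
        raise ValueError("manual_grades and h_scores must align")
    levels = np.unique(manual)
    if levels.size < 2:
        raise ValueError("need at least two distinct manual grade levels")
    groups = [scores[manual == g] for g in levels]
    if np.ptp(scores) == 0:
        # all scores tied: zero statistic by the tie-correction convention
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)
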