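"""Synthetic inputs for the TMA profiling pipeline, with full ground truth.

Three generators cover every input the pipeline consumes:

* :func:`generate_spot_image` — an immunohistochemistry spot rendered as an
  8-bit RGB array: hematoxylin-blue negative nuclei and DAB-brown positive
  nuclei at three intensity levels on a near-white background, plus a
  :class:`SpotTruth` record of every nucleus.
* :func:`generate_cohort_matrix` — a patients × location-specific-protein
  H-score matrix with two latent prognostic groups, planted differential
  features and MCAR missingness, plus a :class:`CohortTruth`.
* :func:`generate_survival` / :func:`generate_expression_dataset` — clinical
  records tied to the latent groups, and a gene-expression analog of the
  protein cohort for cross-platform validation.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse

__all__ = [
    "SpotTruth",
    "CohortTruth",
    "ClinicalRecord",
    "BACKGROUND_RGB",
    "HEMATOXYLIN_RGB",
    "DAB_RGB_BY_GRADE",
    "generate_spot_image",
    "generate_cohort_matrix",
    "generate_survival",
    "generate_expression_dataset",
    "clinical_to_frame",
]

# Color model: background near-white; hematoxylin blue (blue > red); DAB
# grades 1-3 at red-minus-blue margins 30, 70, 110 so the red>blue positivity
# rule and the default grading thresholds separate classes at default noise.
BACKGROUND_RGB = (240, 240, 240)
HEMATOXYLIN_RGB = (70, 70, 160)
DAB_RGB_BY_GRADE = {
    1: (140, 100, 110),  # weak: red - blue = 30
    2: (150, 95, 80),    # moderate: red - blue = 70
    3: (160, 85, 50),    # strong: red - blue = 110
}


@dataclass
class SpotTruth:
    """Ground truth for one synthetic spot.

    ``true_h_score`` is Σᵢ fractionᵢ·100·i over the realized per-grade
    nucleus fractions; it is ``None`` for an empty spot.
    """

    nucleus_centers: list[tuple[int, int]]
    nucleus_labels: list[int]
    positive_fraction_by_grade: tuple[float, float, float, float]
    true_h_score: float | None

    def __post_init__(self) -> None:
        f = np.asarray(self.positive_fraction_by_grade, dtype=float)
        if self.nucleus_labels:
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("grade fractions must be nonnegative and sum to 1")
            expected = float(np.dot(f, 100.0 * np.arange(4)))
            if self.true_h_score is None or abs(self.true_h_score - expected) > 1e-9:
                raise ValueError("true_h_score inconsistent with grade fractions")


@dataclass
class CohortTruth:
    """Latent structure planted in a synthetic patient cohort."""

    group_assignment: pd.Series          # per-patient label in {1, 2}; 1 = poor prognosis
    planted_features: set[str]
    effect_size: float                   # standardized mean difference magnitude
    feature_direction: dict[str, int]    # planted feature -> +1 (up in poor group) / -1
    survival_params: tuple[float, float] # per-group hazard rates (group 1, group 2)
    censor_rate: float

    def __post_init__(self) -> None:
        h1, h2 = self.survival_params
        if h1 < h2:
            raise ValueError("group 1 is poor-prognosis: its hazard must be >= group 2's")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class ClinicalRecord:
    """One patient's clinical row: survival outcome plus covariates."""

    patient_id: str
    time_months: float
    event: bool
    age: float
    sex: str
    kps: int
    resection: int    # 1 biopsy, 2 partial, 3 total
    ucsf_grade: int   # ordinal I-IV
    chemo: bool


# ---------------------------------------------------------------------------
# Spot images
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Apportion n nuclei over grades so counts/n tracks the fractions."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def generate_spot_image(
    n_nuclei: int,
    grade_fractions: tuple[float, float, float, float],
    noise_sd: float = 4.0,
    seed: int = 0,
    *,
    image_size: int | None = None,
    nucleus_radius: float = 5.0,
    radius_jitter: float = 1.0,
    min_gap: float = 3.0,
) -> tuple[np.ndarray, SpotTruth]:
    """Render a synthetic IHC spot and its ground truth.

    Nuclei are non-overlapping ellipses placed on a jittered grid; grade-0
    nuclei are hematoxylin blue, grades 1-3 DAB brown at increasing
    red-minus-blue margins. Gaussian pixel noise (``noise_sd`` gray levels)
    is truncated to [0, 255].

    Raises
    ------
    ValueError
        If the fractions do not sum to 1, or ``image_size`` is too small to
        pack ``n_nuclei`` non-overlapping nuclei.
    """
    fractions = np.asarray(grade_fractions, dtype=float)
    if fractions.shape != (4,) or np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("grade_fractions must be four nonnegative values summing to 1")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be nonnegative")

    rng = np.random.default_rng(seed)
    r_max = nucleus_radius + radius_jitter
    cell = int(np.ceil(2.0 * r_max + min_gap))

    if image_size is None:
        grid = max(1, int(np.ceil(np.sqrt(max(n_nuclei, 1)))))
        image_size = grid * cell + cell
    else:
        grid = (image_size - cell) // cell
        if n_nuclei > 0 and grid * grid < n_nuclei:
            raise ValueError(
                f"cannot pack {n_nuclei} nuclei of radius <= {r_max:.1f} with gap "
                f"{min_gap:.1f} into a {image_size}x{image_size} image "
                f"(density limit {grid * grid} nuclei)"
            )
        grid = max(1, grid)

    img = np.empty((image_size, image_size, 3), dtype=float)
    img[...] = BACKGROUND_RGB

    if n_nuclei == 0:
        noisy = _add_noise(img, noise_sd, rng)
        return noisy, SpotTruth([], [], (0.0, 0.0, 0.0, 0.0), None)

    counts = _largest_remainder_counts(fractions, n_nuclei)
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)

    # jittered-grid placement guarantees non-overlap
    slots = [(i, j) for i in range(grid) for j in range(grid)]
    chosen = rng.choice(len(slots), size=n_nuclei, replace=False)
    jitter_span = (cell - 2.0 * r_max) / 2.0

    centers: list[tuple[int, int]] = []
    for slot_idx, grade in zip(chosen, labels):
        gi, gj = slots[slot_idx]
        cy = (gi + 0.5) * cell + cell / 2.0 + rng.uniform(-jitter_span, jitter_span)
        cx = (gj + 0.5) * cell + cell / 2.0 + rng.uniform(-jitter_span, jitter_span)
        ry = nucleus_radius + rng.uniform(-radius_jitter, radius_jitter)
        rx = nucleus_radius + rng.uniform(-radius_jitter, radius_jitter)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(image_size, image_size))
        color = HEMATOXYLIN_RGB if grade == 0 else DAB_RGB_BY_GRADE[int(grade)]
        img[rr, cc] = color
        centers.append((int(round(cy)), int(round(cx))))

    noisy = _add_noise(img, noise_sd, rng)
    realized = counts / n_nuclei
    true_h = float(np.dot(realized, 100.0 * np.arange(4)))
    truth = SpotTruth(centers, [int(g) for g in labels], tuple(realized), true_h)
    return noisy, truth


def _add_noise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Cohort H-score matrix
# ---------------------------------------------------------------------------

_COMPARTMENTS = ("Nuclear", "Cytoplasm", "Membrane")

# Default per-group hazards reproduce the study medians of roughly 11.7 and
# 13.2 months under an exponential model (lambda = ln 2 / median).
DEFAULT_HAZARDS = (float(np.log(2) / 11.7), float(np.log(2) / 13.2))


def _default_feature_names(n_features: int) -> list[str]:
    return [
        f"P{i // 3 + 1:03d}_{_COMPARTMENTS[i % 3]}" for i in range(n_features)
    ]


def generate_cohort_matrix(
    n_patients: int = 56,
    n_features: int = 108,
    n_planted: int = 10,
    effect: float = 2.0,
    group_sizes: tuple[int, int] = (19, 37),
    missing_rate: float = 0.05,
    seed: int = 0,
    *,
    feature_names: list[str] | None = None,
    hazards: tuple[float, float] = DEFAULT_HAZARDS,
    censor_rate: float = 0.2,
    baseline_sd: float = 30.0,
    baseline_mu: np.ndarray | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a patients × features H-score matrix with planted structure.

    Non-planted features are drawn from a feature-specific baseline shared by
    both groups; each planted feature is shifted by ``effect`` standard
    deviations in the poor-prognosis group (direction random per feature).
    Values are clipped to the H-score range [0, 300]; missing entries are
    inserted completely at random at ``missing_rate``.

    Returns the matrix as a DataFrame (rows = patients, columns = features,
    NaN = missing) together with the :class:`CohortTruth`.
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative; direction is per-feature")
    if n_planted > n_features:
        raise ValueError("n_planted cannot exceed n_features")
    if sum(group_sizes) != n_patients:
        raise ValueError("group sizes must sum to n_patients")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    names = list(feature_names) if feature_names is not None else _default_feature_names(n_features)
    if len(names) != n_features or len(set(names)) != n_features:
        raise ValueError("feature_names must be unique and match n_features")

    patient_ids = [f"GBM{i + 1:03d}" for i in range(n_patients)]
    groups = np.concatenate([np.ones(group_sizes[0], int), np.full(group_sizes[1], 2)])
    rng.shuffle(groups)
    group_s = pd.Series(groups, index=patient_ids, name="group")

    # mid-range baselines keep the effect shift inside [0, 300] at default sd;
    # an explicit baseline_mu lets matched cohorts (e.g. tumor vs normal)
    # share feature-level means
    if baseline_mu is not None:
        mu = np.asarray(baseline_mu, dtype=float)
        if mu.shape != (n_features,):
            raise ValueError("baseline_mu must have one mean per feature")
    else:
        mu = rng.uniform(80.0, 200.0, size=n_features)
    values = rng.normal(mu, baseline_sd, size=(n_patients, n_features))

    planted_idx = rng.choice(n_features, size=n_planted, replace=False)
    directions = rng.choice([-1, 1], size=n_planted)
    poor = groups == 1
    for idx, sign in zip(planted_idx, directions):
        values[poor, idx] += sign * effect * baseline_sd

    values = np.clip(values, 0.0, 300.0)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan

    matrix = pd.DataFrame(values, index=patient_ids, columns=names)
    truth = CohortTruth(
        group_assignment=group_s,
        planted_features={names[i] for i in planted_idx},
        effect_size=effect,
        feature_direction={names[i]: int(s) for i, s in zip(planted_idx, directions)},
        survival_params=hazards,
        censor_rate=censor_rate,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival and clinical covariates
# ---------------------------------------------------------------------------

def generate_survival(truth: CohortTruth, seed: int = 0) -> list[ClinicalRecord]:
    """Draw survival outcomes and clinical covariates for a cohort.

    Event times are exponential with the patient's group hazard; censoring is
    an independent exponential chosen so the expected censored fraction
    equals ``truth.censor_rate``. Covariates are drawn from distributions
    typical of a glioblastoma cohort and are independent of group.
    """
    h1, h2 = truth.survival_params
    if h1 <= 0 or h2 <= 0:
        raise ValueError("per-group hazards must be positive")
    if truth.censor_rate >= 1.0:
        raise ValueError("censor_rate=1 leaves no events; downstream tests undefined")

    rng = np.random.default_rng(seed)
    records: list[ClinicalRecord] = []
    for pid, grp in truth.group_assignment.items():
        lam = h1 if grp == 1 else h2
        t_event = rng.exponential(1.0 / lam)
        if truth.censor_rate > 0:
            # exponential censoring at rate lam*c/(1-c) gives P(censored) = c
            lam_c = lam * truth.censor_rate / (1.0 - truth.censor_rate)
            t_cens = rng.exponential(1.0 / lam_c)
        else:
            t_cens = np.inf
        time = min(t_event, t_cens)
        records.append(
            ClinicalRecord(
                patient_id=str(pid),
                time_months=float(max(time, 1e-6)),
                event=bool(t_event <= t_cens),
                age=float(np.clip(rng.normal(54.0, 11.0), 18.0, 89.0)),
                sex=str(rng.choice(["M", "F"], p=[0.6, 0.4])),
                kps=int(rng.choice([50, 60, 70, 80, 90, 100], p=[0.05, 0.1, 0.2, 0.3, 0.25, 0.1])),
                resection=int(rng.choice([1, 2, 3], p=[0.02, 0.22, 0.76])),
                ucsf_grade=int(rng.choice([1, 2, 3, 4])),
                chemo=bool(rng.random() < 0.8),
            )
        )
    return records


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient id."""
    df = pd.DataFrame([vars(r) for r in records]).set_index("patient_id")
    return df


# ---------------------------------------------------------------------------
# Gene-expression analog
# ---------------------------------------------------------------------------

def generate_expression_dataset(
    truth: CohortTruth,
    n_genes: int = 500,
    seed: int = 0,
    *,
    marker_effect: float | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a gene-expression matrix mirroring the planted protein markers.

    Location-specific marker features of the same protein collapse to a
    single gene (``Myc_Cytoplasm`` and ``Myc_Nuclear`` → gene ``MYC``), so
    ten markers spanning nine proteins emit nine marker genes. Marker genes
    carry the same group structure as the planted features; the remaining
    genes are standard-normal noise.

    Returns (genes × patients DataFrame, marker feature → gene symbol map).
    """
    markers = sorted(truth.planted_features)
    proteins: list[str] = []
    gene_map: dict[str, str] = {}
    for m in markers:
        prot = m.rsplit("_", 1)[0]
        if prot not in proteins:
            proteins.append(prot)
        gene_map[m] = f"{prot.upper()}_GENE"
    marker_genes = [f"{p.upper()}_GENE" for p in proteins]
    if n_genes < len(marker_genes):
        raise ValueError("n_genes must be at least the number of marker genes")

    rng = np.random.default_rng(seed)
    effect = truth.effect_size if marker_effect is None else marker_effect
    patients = list(truth.group_assignment.index)
    poor = (truth.group_assignment == 1).to_numpy()

    gene_names = marker_genes + [f"GENE{i + 1:04d}" for i in range(n_genes - len(marker_genes))]
    values = rng.normal(0.0, 1.0, size=(n_genes, len(patients)))
    for gi, prot in enumerate(proteins):
        signs = [truth.feature_direction[m] for m in markers if m.rsplit("_", 1)[0] == prot]
        sign = 1 if sum(signs) >= 0 else -1
        values[gi, poor] += sign * effect
    expr = pd.DataFrame(values, index=gene_names, columns=patients)
    return expr, gene_map
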