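# Methods

`tmaprog` implements a protein-expression prognostic-profiling pipeline for
tissue-microarray (TMA) immunohistochemistry: continuous per-spot H-scores
are computed from stained images, assembled into a patients ×
location-specific-protein matrix, normalized, clustered into two prognostic
groups, mined for differential biomarkers, and validated both by supervised
classification and on a gene-expression analog. Every stage can be driven
end-to-end on synthetic data with known ground truth.

## H-score quantification

A DAB/hematoxylin-stained spot is summarized by

    H = Σᵢ Pᵢ · i,  i = 0, 1, 2, 3,   H ∈ [0, 300],

where `Pᵢ` is the percentage of scored units at intensity grade `i`
(0 negative, 1 weak, 2 moderate, 3 strong). Positivity follows the
colorimetric rule that DAB-brown pixels have red greater than blue, while
hematoxylin-blue counterstain has blue greater than red; pixels whose mean
channel exceeds 220 (of 255) are background. Nuclei are connected
components of the tissue mask (8-connectivity, minimum area 20 px), and an
object's grade is binned from its mean red-minus-blue margin with default
thresholds (10, 55, 90) — midpoints between the synthetic stain margins of
30/70/110 — with boundary values falling to the lower grade. A pixel mode
grades every tissue pixel by the same thresholds instead of segmenting.

Two grading conventions exist in practice and both are implemented:
object-intensity grading (the default above), and percent-positive binning
in which the spot's grade is read off the fraction of positive cells —
grade 0 for [0, 10)%, 1 for [10, 25)%, 2 for [25, 50)%, 3 for [50, 100]%.
Only the grade-1 interval is fixed by the published convention; the
flanking bins are this package's defaults, chosen to partition [0, 100]
with monotone, non-overlapping intervals. Agreement of the continuous
H-score with an ordinal manual reading is checked by a Kruskal–Wallis rank
test across manual-grade groups (tie-corrected; an all-tied input returns
H = 0, p = 1 by convention).

## Matrix construction and normalization

Each antibody is scored per annotated subcellular compartment, giving
features named `Protein_Compartment`. The packaged 78-antibody
glioblastoma panel expands to 108 features under reported localizations and
234 when every antibody is read in all three compartments; both modes are
exposed because group comparison across all compartments can reveal
mislocalization that the reported-only mode hides.

Patients are excluded when they miss strictly more than 15% of feature
values, are flagged recurrent, or lack clinical data. Quantile
normalization then forces every patient's observed H-score distribution
onto a common reference — the mean of per-rank sorted values across
patients — on the assumption that inter-patient distributional differences
are technical. Numerical choices: missing entries are excluded from the
quantile computation and stay missing (no distribution mass is fabricated);
ties within a patient receive the midpoint of the reference quantiles their
rank span covers (average-rank interpolation), which preserves within-
patient order and makes the transform idempotent to 1e-9; patients with
unequal observed counts are mapped through linear interpolation of the
reference at their own quantile positions. Remaining missing entries are
imputed with the feature median across patients only after normalization,
because downstream Euclidean clustering needs complete vectors.

## Clustering and survival analysis

Patients are clustered by agglomerative hierarchical clustering with
standard Euclidean distance and complete linkage (no additional feature
scaling beyond quantile normalization), and the tree is cut into k = 2
groups; labels are renumbered by first occurrence so the assignment is
deterministic and order-invariant up to the label swap. The group with the
smaller Kaplan–Meier median survival is marked poor-prognosis (restricted
mean as fallback when medians are unreached; an exact tie raises rather
than guessing). Group survival is compared with the log-rank test;
confounding is assessed with a multivariate Cox proportional-hazards model
over cluster membership, age ≥ 70, KPS ≥ 70, UCSF grade (ordinal) and
resection extent (ordinal), with constant covariates dropped. Tumor/normal
separability is tested by clustering the combined matrix and applying a
two-sided Fisher exact test to the cluster × tissue-type 2×2 table.

## Biomarker selection

Per-feature differential expression uses the classical pooled-variance
Student t-test (Welch behind a flag), two-sided, with
Benjamini–Hochberg step-up adjustment across all tested features of the
chosen family; selection tiers default to q < 0.05 and q < 0.01.
Direction is reported relative to the poor-prognosis group. Tumor-vs-
normal comparison reuses the same t/BH machinery (the choice of test for
this comparison is this package's assumption), and the mislocalization
screen flags proteins with at least one compartment increased and a
different compartment decreased.

## Supervised validation

A stratified split assigns round(⅔ × class size) patients per class
(rounding half up) to training; three classifier families are provided —
linear-kernel SVM, random forest (200 trees), and logistic regression on
standardized markers (the "GLM" reading of a binomial general linear
model). Sensitivity is the recall of the better-prognosis class. The ROC
curve is a threshold sweep over unique scores with ties advancing
diagonally, so the trapezoidal AUC equals the Mann–Whitney pair-counting
probability; this identity is enforced by test. Feature importance for
the logistic model is the absolute standardized coefficient (equivalent to
ranking by Wald z); with collinear informative features the ordering
between them is unstable. A single fixed-seed split is the default, and a
repeated-split mode exists because single-split estimates on ~56 patients
are high-variance.

## Gene-expression validation

Markers map many-to-one to gene symbols (compartment variants of one
protein collapse, so the packaged ten-marker panel yields nine genes; the
symbols in the default map are annotations chosen by this package).
Patients are embedded by classical (Torgerson) MDS of their pairwise
Euclidean distances over the marker genes — double-center the squared
distances, B = −½ J D² J, and scale the top-2 eigenvectors by √λ, clipping
negative eigenvalues with a warning — then split by k-means with k = 2
(25 restarts to remove initialization variance) and compared by
Kaplan–Meier/log-rank as before.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions used throughout the tests:

* **Spot images.** Non-overlapping elliptical nuclei (radius 5 ± 1 px) on
  a jittered grid; background (240, 240, 240), hematoxylin (70, 70, 160),
  and DAB grades 1–3 at red-minus-blue margins 30/70/110; Gaussian pixel
  noise (sd 4 gray levels) truncated to [0, 255]. Grade counts are
  apportioned by largest remainder so the recorded truth H-score equals
  the realized per-nucleus fractions exactly. The renderer guarantees the
  red>blue rule separates classes at default noise; it does not emulate
  histology texture, stain spectra, overlapping nuclei, or scanner
  artifacts, so perfect segmentation on synthetic spots does not imply
  comparable accuracy on scanned tissue.
* **Cohorts.** 56 patients × 108 features by default, latent groups of
  19/37, feature baselines uniform on [80, 200] with sd 30, ten planted
  features shifted by 2 pooled standard deviations in the poor group
  (random per-feature direction), values clipped to [0, 300], 5% missing
  completely at random. Real matrices have correlated features and
  informative missingness; the generator's independence assumptions make
  FDR calibration cleaner than reality.
* **Survival.** Exponential event times per group — the simplest model
  satisfying proportional hazards, so Cox recovery is well-posed — with
  default hazards ln 2 / 11.7 and ln 2 / 13.2 per month, matching the
  study-scale group medians of 11.7 and 13.2 months; independent
  exponential censoring calibrated to a 20% censored fraction. Power
  checks that need a detectable gap use hazard ratio 3 explicitly.
  Clinical covariates are drawn independently of group.
* **Gene expression.** Marker genes inherit the planted group structure
  (standard-normal noise elsewhere); compartment variants collapse to one
  gene, reproducing the ten-markers → nine-genes structure.

## Problem sizes in the test and acceptance runs

Simulation-backed checks use the study-scale cohort (56 × 108, groups
19/37) with 50 seeds for marker recovery, 200 replicates for log-rank
power at hazard ratio 3, 100 replicates for Cox recovery at n = 200, 100
rendered spots (60 nuclei each) for H-score recovery, and 10⁴ label
permutations for the log-rank oracle. These sizes give Monte-Carlo error
comfortably below the asserted margins while keeping the default run fast.

## Known limitations

Compartment assignment on synthetic data comes from the annotation table,
not from subcellular segmentation; color deconvolution by stain-vector
unmixing is not implemented; clustering k is fixed at 2; probe-level
microarray preprocessing is out of scope (the validation stage consumes an
already-normalized gene × patient matrix). On the default full-matrix
conditions (10 informative of 108 features, effect 2), Euclidean
complete-linkage clustering on all features recovers the latent groups
only partially — the informative signal is diluted by the null features —
which is precisely why the pipeline re-clusters on the selected marker
panel for validation.
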