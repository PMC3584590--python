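"""Unsupervised two-group patient classification and survival comparison.

Patients are clustered on their normalized H-score profiles by agglomerative
hierarchical clustering (standard Euclidean distance, complete linkage) and
the tree is cut into two groups. Group survival is compared with the
Kaplan-Meier product-limit estimator and the log-rank test; confounding by
clinical covariates is assessed with a multivariate Cox proportional-hazards
model. A Fisher exact test checks that clustering the combined tumor+normal
matrix separates tissue types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterAssignment",
    "SurvivalComparison",
    "hierarchical_cluster",
    "km_estimate",
    "logrank_test",
    "cox_multivariate",
    "fisher_exact_2x2",
    "assign_prognosis_labels",
    "tumor_normal_separation",
    "compare_group_survival",
    "plot_km_curves",
]


@dataclass
class ClusterAssignment:
    """Two-group patient partition from the hierarchical tree."""

    labels: pd.Series                    # per-patient label in {1, 2}
    linkage_tree: np.ndarray             # scipy linkage matrix (merge history)
    poor_prognosis_label: int | None = None


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves and log-rank comparison of two patient groups."""

    km_curves: dict[int, pd.DataFrame]   # label -> step table (time, survival)
    median_survival: dict[int, float]    # label -> median (nan if not reached)
    logrank_chi2: float
    p_value: float


def hierarchical_cluster(matrix: pd.DataFrame, k: int = 2) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering of patients, cut into k groups.

    Labels are renumbered 1..k in order of first appearance in the input,
    which makes the assignment deterministic and invariant (up to the label
    permutation) to patient order.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("clustering requires a complete (imputed) matrix")
    if matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} patients, got {matrix.shape[0]}")
    tree = linkage(matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # renumber by first occurrence for a stable, order-derived labeling
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return ClusterAssignment(pd.Series(labels, index=matrix.index, name="cluster"), tree)


def km_estimate(times, events) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier product-limit curve and median survival.

    The median is the earliest time with S(t) ≤ 0.5 and is ``nan`` when the
    curve never reaches 0.5. Ties between events and censorings at the same
    time follow the standard risk-set convention (events first).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return curve, median


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test (observed minus expected events, 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    if labs.size != 2:
        raise ValueError(f"log-rank needs exactly two nonempty groups, got {labs.size}")
    a = groups == labs[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    clinical: pd.DataFrame,
    labels: pd.Series,
    *,
    age_cut: float = 70.0,
    kps_cut: float = 70.0,
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit of survival on cluster and
    clinical covariates.

    Covariates: cluster membership (indicator of the second cluster), age
    dichotomized at ``age_cut`` years, KPS dichotomized at ``kps_cut``,
    UCSF grade (ordinal I-IV) and resection extent (ordinal). Constant
    covariates are dropped with a warning. Returns one row per covariate
    with hazard ratio, 95% CI and p-value.
    """
    df = pd.DataFrame(index=clinical.index)
    df["cluster2"] = (labels.reindex(clinical.index) == 2).astype(float)
    df["age_ge_cut"] = (clinical["age"] >= age_cut).astype(float)
    if "kps" in clinical:
        df["kps_ge_cut"] = (clinical["kps"] >= kps_cut).astype(float)
    if "ucsf_grade" in clinical:
        df["ucsf_grade"] = clinical["ucsf_grade"].astype(float)
    if "resection" in clinical:
        df["resection"] = clinical["resection"].astype(float)

    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariates: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    if df.shape[1] == 0:
        raise ValueError("no non-constant covariates to fit")
    n_events = int(clinical["event"].sum())
    if n_events < df.shape[1]:
        raise ValueError("fewer events than covariates; Cox fit not identifiable")

    df["time"] = clinical["time_months"].astype(float)
    df["event"] = clinical["event"].astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    out = pd.DataFrame(
        {
            "hazard_ratio": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p": cph.summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(int)
        if np.any(t_int != t) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t_int
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def _restricted_mean(curve: pd.DataFrame) -> float:
    t = curve["time"].to_numpy()
    s = curve["survival"].to_numpy()
    return float(np.trapezoid(s, t))


def assign_prognosis_labels(
    assignment: ClusterAssignment, times, events
) -> ClusterAssignment:
    """Mark the cluster with shorter survival as the poor-prognosis group.

    Smaller Kaplan-Meier median wins; if either median is undefined the
    restricted mean (area under the KM curve) breaks the comparison. An
    exact tie raises, demanding a manual choice.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = assignment.labels.to_numpy()
    stat: dict[int, float] = {}
    for lab in (1, 2):
        mask = labels == lab
        if mask.sum() == 0:
            raise ValueError(f"cluster {lab} is empty")
        curve, median = km_estimate(times[mask], events[mask])
        stat[lab] = median if not np.isnan(median) else np.inf
    if np.isinf(stat[1]) and np.isinf(stat[2]) or stat[1] == stat[2]:
        # medians unavailable or tied: fall back to restricted means
        for lab in (1, 2):
            mask = labels == lab
            curve, _ = km_estimate(times[mask], events[mask])
            stat[lab] = _restricted_mean(curve)
        if stat[1] == stat[2]:
            raise ValueError("clusters have identical survival; choose the poor group manually")
    poor = 1 if stat[1] < stat[2] else 2
    return ClusterAssignment(assignment.labels, assignment.linkage_tree, poor)


def tumor_normal_separation(
    combined_matrix: pd.DataFrame, tissue_type: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Cluster the combined tumor+normal matrix and test the cluster ×
    tissue-type cross-tabulation with Fisher's exact test."""
    assignment = hierarchical_cluster(combined_matrix, k=2)
    tab = pd.crosstab(assignment.labels, tissue_type.reindex(combined_matrix.index))
    if tab.shape != (2, 2):
        raise ValueError("need two clusters and two tissue types for the 2x2 test")
    return fisher_exact_2x2(tab.to_numpy()), tab


def plot_km_curves(comparison: SurvivalComparison, path) -> None:
    """Write the per-group Kaplan-Meier step curves to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, curve in sorted(comparison.km_curves.items()):
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"cluster {lab}")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"log-rank p = {comparison.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_group_survival(times, events, groups) -> SurvivalComparison:
    """KM curves, medians and log-rank comparison for a two-group labeling."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    curves: dict[int, pd.DataFrame] = {}
    medians: dict[int, float] = {}
    for lab in labs:
        mask = groups == lab
        curves[int(lab)], medians[int(lab)] = km_estimate(times[mask], events[mask])
    chi2, p = logrank_test(times, events, groups)
    return SurvivalComparison(curves, medians, chi2, p)
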