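"""Differential-expression biomarker selection between prognostic groups.

Features separating the two survival clusters are found with a per-feature
two-sample Student t-test (pooled variance; Welch available behind a flag)
followed by Benjamini-Hochberg step-up FDR adjustment across the tested
family. Direction is reported relative to the poor-prognosis
(chemo-radiation-resistant) group. The same machinery compares tumor
against normal tissue, and a mislocalization screen flags proteins whose
signal rises in one compartment while falling in another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomarkerResult",
    "t_test_per_feature",
    "bh_adjust",
    "select_biomarkers",
    "tumor_vs_normal",
    "detect_mislocalized",
]


@dataclass
class BiomarkerResult:
    feature: str
    t_stat: float
    p_raw: float
    q_value: float
    direction: str  # "Up" / "Down" in the poor-prognosis group


def t_test_per_feature(
    matrix: pd.DataFrame,
    labels: pd.Series,
    poor_label: int = 1,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test for every feature, poor vs good group.

    Missing values are dropped per feature; a feature with fewer than two
    observed values in either group is reported untested (NaN statistics).
    Zero pooled variance with equal means yields t=0, p=1 with a warning.

    Returns a DataFrame indexed by feature with columns
    ``t``, ``p``, ``mean_poor``, ``mean_good``, ``tested``.
    """
    labels = labels.reindex(matrix.index)
    poor = (labels == poor_label).to_numpy()
    good = ~poor & labels.notna().to_numpy()
    rows = []
    for feat in matrix.columns:
        col = matrix[feat].to_numpy(dtype=float)
        x = col[poor]
        y = col[good]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, False))
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"feature {feat}: zero variance; p set to 1", stacklevel=2)
            rows.append((feat, 0.0, 1.0, float(x.mean()), float(y.mean()), True))
            continue
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
        rows.append((feat, float(t), float(p), float(x.mean()), float(y.mean()), True))
    return pd.DataFrame(
        rows, columns=["feature", "t", "p", "mean_poor", "mean_good", "tested"]
    ).set_index("feature")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_biomarkers(
    ttest: pd.DataFrame, q_cut: float = 0.05
) -> list[BiomarkerResult]:
    """Features with BH q-value below ``q_cut``, with direction labels.

    Direction is "Up" when the poor-prognosis group mean exceeds the good
    group mean, else "Down". BH is applied across all tested features of
    the supplied family; untested features are excluded from the family.
    """
    if not 0.0 < q_cut < 1.0:
        raise ValueError("q_cut must lie in (0, 1)")
    tested = ttest[ttest["tested"].astype(bool)]
    if tested.empty:
        return []
    q = bh_adjust(tested["p"].to_numpy())
    out = []
    for (feat, row), qv in zip(tested.iterrows(), q):
        if qv < q_cut:
            direction = "Up" if row["mean_poor"] > row["mean_good"] else "Down"
            out.append(BiomarkerResult(feat, row["t"], row["p"], float(qv), direction))
    out.sort(key=lambda r: r.q_value)
    return out


def tumor_vs_normal(
    matrix_tumor: pd.DataFrame,
    matrix_normal: pd.DataFrame,
    q_cut: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Features significantly increased / decreased in tumor vs normal.

    Per-feature Student t-test with BH adjustment across all compared
    features, partitioned by sign of the tumor-minus-normal difference.
    """
    if matrix_normal.shape[0] < 2:
        raise ValueError("need at least two normal samples")
    common = [c for c in matrix_tumor.columns if c in matrix_normal.columns]
    stacked = pd.concat([matrix_tumor[common], matrix_normal[common]])
    labels = pd.Series(
        [1] * matrix_tumor.shape[0] + [2] * matrix_normal.shape[0], index=stacked.index
    )
    res = t_test_per_feature(stacked, labels, poor_label=1)
    selected = select_biomarkers(res, q_cut)
    increased = [r.feature for r in selected if r.direction == "Up"]
    decreased = [r.feature for r in selected if r.direction == "Down"]
    return increased, decreased


def _split_feature(name: str) -> tuple[str, str]:
    if "_" not in name:
        raise ValueError(f"feature name {name!r} does not parse as Protein_Compartment")
    prot, comp = name.rsplit("_", 1)
    if not prot or not comp:
        raise ValueError(f"feature name {name!r} does not parse as Protein_Compartment")
    return prot, comp


def detect_mislocalized(increased, decreased) -> list[str]:
    """Proteins increased in one compartment and decreased in another.

    The classic pattern is cytoplasmic gain with nuclear loss of the same
    protein, suggesting aberrant subcellular localization in tumor tissue.
    """
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for name in increased:
        prot, comp = _split_feature(name)
        up.setdefault(prot, set()).add(comp)
    for name in decreased:
        prot, comp = _split_feature(name)
        down.setdefault(prot, set()).add(comp)
    flagged = [
        prot
        for prot in sorted(set(up) & set(down))
        if (up[prot] - down[prot]) and (down[prot] - up[prot])
    ]
    return flagged
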