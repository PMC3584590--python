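"""Build and normalize the patients × location-specific-feature matrix.

Each antibody is scored separately in each annotated subcellular compartment
(nucleus, cytoplasm, membrane), giving "location-specific" features named
``Protein_Compartment`` (e.g. ``p16_Nuclear``). The packaged antibody panel
of 78 antibodies expands to 108 such features under its reported
localizations, or 234 when every antibody is read in all three compartments.

Patient-level exclusion rules (excess missingness, recurrent tumors, absent
clinical data) are applied before quantile normalization, which forces every
patient's H-score distribution onto a common reference — the mean of the
per-rank values across patients — on the assumption that inter-patient
distributional differences are technical rather than biological.
"""

from __future__ import annotations

import importlib.resources
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENT_NAMES",
    "load_antibody_panel",
    "expand_localized_features",
    "apply_exclusions",
    "quantile_normalize",
    "impute_missing",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

COMPARTMENT_NAMES = {"N": "Nuclear", "C": "Cytoplasm", "M": "Membrane"}
_COMPARTMENT_ORDER = ("N", "C", "M")


def load_antibody_panel(path=None) -> pd.DataFrame:
    """Load the antibody panel table (code, antibody, localization, observed).

    Without ``path`` the packaged 78-antibody glioblastoma panel is used.
    """
    if path is None:
        ref = importlib.resources.files("tmaprog.data") / "antibodies.tsv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def _sanitize(name: str) -> str:
    """Protein display name -> feature-name token (no separators)."""
    out = []
    for ch in str(name).strip():
        if ch.isalnum() or ch in "-.":
            out.append(ch)
        elif ch in " /":
            continue
        # parentheses and other punctuation dropped
    return "".join(out)


def expand_localized_features(panel: pd.DataFrame, mode: str = "reported") -> list[str]:
    """Expand an antibody panel into location-specific feature names.

    ``mode="reported"`` emits one ``Protein_Compartment`` feature per
    annotated (protein, compartment) pair; ``mode="all"`` emits all three
    compartments for every protein. Feature names are guaranteed unique
    (the antibody code is appended on a name collision).
    """
    if mode not in ("reported", "all"):
        raise ValueError(f"mode must be 'reported' or 'all', got {mode!r}")
    tokens: list[str] = []
    seen: dict[str, str] = {}
    for _, row in panel.iterrows():
        tok = _sanitize(row["antibody"])
        if tok in seen.values():
            tok = f"{tok}{row['code']}"
        seen[row["code"]] = tok
        tokens.append(tok)

    features: list[str] = []
    for (_, row), tok in zip(panel.iterrows(), tokens):
        if mode == "all":
            codes = _COMPARTMENT_ORDER
        else:
            codes = tuple(c.strip() for c in str(row["localization"]).split(","))
            if not codes or any(c not in COMPARTMENT_NAMES for c in codes):
                raise ValueError(
                    f"unknown localization code in {row['localization']!r} for {row['code']}"
                )
        for c in codes:
            features.append(f"{tok}_{COMPARTMENT_NAMES[c]}")
    if len(set(features)) != len(features):
        raise ValueError("feature names are not unique after expansion")
    return features


def apply_exclusions(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    recurrent: pd.Series | None = None,
    missing_threshold: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop patients failing any exclusion rule; report counts per rule.

    Rules: (i) missing strictly more than ``missing_threshold`` of the
    feature values, (ii) flagged recurrent, (iii) no clinical record.
    A patient missing exactly the threshold fraction is retained.
    """
    frac_missing = matrix.isna().mean(axis=1)
    rule_missing = frac_missing > missing_threshold
    rule_recurrent = (
        recurrent.reindex(matrix.index).fillna(False).astype(bool)
        if recurrent is not None
        else pd.Series(False, index=matrix.index)
    )
    rule_no_clinical = ~matrix.index.isin(clinical.index)
    drop = rule_missing | rule_recurrent | rule_no_clinical
    report = {
        "excess_missing": int(rule_missing.sum()),
        "recurrent": int(rule_recurrent.sum()),
        "no_clinical_data": int(rule_no_clinical.sum()),
        "excluded_total": int(drop.sum()),
        "retained": int((~drop).sum()),
    }
    kept = matrix.loc[~drop]
    if kept.empty:
        raise ValueError("no patients survive exclusion")
    return kept, report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every patient's observed H-score distribution onto the mean
    per-rank reference.

    Missing entries are excluded from the quantile computation and remain
    missing afterwards. Ties within a patient receive the mean of the
    reference quantiles they span, so within-patient rank order is
    preserved and the transform is idempotent. Patients with unequal
    observed counts are mapped through linear interpolation of the
    reference at their own quantile positions.
    """
    if matrix.shape[0] < 2:
        raise ValueError("quantile normalization needs at least two patients")
    counts = matrix.notna().sum(axis=1)
    if (counts == 0).any():
        bad = counts.index[counts == 0].tolist()
        raise ValueError(f"patients with all values missing: {bad}")
    if (counts < 2).any():
        raise ValueError("every patient needs at least two observed values")

    n_ref = int(counts.max())
    ref_grid = np.arange(n_ref) / (n_ref - 1)

    # reference = mean across patients of per-rank sorted values, each
    # patient's sorted vector interpolated onto the common rank grid
    acc = np.zeros(n_ref)
    for _, row in matrix.iterrows():
        obs = np.sort(row.dropna().to_numpy(dtype=float))
        grid = np.arange(obs.size) / max(obs.size - 1, 1)
        acc += np.interp(ref_grid, grid, obs)
    reference = acc / matrix.shape[0]

    out = matrix.copy().astype(float)
    for pid, row in matrix.iterrows():
        obs_mask = row.notna().to_numpy()
        obs = row.to_numpy(dtype=float)[obs_mask]
        m = obs.size
        # average ranks handle ties: tied values share the midpoint of the
        # reference quantiles their rank span covers
        avg = pd.Series(obs).rank(method="average").to_numpy() - 1.0
        pos = avg / max(m - 1, 1)
        newvals = np.interp(pos, ref_grid, reference)
        full = np.full(row.size, np.nan)
        full[obs_mask] = newvals
        out.loc[pid] = full
    return out


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the feature's median across patients."""
    all_missing = matrix.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"features missing in all patients: {matrix.columns[all_missing].tolist()}"
        )
    n = int(matrix.isna().to_numpy().sum())
    if n:
        warnings.warn(f"imputing {n} missing entries with feature medians", stacklevel=2)
    return matrix.fillna(matrix.median(axis=0))


def read_matrix_tsv(path) -> pd.DataFrame:
    """Patients × features TSV with 'NA' for missing."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")
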