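"""Cross-platform validation of protein markers on gene-expression data.

The selected location-specific protein markers are mapped (many-to-one) to
gene symbols, patients are embedded by classical multidimensional scaling of
their pairwise Euclidean distances over the marker genes, split into two
groups by k-means (k=2), and the groups' survival is compared exactly as in
the clustering stage. Because compartment variants of one protein collapse
to a single gene, ten markers spanning nine proteins yield nine genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .prognostic_clustering import SurvivalComparison, compare_group_survival

__all__ = [
    "DEFAULT_GENE_MAP",
    "map_markers_to_genes",
    "gene_distance_matrix",
    "classical_mds",
    "kmeans_two",
    "validate_survival",
    "read_gene_map_tsv",
]

# Packaged marker -> gene map for the ten-marker prognostic panel; the two
# p16 compartment features collapse to CDKN2A, giving nine genes. The gene
# symbols are this package's annotations of the marker proteins.
DEFAULT_GENE_MAP = {
    "CyclinESC-198_Nuclear": "CCNE1",
    "DCC_Nuclear": "DCC",
    "Survivin_Nuclear": "BIRC5",
    "TGF-b_Cytoplasm": "TGFB1",
    "CDC25B_Nuclear": "CDC25B",
    "HistoneH1B419_Nuclear": "HIST1H1C",
    "p-EGFRTyr1173_Cytoplasm": "EGFR",
    "p-VEGFR23_Cytoplasm": "KDR",
    "p16_Cytoplasm": "CDKN2A",
    "p16_Nuclear": "CDKN2A",
}


def map_markers_to_genes(markers, gene_map: dict[str, str] | None = None) -> list[str]:
    """Map marker features to a deduplicated, order-stable gene list."""
    gene_map = DEFAULT_GENE_MAP if gene_map is None else gene_map
    genes: list[str] = []
    for m in markers:
        if m not in gene_map:
            raise KeyError(f"marker {m!r} is absent from the gene map")
        g = gene_map[m]
        if g not in genes:
            genes.append(g)
    return genes


def gene_distance_matrix(expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Pairwise Euclidean distances between patients over a gene subset.

    ``expr`` is genes × patients. Returns a symmetric patients × patients
    DataFrame with zero diagonal.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing}")
    X = expr.loc[genes].to_numpy(dtype=float).T  # patients × genes
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=expr.columns, columns=expr.columns)


def classical_mds(distance: pd.DataFrame | np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, B = −½ J D² J, and embeds
    points on the top ``dim`` eigenvectors scaled by the square roots of
    their eigenvalues. Negative eigenvalues among the top ``dim`` (distances
    not realizable in Euclidean space) are clipped to zero with a warning.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1][:dim]
    lam = eigval[idx]
    if np.any(lam < -1e-10 * max(abs(eigval).max(), 1.0)):
        warnings.warn("negative eigenvalues clipped in classical MDS", stacklevel=2)
    lam = np.clip(lam, 0.0, None)
    return eigvec[:, idx] * np.sqrt(lam)


def kmeans_two(coords: np.ndarray, seed: int = 0, restarts: int = 25) -> np.ndarray:
    """k-means with k=2, best of ``restarts`` initializations.

    Deterministic given the seed; labels are in {1, 2} with label 1 for the
    cluster containing the first point.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if np.ptp(coords, axis=0).max() == 0:
        raise ValueError("all points identical; k-means with k=2 undefined")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    raw = km.fit_predict(coords)
    labels = np.where(raw == raw[0], 1, 2)
    return labels


def validate_survival(labels, times, events) -> SurvivalComparison:
    """Survival comparison of the two expression-derived groups."""
    return compare_group_survival(times, events, labels)


def read_gene_map_tsv(path) -> dict[str, str]:
    """Two-column TSV (marker, gene) -> mapping dict."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
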