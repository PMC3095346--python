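"""Sample clustering: does the transcriptome split paternal vs maternal?

Expression profiles (one column per cross per platform, 11 in the full
design) are variance-filtered, converted to a pairwise dissimilarity
(Pearson correlation distance by default, with covariance and cosine
variants as robustness checks), and agglomerated with complete linkage.
The depth-1 bipartition of the dendrogram is the headline result: with
the planted structure it separates the paternalized samples (2xX4x,
2xX6x, fis1X2x) from the maternalized ones (4xX2x, 6xX2x, msi1).  A PCA
of the samples on the covariance metric serves as a cross-check.

Raw covariance is a similarity, so its 'distance' is the standard
rescaling max_pairwise_cov - cov(x, y); columns are sorted
lexicographically before agglomeration, which makes the tree
independent of input column order.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

METRICS = ("pearson", "covariance", "cosine")


def build_profile_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Genes x samples matrix of averaged pSLR/SLR values.

    Column labels are ``<cross>_affy`` / ``<cross>_agilent``; crosses
    without Agilent data contribute an Affymetrix column only.  Genes
    missing a value in any retained column are dropped.
    """
    affy = summary.pivot(index="at_id", columns="cross", values="avg_pslr")
    affy.columns = [f"{c}_affy" for c in affy.columns]
    agil = summary.pivot(index="at_id", columns="cross", values="avg_slr_agilent")
    agil = agil.dropna(axis=1, how="all")
    agil.columns = [f"{c}_agilent" for c in agil.columns]
    mat = pd.concat([affy, agil], axis=1).dropna(axis=0)
    return mat[sorted(mat.columns)]


def variance_filter(matrix: pd.DataFrame, keep_fraction: float = 0.5) -> pd.DataFrame:
    """Keep the ceil(keep_fraction * n) genes with highest across-sample
    variance (population variance; ties broken by row order, stably)."""
    if matrix.empty:
        raise ValueError("empty profile matrix")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n_keep = math.ceil(keep_fraction * len(matrix))
    var = matrix.var(axis=1, ddof=0).to_numpy()
    order = np.argsort(-var, kind="stable")[:n_keep]
    return matrix.iloc[np.sort(order)]


def sample_distance(x, y, metric: str = "pearson", cov_offset: float = 0.0) -> float:
    """Dissimilarity between two sample profiles.

    pearson: 1 - r; cosine: 1 - cos; covariance: cov_offset - cov(x, y)
    (pass the maximum pairwise covariance of the dataset as the offset —
    :func:`distance_matrix` does this automatically).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("profiles must share a length of at least 2")
    if metric == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("Pearson distance undefined for a constant profile")
        return float(1.0 - np.corrcoef(x, y)[0, 1])
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("cosine distance undefined for a zero profile")
        return float(1.0 - x.dot(y) / (nx * ny))
    if metric == "covariance":
        return float(cov_offset - np.cov(x, y, ddof=1)[0, 1])
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def distance_matrix(matrix: pd.DataFrame, metric: str = "pearson") -> pd.DataFrame:
    """Pairwise sample dissimilarities over the columns of ``matrix``."""
    cols = list(matrix.columns)
    n = len(cols)
    cov_offset = 0.0
    if metric == "covariance":
        c = np.cov(matrix.to_numpy().T, ddof=1)
        cov_offset = float(c[~np.eye(n, dtype=bool)].max()) if n > 1 else 0.0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sample_distance(
                matrix.iloc[:, i], matrix.iloc[:, j], metric, cov_offset
            )
    return pd.DataFrame(d, index=cols, columns=cols)


class Dendrogram:
    """Complete-linkage sample tree with ultrametric merge heights."""

    def __init__(self, linkage: np.ndarray, labels: list[str]):
        self.linkage = linkage
        self.labels = labels
        self._tree = hierarchy.to_tree(linkage)

    def _leaf_labels(self, node) -> frozenset[str]:
        return frozenset(self.labels[i] for i in node.pre_order())

    def depth1_bipartition(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf sets of the root's two children."""
        left = self._leaf_labels(self._tree.get_left())
        right = self._leaf_labels(self._tree.get_right())
        return (left, right) if sorted(left)[0] < sorted(right)[0] else (right, left)

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(
                render(c, node.dist) for c in (node.get_left(), node.get_right())
            )
            return f"({inner}):{length:.6g}"

        root = self._tree
        inner = ",".join(
            render(c, root.dist) for c in (root.get_left(), root.get_right())
        )
        return f"({inner});"


def hierarchical_cluster(matrix: pd.DataFrame, metric: str = "pearson") -> Dendrogram:
    """Agglomerative complete-linkage clustering of the sample columns."""
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    matrix = matrix[sorted(matrix.columns)]
    dm = distance_matrix(matrix, metric)
    condensed = squareform(dm.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(linkage, list(matrix.columns))


def principal_components(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components (covariance PCA).

    Columns of ``matrix`` are samples; genes are centred, and each
    component's sign is fixed so its largest-magnitude score is positive.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if scores[np.abs(scores[:, j]).argmax(), j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
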