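"""PCA comprehensive-score quality ranking and hierarchical clustering.

Batch quality is ranked by correlation-matrix PCA of the aligned peak-area
matrix: principal components with eigenvalue above a threshold (0.99 by
default, the usual "eigenvalue about 1" rule on a correlation matrix) are
retained, and each batch's comprehensive score is the variance-contribution-
weighted sum of its retained PC scores.  Higher score = better quality.
Hierarchical cluster analysis (Ward/Euclidean on the autoscaled matrix by
default) groups batches, typically by geographic origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import DataError, DegenerateColumnError, ParameterError
from .fingerprint import FingerprintMatrix


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, FingerprintMatrix):
        return np.asarray(m.areas, dtype=float)
    return np.asarray(m, dtype=float)


def autoscale(m) -> np.ndarray:
    """Standardize each column to mean 0, sd 1 (sample sd, n-1)."""
    X = _as_matrix(m)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("autoscale needs a 2-D matrix with at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise DegenerateColumnError(
            f"zero-variance column(s) {zero.tolist()} cannot be autoscaled"
        )
    return (X - X.mean(axis=0)) / sd


@dataclass
class PCAResult:
    eigenvalues: np.ndarray            # descending
    variance_contribution: np.ndarray  # fractions summing to 1
    loadings: np.ndarray               # variables x PCs
    scores: np.ndarray                 # samples x PCs
    retained: int
    eigen_threshold: float


def pca(standardized: np.ndarray, eigen_threshold: float = 0.99) -> PCAResult:
    """Eigendecomposition of the correlation matrix of autoscaled data.

    Scores are the standardized data projected on the loadings.  PCs whose
    eigenvalue exceeds ``eigen_threshold`` are retained for scoring.  Each
    loading vector is oriented so its largest-magnitude element is positive,
    making score signs reproducible across linear-algebra backends.
    """
    X = np.asarray(standardized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("pca needs at least 2 samples")
    if eigen_threshold <= 0:
        raise ParameterError("eigen_threshold must be > 0")
    n = X.shape[0]
    corr = X.T @ X / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    contrib = eigval / eigval.sum()
    scores = X @ eigvec
    retained = int(np.sum(eigval > eigen_threshold))
    return PCAResult(eigval, contrib, eigvec, scores, retained, eigen_threshold)


def comprehensive_scores(
    p: PCAResult,
    sample_ids: list[str] | None = None,
    weights: str = "renormalized",
) -> pd.DataFrame:
    """Quality ranking from variance-contribution-weighted PC scores.

    ``weights="renormalized"`` (default) uses w_k = contribution_k / sum of
    contributions over the retained PCs; ``weights="raw"`` uses the raw
    contribution fractions.  Rank 1 is the highest comprehensive score; ties
    are broken by sample id for determinism.
    """
    if p.retained < 1:
        raise DataError("no principal components retained")
    if weights not in ("renormalized", "raw"):
        raise ParameterError(f"unknown weights option {weights!r}")
    k = p.retained
    w = p.variance_contribution[:k].copy()
    if weights == "renormalized":
        w = w / w.sum()
    comp = p.scores[:, :k] @ w
    n = p.scores.shape[0]
    ids = sample_ids if sample_ids is not None else [f"S{i+1}" for i in range(n)]
    df = pd.DataFrame(
        p.scores[:, :k], columns=[f"PC{j+1}" for j in range(k)], index=ids
    )
    df["comprehensive_score"] = comp
    order = sorted(range(n), key=lambda i: (-comp[i], ids[i]))
    rank = np.empty(n, dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    df["rank"] = rank
    df.index.name = "sample_id"
    return df


_LINKAGES = {"ward", "single", "complete", "average", "centroid", "median", "weighted"}
_METRICS = {"euclidean", "cityblock", "cosine", "correlation", "chebyshev"}


@dataclass
class HCAResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]

    def flat_labels(self, k: int) -> np.ndarray:
        """Cluster labels from cutting the merge tree into k groups."""
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hca(
    standardized: np.ndarray,
    linkage: str = "ward",
    metric: str = "euclidean",
    sample_ids: list[str] | None = None,
) -> HCAResult:
    """Agglomerative clustering of samples on the autoscaled matrix."""
    X = np.asarray(standardized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("hca needs at least 2 samples")
    if linkage not in _LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    if metric not in _METRICS:
        raise ParameterError(f"unknown metric {metric!r}")
    if linkage in ("ward", "centroid", "median") and metric != "euclidean":
        raise ParameterError(f"{linkage} linkage requires the euclidean metric")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    ids = sample_ids if sample_ids is not None else [f"S{i+1}" for i in range(X.shape[0])]
    return HCAResult(Z, list(ids))


def label_agreement(labels_a, labels_b) -> float:
    """Fraction of sample pairs on which two clusterings agree (Rand index)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise DataError("label vectors must have equal length")
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))
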