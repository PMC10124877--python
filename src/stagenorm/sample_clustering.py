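"""Sample clustering on module-gene profiles.

Advanced-stage samples are clustered by the cosine distance between
their expression profiles restricted to module genes, agglomerated with
Ward's method, and the number of clusters k is chosen by maximal
average silhouette width over a candidate range.  Cosine distance makes
the clustering invariant to per-sample positive rescaling, so overall
expression level does not drive the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score


@dataclass
class ClusterAssignment:
    """Sample-to-cluster map at the silhouette-selected k."""

    labels: pd.Series  # sample_id -> cluster index (1..k)
    k: int
    silhouette_by_k: dict[int, float]
    linkage_matrix: np.ndarray

    def cluster_of(self, sample_id: str) -> int:
        return int(self.labels[sample_id])

    def samples_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def cosine_distance_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distances between sample columns.

    d(u, v) = 1 - u.v / (|u||v|); symmetric, zero diagonal, range [0,2].
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [s for s, nz in zip(expr.columns, norms) if nz == 0]
        raise ValueError(f"zero-norm sample profiles: {bad[:5]}")
    sim = (X @ X.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def ward_tree(distances: pd.DataFrame) -> np.ndarray:
    """Ward agglomeration of a precomputed distance matrix.

    Uses the Lance-Williams recurrence on the given distances (the
    squared-distance dialect), deterministic with index-order
    tie-breaking.
    """
    d = distances.to_numpy(dtype=float)
    return linkage(squareform(d, checks=False), method="ward")


def cut_tree(linkage_matrix: np.ndarray, k: int) -> np.ndarray:
    """Cut the dendrogram into exactly k groups (labels 1..k)."""
    return fcluster(linkage_matrix, t=k, criterion="maxclust")


def find_k(
    linkage_matrix: np.ndarray,
    distances: pd.DataFrame,
    k_range: Optional[range] = None,
) -> ClusterAssignment:
    """Select k by maximal average silhouette width over the range.

    Silhouettes are computed from the same cosine distances used for
    the tree; ties resolve to the smaller k.
    """
    n = distances.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples to select k")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    d = distances.to_numpy(dtype=float)
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = cut_tree(linkage_matrix, k)
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
            continue
        sil[k] = float(silhouette_score(d, labels, metric="precomputed"))
    best_k = min(ks, key=lambda k: (-sil[k], k))
    return ClusterAssignment(
        labels=pd.Series(labels_by_k[best_k], index=distances.index),
        k=best_k,
        silhouette_by_k=sil,
        linkage_matrix=linkage_matrix,
    )


def cluster_samples(
    expr: pd.DataFrame,
    module_genes: Optional[list[str]] = None,
    k_range: Optional[range] = None,
) -> ClusterAssignment:
    """Full clustering pass: restrict to module genes, cosine, Ward, find_k."""
    sub = expr.loc[module_genes] if module_genes is not None else expr
    d = cosine_distance_matrix(sub)
    Z = ward_tree(d)
    return find_k(Z, d, k_range=k_range)
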