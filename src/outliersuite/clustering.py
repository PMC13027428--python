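"""Clustering tendency, k selection, partitioning, and cluster profiling.

Hopkins statistic and the VAT (Visual Assessment of cluster Tendency)
reordering assess whether the data warrant clustering at all; four
internal indices (WSS, silhouette, Calinski-Harabasz, Davies-Bouldin)
guide the choice of k; K-means and complete-linkage hierarchical
clustering produce the partitions, and profiles summarize each cluster
in PC space and standardized marker units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "HopkinsResult",
    "hopkins",
    "vat_order",
    "k_selection",
    "kmeans",
    "hierarchical",
    "ClusteringResult",
    "profile_clusters",
    "merge_tree_newick",
]


@dataclass
class HopkinsResult:
    H: float
    m: int
    seed: int


def hopkins(m: pd.DataFrame, frac: float = 0.1, seed: int = 0) -> HopkinsResult:
    """Hopkins clustering-tendency statistic H = sum(u) / (sum(u) + sum(w)).

    ``m_probes = max(5, ceil(frac*n))`` real points are sampled without
    replacement; ``w`` are their nearest-neighbour distances to the other
    real points and ``u`` the nearest-neighbour distances of uniform
    points drawn in the per-feature min-max bounding box.  H ~ 0.5 for
    spatially random data and approaches 1 for clustered data.
    """
    x = m.to_numpy(dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("Hopkins statistic needs n >= 10")
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(seed)
    m_probes = max(5, int(np.ceil(frac * n)))
    m_probes = min(m_probes, n - 1)
    probe_idx = rng.choice(n, size=m_probes, replace=False)
    w = np.empty(m_probes)
    for i, idx in enumerate(probe_idx):
        d = np.linalg.norm(x - x[idx], axis=1)
        d[idx] = np.inf
        w[i] = d.min()
    uniform = rng.uniform(lo, hi, size=(m_probes, p))
    u = cdist(uniform, x).min(axis=1)
    return HopkinsResult(H=float(u.sum() / (u.sum() + w.sum())), m=m_probes, seed=seed)


def vat_order(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical VAT reordering of a dissimilarity matrix.

    A Prim-style minimum-spanning-tree traversal: start from one endpoint
    of the globally largest dissimilarity, then repeatedly append the
    unvisited point closest to the visited set (lowest index on ties).
    Returns (permutation, reordered matrix).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        return np.array([0]), d.copy()
    start = int(np.unravel_index(np.argmax(d), d.shape)[0])
    order = [start]
    visited = np.zeros(n, dtype=bool)
    visited[start] = True
    best = d[start].copy()
    while len(order) < n:
        best_masked = np.where(visited, np.inf, best)
        nxt = int(np.argmin(best_masked))  # argmin takes the lowest index on ties
        order.append(nxt)
        visited[nxt] = True
        best = np.minimum(best, d[nxt])
    perm = np.array(order)
    return perm, d[np.ix_(perm, perm)]


def k_selection(
    m: pd.DataFrame, k_range: range = range(2, 11), seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Internal-index table (WSS, silhouette, CH, DB) over seeded K-means
    runs for each k.  The silhouette-optimal k is the recommended default
    when the indices disagree."""
    x = m.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("k selection needs n >= 3")
    rows = []
    for k in k_range:
        if k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        labels = km.labels_
        rows.append(dict(
            k=k,
            wss=float(km.inertia_),
            silhouette=float(silhouette_score(x, labels)),
            calinski_harabasz=float(calinski_harabasz_score(x, labels)),
            davies_bouldin=float(davies_bouldin_score(x, labels)),
        ))
    return pd.DataFrame(rows).set_index("k")


@dataclass
class ClusteringResult:
    labels: pd.Series
    method: str
    k: int
    centroids: np.ndarray | None = None
    wss: float | None = None
    merge_tree: np.ndarray | None = None  # scipy linkage matrix


def kmeans(m: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """Seeded K-means (k-means++ initialisation, best of ``n_init`` runs)."""
    x = m.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds n={x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return ClusteringResult(
        labels=pd.Series(km.labels_, index=m.index, name="cluster"),
        method="kmeans", k=k, centroids=km.cluster_centers_, wss=float(km.inertia_),
    )


def hierarchical(
    m: pd.DataFrame, k: int, method: str = "complete", metric: str = "euclidean"
) -> ClusteringResult:
    """Agglomerative clustering (complete linkage, Euclidean by default);
    the full merge tree is retained and cut at k."""
    x = m.to_numpy(dtype=float)
    z = linkage(x, method=method, metric=metric)
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 0..k-1 in order of first appearance, for determinism
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        labels[i] = mapping.setdefault(c, len(mapping))
    return ClusteringResult(
        labels=pd.Series(labels, index=m.index, name="cluster"),
        method="hierarchical", k=k, merge_tree=z,
    )


def merge_tree_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def profile_clusters(
    m: pd.DataFrame, labels: pd.Series, pca_scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-cluster size, percentage, PC-space centroid, and per-feature mean
    (z-profile when ``m`` is standardized)."""
    labels = labels.reindex(m.index)
    rows = []
    n = len(labels)
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        row: dict = {"cluster": int(c), "size": len(members),
                     "percentage": round(100.0 * len(members) / n, 1)}
        if pca_scores is not None:
            for col in pca_scores.columns[:2]:
                row[f"centroid_{col}"] = float(pca_scores.loc[members, col].mean())
        for feat in m.columns:
            row[f"mean_{feat}"] = float(m.loc[members, feat].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
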