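"""Ward hierarchical clustering of kinetic scores and cluster diagnostics.

Channels are grouped with Ward's minimal-variance linkage on their total
scores.  The number of clusters is not chosen automatically: ``scan_k``
tabulates internal validity indexes (silhouette, Dunn, Davies-Bouldin,
Calinski-Harabasz), the per-protocol *inner distance* and the singleton
count across a range of cuts, and the user picks a cut from their knees
and extrema.

The inner distance of a clustering, for one protocol, is the scatter of
members' raw feature traces around their cluster-mean trace, averaged over
clusters::

    d_inner = (1/n_clusters) * sum_k (1/|C_k|) * sum_{j in C_k} ||s_j - c_k||

with the norm the mean absolute value over all trace entries.  It is
computed on the preprocessed (not Z-scored) feature vectors, which makes
it comparable across protocols with different step counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .features import FeatureVector

__all__ = [
    "LinkageTree",
    "WardClustering",
    "ward_linkage",
    "cut",
    "validity_indexes",
    "dunn_index",
    "inner_distance",
    "reference_models",
    "cluster_names",
    "scan_k",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge tree (scipy linkage matrix plus leaf ids)."""

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def ward_linkage(scores: np.ndarray, ids: list[str] | None = None) -> LinkageTree:
    """Ward's minimal-variance agglomeration of an (N, D) score matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need at least two D-dimensional scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    z = hierarchy.linkage(scores, method="ward")
    if ids is None:
        ids = [str(i) for i in range(scores.shape[0])]
    return LinkageTree(merges=z, leaf_ids=tuple(ids))


def cut(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels (0..k-1) for the cut of the tree into exactly ``k`` clusters."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    labels = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    # relabel by order of first appearance for determinism
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def dunn_index(scores: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min inter-cluster distance over max intra-cluster diameter."""
    from scipy.spatial.distance import cdist, pdist

    clusters = [scores[labels == c] for c in np.unique(labels)]
    max_diam = max((pdist(c).max() if len(c) > 1 else 0.0) for c in clusters)
    min_inter = min(
        cdist(clusters[i], clusters[j]).min()
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
    )
    if max_diam == 0.0:
        return float("inf")
    return float(min_inter / max_diam)


def validity_indexes(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Internal cluster-validity indexes for one cut.

    Silhouette, Dunn and Calinski-Harabasz flag compact, well-separated
    clusterings with high values; Davies-Bouldin with low values.  The
    singleton count tracks fragmentation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("validity indexes need at least two clusters")
    n = len(labels)
    out: dict[str, float] = {}
    if len(uniq) < n:
        out["silhouette"] = float(silhouette_score(scores, labels))
        out["davies_bouldin"] = float(davies_bouldin_score(scores, labels))
        out["calinski_harabasz"] = float(calinski_harabasz_score(scores, labels))
    else:  # all singletons: scatter-based indexes are undefined
        out["silhouette"] = float("nan")
        out["davies_bouldin"] = float("nan")
        out["calinski_harabasz"] = float("nan")
    out["dunn"] = dunn_index(scores, labels)
    out["singleton_count"] = int(np.sum(counts == 1))
    return out


def inner_distance(
    features: dict[str, np.ndarray] | np.ndarray,
    labels: np.ndarray,
) -> dict[str, float] | float:
    """Per-protocol scatter of raw feature traces around cluster means.

    ``features`` maps protocol name to an (N, L) matrix of preprocessed
    feature vectors (or is a single such matrix).  The norm is the mean
    absolute value over the L trace entries.
    """
    if isinstance(features, dict):
        return {name: inner_distance(mat, labels) for name, mat in features.items()}
    mat = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if mat.shape[0] != labels.size:
        raise ValueError("feature matrix and labels disagree on the number of channels")
    total = 0.0
    uniq = np.unique(labels)
    for c in uniq:
        members = mat[labels == c]
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        center = members.mean(axis=0)
        total += float(np.mean(np.abs(members - center)))
    return total / len(uniq)


def reference_models(
    scores: np.ndarray, labels: np.ndarray, ids: list[str]
) -> dict[int, str]:
    """Per cluster, the member closest to the cluster's mean score.

    Ties are broken by lexicographically smallest channel id.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out: dict[int, str] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        center = scores[idx].mean(axis=0)
        dists = np.linalg.norm(scores[idx] - center, axis=1)
        best = min(zip(dists, (ids[i] for i in idx)), key=lambda t: (t[0], t[1]))
        out[int(c)] = best[1]
    return out


def cluster_names(
    labels: np.ndarray, subtypes: list[str], min_fraction: float = 0.30
) -> dict[int, str]:
    """Name each cluster by the subtype labels contributing >= ``min_fraction``.

    Clusters with no label reaching the threshold are named ``"mixed"``.
    """
    labels = np.asarray(labels)
    out: dict[int, str] = {}
    for c in np.unique(labels):
        members = [subtypes[i] for i in np.flatnonzero(labels == c)]
        counts = Counter(members)
        dominant = sorted(
            name for name, cnt in counts.items() if cnt / len(members) >= min_fraction
        )
        out[int(c)] = "/".join(dominant) if dominant else "mixed"
    return out


def scan_k(
    tree: LinkageTree,
    scores: np.ndarray,
    features: dict[str, np.ndarray] | None = None,
    k_range: range | list[int] | None = None,
) -> pd.DataFrame:
    """Validity indexes and inner distances across a range of cuts.

    Returns one row per k; no cut is selected automatically — the table is
    meant for the usual knee/extremum heuristics.
    """
    n = tree.n_leaves
    if k_range is None:
        k_range = range(2, n + 1)
    rows = []
    for k in k_range:
        labels = cut(tree, k)
        row: dict[str, float] = {"k": k}
        if k >= 2:
            row.update(validity_indexes(scores, labels))
        else:
            row.update(
                silhouette=float("nan"), davies_bouldin=float("nan"),
                calinski_harabasz=float("nan"), dunn=float("nan"),
                singleton_count=int(np.sum(np.unique(labels, return_counts=True)[1] == 1)),
            )
        if features is not None:
            for name, val in inner_distance(features, labels).items():
                row[f"inner_distance_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


class WardClustering(BaseEstimator, ClusterMixin):
    """Ward clustering of total scores at a fixed cut (scikit-learn estimator).

    Parameters
    ----------
    n_clusters : int
        Number of clusters at the cut.

    Attributes (after ``fit``)
    --------------------------
    tree_ : LinkageTree
    labels_ : cluster label per channel (0..k-1, order of first appearance)
    indexes_ : validity-index table for the cut
    reference_models_ : channel id closest to each cluster's mean score
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None, ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(X.shape[0])]
        self.tree_ = ward_linkage(X, ids)
        self.labels_ = cut(self.tree_, self.n_clusters)
        self.indexes_ = validity_indexes(X, self.labels_) if self.n_clusters >= 2 else {}
        self.reference_models_ = reference_models(X, self.labels_, ids)
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_
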