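"""Functional clustering of chirp responses.

Repeat-averaged local and global chirp responses are downsampled by
block-averaging every four consecutive time points, concatenated, and
clustered with Ward hierarchical clustering on Euclidean distances.  The
dendrogram can be cut either at a distance threshold (the threshold is
dataset-scale dependent and was originally chosen from the dendrogram by
eye) or at a target cluster count (default 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["ClusterAssignment", "build_features", "ChirpWardClusterer", "cluster"]


@dataclass
class ClusterAssignment:
    features: np.ndarray
    linkage: np.ndarray          # scipy linkage matrix (dendrogram)
    threshold: float | None
    labels: np.ndarray


def build_features(local_avg: np.ndarray, global_avg: np.ndarray,
                   block: int = 4) -> np.ndarray:
    """Downsample two chirp averages by block-averaging and concatenate.

    Trailing partial blocks are averaged over their actual length; the
    feature length is ``ceil(len(local)/block) + ceil(len(global)/block)``.
    """
    def down(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n_full = len(x) // block
        out = x[: n_full * block].reshape(n_full, block).mean(axis=1)
        if len(x) % block:
            out = np.r_[out, x[n_full * block:].mean()]
        return out

    return np.concatenate([down(local_avg), down(global_avg)])


class ChirpWardClusterer(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering with a distance- or count-based cut.

    Exactly one of ``distance_threshold`` and ``n_clusters`` applies;
    ``n_clusters=3`` by default (the threshold of the original dendrogram
    cut is dataset-scale dependent).

    Attributes: ``labels_``, ``linkage_`` (scipy linkage matrix),
    ``assignment_``.
    """

    def __init__(self, n_clusters: int | None = 3,
                 distance_threshold: float | None = None):
        self.n_clusters = n_clusters
        self.distance_threshold = distance_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 2:
            raise ValueError("need at least 2 feature vectors")
        Z = linkage(X, method="ward", metric="euclidean")
        if self.distance_threshold is not None:
            labels = fcluster(Z, t=self.distance_threshold, criterion="distance")
        else:
            labels = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        self.linkage_ = Z
        self.labels_ = labels - 1
        self.assignment_ = ClusterAssignment(X, Z, self.distance_threshold,
                                             self.labels_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster(features: np.ndarray, threshold: float | None = None,
            n_clusters: int | None = 3) -> ClusterAssignment:
    """Cluster feature vectors; cut at `threshold` if given, else `n_clusters`."""
    est = ChirpWardClusterer(
        n_clusters=None if threshold is not None else n_clusters,
        distance_threshold=threshold)
    return est.fit(features).assignment_
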