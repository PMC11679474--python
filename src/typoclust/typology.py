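"""Typology clustering of labeled volunteers (methodology M1).

The labeled feature map D (windows x features) is collapsed into a
per-volunteer profile matrix D' whose columns are the mean and sample
standard deviation of every feature within every target class — 228 columns
for 57 features and two classes.  D' is clustered with Ward-linkage
hierarchical clustering; the number of clusters is chosen by maximizing the
Dunn index over k in [2, 10], and any cluster smaller than 15% of the
volunteers is merged into its nearest neighbor.  New labeled volunteers are
assigned to the typology cluster (TC) with the nearest centroid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES
from .simulate import FEAR, NON_FEAR

CLASS_ORDER = (FEAR, NON_FEAR)
STAT_ORDER = ("mean", "std")


def transformed_columns(feature_names=FEATURE_NAMES,
                        classes=CLASS_ORDER) -> list[str]:
    return [f"{f}|{c}|{s}" for f in feature_names for c in classes for s in STAT_ORDER]


def transform_feature_map(feature_map: pd.DataFrame,
                          classes=CLASS_ORDER,
                          feature_names=None) -> pd.DataFrame:
    """Collapse the window-level feature map D into the volunteer-level D'.

    Each volunteer contributes one row; for every (feature, class) pair the
    row holds the mean and sample std of that feature over the volunteer's
    windows of that class.  Every volunteer must have at least two windows of
    each class, otherwise the std is undefined and an error lists the
    offending volunteer/class pairs.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    missing = []
    for vol, grp in feature_map.groupby("volunteer_id"):
        for c in classes:
            if (grp["label"] == c).sum() < 2:
                missing.append((vol, c))
    if missing:
        raise ValueError(
            "volunteers lacking >= 2 windows of a class: "
            + "; ".join(f"{v} ({c})" for v, c in missing)
        )
    rows, index = [], []
    for vol, grp in feature_map.groupby("volunteer_id", sort=True):
        row = []
        for f in feature_names:
            for c in classes:
                vals = grp.loc[grp["label"] == c, f].to_numpy(dtype=float)
                row.extend([vals.mean(), vals.std(ddof=1)])
        rows.append(row)
        index.append(vol)
    return pd.DataFrame(rows, index=pd.Index(index, name="volunteer_id"),
                        columns=transformed_columns(feature_names, classes))


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Classical Dunn index: minimum inter-cluster point distance divided by
    the maximum cluster diameter.  All-singleton partitions (zero diameter)
    score +inf by convention."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("dunn_index requires at least two clusters")
    d = cdist(points, points)
    same = labels[:, None] == labels[None, :]
    diam = float(np.max(d[same])) if same.any() else 0.0
    inter = float(np.min(d[~same]))
    if diam == 0.0:
        return float("inf")
    return inter / diam


def optimal_cluster_search(X: np.ndarray, k_min: int = 2, k_max: int = 10
                           ) -> tuple[np.ndarray, int, dict[int, float]]:
    """Ward-linkage hierarchical clustering scored by the Dunn index.

    Cuts the dendrogram at every k in [k_min, min(k_max, N)] and returns the
    labeling with the largest Dunn index (ties broken toward smaller k),
    together with the chosen k and the full search trace.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least two points to cluster")
    k_max = min(k_max, n)
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds the number of points {n}")
    Z = linkage(X, method="ward", metric="euclidean")
    best_labels, best_k, trace = None, None, {}
    for k in range(k_min, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = dunn_index(X, labels)
        trace[k] = score
        if best_k is None or score > trace[best_k]:
            best_labels, best_k = labels, k
    if best_k is None:
        raise ValueError("no valid partition found in the requested k range")
    return _canonical_labels(best_labels), best_k, trace


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters as 0..K-1 in order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        mapping.setdefault(lab, len(mapping))
        out[i] = mapping[lab]
    return out


def _centroids(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    return np.vstack([X[labels == k].mean(axis=0) for k in range(labels.max() + 1)])


def enforce_min_size(labels: np.ndarray, X: np.ndarray, min_frac: float = 0.15
                     ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Merge under-sized clusters until all hold >= ceil(min_frac * N) points.

    The smallest violating cluster is absorbed by the cluster with the
    nearest centroid; centroids are recomputed after every merge.  Collapsing
    to a single cluster raises.  Returns (labels, merge log of (src, dst))
    with labels renumbered 0..K-1.
    """
    import warnings

    labels = _canonical_labels(np.asarray(labels))
    X = np.asarray(X, dtype=float)
    n = len(labels)
    threshold = int(np.ceil(min_frac * n))
    if min_frac >= 0.5 and labels.max() + 1 > 2:
        warnings.warn("min_frac >= 0.5 with more than two clusters may collapse "
                      "the partition", stacklevel=2)
    log: list[tuple[int, int]] = []
    while True:
        k = labels.max() + 1
        sizes = np.bincount(labels, minlength=k)
        violators = np.where(sizes < threshold)[0]
        if len(violators) == 0:
            return labels, log
        if k <= 1:
            raise ValueError("minimum-size merging collapsed to a single cluster")
        src = violators[np.argmin(sizes[violators])]
        if k == 2:
            raise ValueError(
                "minimum-size merging would collapse to a single cluster"
            )
        cents = _centroids(X, labels)
        dists = np.linalg.norm(cents - cents[src], axis=1)
        dists[src] = np.inf
        dst = int(np.argmin(dists))
        labels[labels == src] = dst
        labels = _canonical_labels(labels)
        log.append((int(src), dst))


class TypologyClusterer(ClusterMixin, BaseEstimator):
    """Dunn-guided Ward clustering of volunteer profiles with a minimum-size
    merge rule (methodology M1).

    Parameters
    ----------
    k_min, k_max : exploration range for the number of clusters (2..10).
    min_frac : minimum cluster share of the volunteers (0.15).
    standardize : z-score the D' columns across volunteers before clustering,
        so mean- and std-scaled columns weigh comparably in Ward distances.

    Attributes
    ----------
    n_clusters_ : final number of typology clusters after merging.
    labels_ : cluster of each training volunteer.
    centroids_ : (n_clusters_, M) cluster means in the (standardized) D' space.
    dunn_trace_ : dict k -> Dunn index from the search.
    k_optimal_ : k chosen by the search before merging.
    merge_log_ : list of (absorbed, absorber) cluster pairs.
    """

    def __init__(self, k_min: int = 2, k_max: int = 10, min_frac: float = 0.15,
                 standardize: bool = True):
        self.k_min = k_min
        self.k_max = k_max
        self.min_frac = min_frac
        self.standardize = standardize

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.scale_mean_) / self.scale_std_

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.volunteer_ids_ = list(X.index)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.volunteer_ids_ = list(range(len(X)))
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("require 2 <= k_min <= k_max")
        self.scale_mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        std[std == 0] = 1.0
        self.scale_std_ = std
        Xs = self._scale(X)
        labels, k_opt, trace = optimal_cluster_search(Xs, self.k_min, self.k_max)
        labels, log = enforce_min_size(labels, Xs, self.min_frac)
        self.labels_ = labels
        self.k_optimal_ = k_opt
        self.dunn_trace_ = trace
        self.merge_log_ = log
        self.n_clusters_ = int(labels.max() + 1)
        self.centroids_ = _centroids(Xs, labels)
        return self

    def predict(self, X):
        """Assign rows of D' to the nearest typology-cluster centroid
        (Euclidean; ties break to the lowest cluster index)."""
        check_is_fitted(self, "centroids_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centroids_.shape[1]:
            raise ValueError(
                f"dimension mismatch: got {X.shape[1]} columns, expected "
                f"{self.centroids_.shape[1]}"
            )
        d = cdist(self._scale(X), self.centroids_)
        return d.argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def assign_labeled_volunteer(row, model: TypologyClusterer) -> int:
    """Nearest-centroid TC assignment for one volunteer's D' row."""
    return int(model.predict(np.atleast_2d(row))[0])
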