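"""Unlabeled volunteer enrollment via internal clusters (methodology M2).

A typology-cluster (TC) centroid lives in the 228-dimensional profile space,
but a new unlabeled volunteer only provides window-level observations in the
57-dimensional feature space.  To bridge the gap, each TC's training
observations are sub-clustered into four to six *internal clusters* (ICs)
with the same Dunn-guided Ward search used for the TCs, giving each TC a
small set of representative centroids in observation space.  A new volunteer
is enrolled into the TC with the lowest summed distance from their
observations to that TC's nearest IC centroids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .typology import _centroids, optimal_cluster_search


class InternalClusterEnroller(BaseEstimator):
    """Per-TC internal clusters and summed-distance enrollment.

    Parameters
    ----------
    ic_min, ic_max : exploration range for the internal-cluster count (4..6).

    Attributes
    ----------
    ic_centroids_ : dict TC id -> (n_ic, F) array of IC centroids.
    ic_counts_ : dict TC id -> number of ICs.
    tcs_ : sorted TC ids seen at fit time.
    """

    def __init__(self, ic_min: int = 4, ic_max: int = 6):
        self.ic_min = ic_min
        self.ic_max = ic_max

    def fit(self, X, y):
        """Compute ICs from training observations ``X`` (volunteer-normalized
        feature rows) with per-observation TC labels ``y``."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.tcs_ = sorted(np.unique(y).tolist())
        self.ic_centroids_ = {}
        self.ic_counts_ = {}
        for tc in self.tcs_:
            pts = X[y == tc]
            if len(pts) < self.ic_max:
                raise ValueError(
                    f"typology cluster {tc} has only {len(pts)} observations; "
                    f"need at least {self.ic_max} to form internal clusters"
                )
            labels, k, _ = optimal_cluster_search(pts, self.ic_min, self.ic_max)
            self.ic_centroids_[tc] = _centroids(pts, labels)
            self.ic_counts_[tc] = int(labels.max() + 1)
        return self

    def decision_scores(self, observations) -> dict:
        """Per-TC score: sum over observations of the Euclidean distance to
        that TC's closest IC centroid (lower is better)."""
        check_is_fitted(self, "ic_centroids_")
        obs = np.atleast_2d(np.asarray(observations, dtype=float))
        if obs.shape[0] == 0:
            raise ValueError("need at least one observation to enroll")
        return {
            tc: float(cdist(obs, cents).min(axis=1).sum())
            for tc, cents in self.ic_centroids_.items()
        }

    def assign(self, observations) -> int:
        """Enroll one volunteer: TC with the lowest summed distance
        (ties break to the lowest TC index)."""
        scores = self.decision_scores(observations)
        best = min(scores, key=lambda tc: (scores[tc], tc))
        return int(best)

    def predict(self, X, groups=None):
        """Enroll volunteers given stacked observations.

        With ``groups=None`` all rows are one volunteer and a single TC id is
        returned; otherwise rows are grouped by the ``groups`` vector and a
        TC id is returned per group (in sorted group order).
        """
        if groups is None:
            return np.array([self.assign(X)])
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        return np.array([self.assign(X[groups == g]) for g in sorted(set(groups.tolist()))])


def compute_internal_clusters(feature_map: pd.DataFrame, tc_of_volunteer: dict,
                              feature_names=None, ic_min: int = 4, ic_max: int = 6
                              ) -> InternalClusterEnroller:
    """Fit an :class:`InternalClusterEnroller` from a normalized feature map
    and a volunteer -> TC mapping."""
    from .features import FEATURE_NAMES

    feature_names = list(feature_names or FEATURE_NAMES)
    fm = feature_map[feature_map["volunteer_id"].isin(tc_of_volunteer)]
    X = fm[feature_names].to_numpy(dtype=float)
    y = fm["volunteer_id"].map(tc_of_volunteer).to_numpy()
    return InternalClusterEnroller(ic_min=ic_min, ic_max=ic_max).fit(X, y)


def assign_unlabeled_volunteer(observations, enroller: InternalClusterEnroller) -> int:
    """TC assignment for a new volunteer's (self-normalized) observations."""
    return enroller.assign(observations)
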