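"""Cluster-label surrogate for the Bayesian clustering step.

Real analyses typically derive population cluster membership from an
external individual-based Bayesian clustering run; every downstream
stage of this package accepts user-supplied labels.  When none are
available, :func:`assign_clusters` provides a deterministic k-means
surrogate on population band-frequency vectors, choosing K by
silhouette and flagging populations whose frequency vector sits nearly
equidistant between two cluster centroids as admixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import FrequencyTable

__all__ = ["ClusterAssignment", "assign_clusters"]


@dataclass
class ClusterAssignment:
    labels: dict[str, str]          # population -> cluster label
    admixed: set[str]               # flagged populations (carry a primary cluster too)
    K: int
    method: str = "surrogate"


def assign_clusters(
    freqs: FrequencyTable,
    K_range=range(2, 7),
    admixed_ratio: float = 0.6,
    seed: int = 0,
) -> ClusterAssignment:
    """K-means over population frequency vectors, K by silhouette.

    A population is flagged admixed when the ratio of its distance to
    the nearest centroid over the distance to the second-nearest
    exceeds ``admixed_ratio`` (it sits nearly halfway between two
    clusters).  Binomial sampling noise at realistic sample sizes puts
    an appreciable floor under every population's ratio and caps a
    50/50 mixture's ratio well below 1, so the default cutoff of 0.6
    separates the two regimes in practice.  Deterministic given
    ``seed``.
    """
    X = freqs.freq.copy()
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    P = X.shape[0]
    K_range = [k for k in K_range]
    if max(K_range) > P:
        raise ValueError("K exceeds number of populations")
    if K_range == [1]:
        return ClusterAssignment(
            {p: "C1" for p in freqs.populations}, set(), 1
        )
    best = None
    for K in K_range:
        if K < 2 or K >= P:
            continue
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        lab = km.fit_predict(X)
        if len(set(lab)) < 2:
            continue
        score = silhouette_score(X, lab)
        if best is None or score > best[0]:
            best = (score, K, km)
    if best is None:
        raise ValueError("no valid K in K_range")
    _, K, km = best
    lab = km.predict(X)
    centroids = km.cluster_centers_
    labels = {}
    admixed = set()
    for i, pop in enumerate(freqs.populations):
        d = np.linalg.norm(centroids - X[i], axis=1)
        order = np.argsort(d)
        labels[pop] = f"C{order[0] + 1}"
        if d[order[1]] > 0 and d[order[0]] / d[order[1]] > admixed_ratio:
            admixed.add(pop)
    return ClusterAssignment(labels, admixed, K)
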