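"""K-Means clustering of image features into maturity groups.

Minimises the usual K-Means objective — the mean squared Euclidean
distance between each feature vector and its assigned centroid — over
both the d×k centroid matrix and the one-hot assignments.  The
assignments are what the training loop consumes as pseudo-labels, so the
implementation pins down every behavioural detail the loop relies on:
k-means++ seeding with restarts, Lloyd iterations with a monotonically
non-increasing objective, deterministic lowest-index tie-breaking, and
repair of empty clusters by splitting the largest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import normalized_mutual_info_score


@dataclass
class ClusteringResult:
    """Assignments, centroids and the objective of one K-Means fit."""

    assignments: np.ndarray            # length N, values in {0..k-1}
    centroids: np.ndarray              # k×d (rows are cluster centres)
    objective: float                   # mean squared distance to assigned centroid
    n_iterations: int
    empty_cluster_repairs: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _check_features(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    return x


def _squared_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Full N×k squared Euclidean distance matrix (clipped at zero)."""
    d2 = (np.sum(x ** 2, axis=1)[:, None]
          - 2.0 * x @ centroids.T
          + np.sum(centroids ** 2, axis=1)[None, :])
    return np.maximum(d2, 0.0)


def assign_to_centroids(features, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; ties break to the lowest centroid index."""
    x = _check_features(getattr(features, "values", features))
    c = np.asarray(centroids, dtype=np.float64)
    if c.ndim != 2 or c.shape[1] != x.shape[1]:
        raise ValueError(
            f"centroid dimension {c.shape} incompatible with features {x.shape}")
    return np.argmin(_squared_distances(x, c), axis=1)


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    idx = int(rng.integers(n))
    centroids[0] = x[idx]
    d2 = np.sum((x - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[j] = x[idx]
        d2 = np.minimum(d2, np.sum((x - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
           ) -> tuple[np.ndarray, np.ndarray, list[float], int, int]:
    n, _ = x.shape
    k = centroids.shape[0]
    repairs = 0
    trace: list[float] = []
    labels = np.argmin(_squared_distances(x, centroids), axis=1)
    for iteration in range(1, max_iter + 1):
        # Update step: means of the assigned points; repair empty clusters
        # by moving in the point farthest from the largest cluster's centre.
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = x[members].mean(axis=0)
        for j in range(k):
            if not (labels == j).any():
                sizes = np.bincount(labels, minlength=k)
                big = int(np.argmax(sizes))
                members = np.flatnonzero(labels == big)
                far = members[np.argmax(
                    np.sum((x[members] - centroids[big]) ** 2, axis=1))]
                centroids[j] = x[far]
                labels[far] = j
                centroids[big] = x[labels == big].mean(axis=0)
                repairs += 1
        d2 = _squared_distances(x, centroids)
        labels = np.argmin(d2, axis=1)
        objective = float(d2[np.arange(n), labels].mean())
        trace.append(objective)
        if len(trace) >= 2 and trace[-2] - trace[-1] <= tol * max(trace[-2], 1e-30):
            break
    return labels, centroids, trace, iteration, repairs


def kmeans_fit(features, k: int, max_iter: int = 100, tol: float = 1e-4,
               n_restarts: int = 5, rng_seed: int = 0) -> ClusteringResult:
    """Best-of-restarts Lloyd K-Means with k-means++ seeding.

    The objective (mean squared distance of each point to its centroid)
    is non-increasing across Lloyd iterations within each restart; the
    restart with the lowest final objective is returned.  Deterministic
    for a fixed ``rng_seed``.
    """
    x = _check_features(getattr(features, "values", features))
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    best: ClusteringResult | None = None
    for _ in range(n_restarts):
        init = _kmeans_pp_init(x, k, rng)
        labels, centroids, trace, iters, repairs = _lloyd(x, init, max_iter, tol)
        result = ClusteringResult(
            assignments=labels, centroids=centroids,
            objective=trace[-1], n_iterations=iters,
            empty_cluster_repairs=repairs,
            objective_trace=np.asarray(trace))
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best


def clustering_agreement(labels_a, labels_b) -> float:
    """Normalized mutual information between two labelings, in [0, 1].

    Permutation-invariant, so it compares clusterings whose label ids
    have no common meaning (e.g. consecutive training rounds).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    return float(normalized_mutual_info_score(a, b))
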