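"""k-means++ clustering of the Δ% feature space, with quality metrics.

The clusterer is implemented here in full (D² seeding + Lloyd iterations with
restarts) rather than delegated, so that every numerical choice — tie-breaks,
empty-cluster reseeding, the convergence count — is explicit and testable;
scikit-learn serves only as an independent cross-check in the test suite.

Features are clustered unstandardized: all three axes are commensurate Δ%-of-
baseline units. Morphology names follow the field's shorthand: iOHYPO (initial
deficit), OHYPO (sustained deficit), OHYPER (persistent rise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "ClusterQuality",
    "kmeanspp_init",
    "fit_kmeans",
    "silhouette",
    "bootstrap_jaccard",
    "cluster_quality",
    "pairwise_centroid_distances",
    "label_morphologies",
    "MORPHOLOGY_NAMES",
]

MORPHOLOGY_NAMES = ("iOHYPO", "OHYPO", "OHYPER")


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray          # (k, d)
    labels: np.ndarray             # (n,) ints in 0..k-1
    inertia: float                 # within-cluster sum of squared distances
    i_conv: int                    # Lloyd iterations before convergence (best init)

    def predict(self, points: np.ndarray) -> np.ndarray:
        return _nearest(np.asarray(points, dtype=float), self.centroids)[0]


@dataclass
class ClusterQuality:
    d_c: np.ndarray                # (k,) mean distance to own centroid
    diameter: np.ndarray           # (k,) max distance to own centroid
    d_cc: np.ndarray               # (k, k) centroid distance matrix
    d_c_per_feature: np.ndarray    # (k, d) mean absolute per-axis deviation
    silhouette: float
    jaccard: float | None = None


def _nearest(points: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and squared distances to the nearest centroid (first wins ties)."""
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(len(points)), labels]


def kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """D² seeding: first centre uniform, each next with prob ∝ squared distance
    to the nearest centre already chosen."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k < 1 or n < k:
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    centroids = np.empty((k, points.shape[1]))
    idx = rng.integers(n)
    centroids[0] = points[idx]
    d2 = ((points - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            idx = rng.choice(n, p=probs)
        else:  # all remaining points coincide with chosen centres
            idx = rng.integers(n)
        centroids[j] = points[idx]
        d2 = np.minimum(d2, ((points - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int,
           tol: float) -> tuple[np.ndarray, np.ndarray, float, int]:
    k = len(centroids)
    centroids = centroids.copy()
    prev_inertia = np.inf
    labels, d2 = _nearest(points, centroids)
    for it in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for j in range(k):
            members = points[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
            else:  # reseed an empty cluster to the farthest point
                far = np.argmax(d2)
                new_centroids[j] = points[far]
        new_labels, new_d2 = _nearest(points, new_centroids)
        inertia = float(new_d2.sum())
        # Lloyd monotonicity is a hard invariant (modulo FP rounding)
        assert inertia <= prev_inertia + 1e-8 * max(1.0, abs(prev_inertia)), (
            "inertia increased across a Lloyd iteration"
        )
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids, labels, d2, prev_inertia = new_centroids, new_labels, new_d2, inertia
        if shift < tol:
            return centroids, labels, inertia, it
    return centroids, labels, prev_inertia, max_iter


def fit_kmeans(points: np.ndarray, k: int, rng: np.random.Generator | int | None = 0,
               n_init: int = 10, max_iter: int = 300, tol: float = 1e-6) -> ClusterModel:
    """Best-of-``n_init`` k-means++ fit by final inertia.

    Deterministic for a fixed seed: the same data and seed give identical
    labels and convergence count.
    """
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    rng = np.random.default_rng(rng)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(n_init):
        init = kmeanspp_init(points, k, rng)
        centroids, labels, inertia, i_conv = _lloyd(points, init, max_iter, tol)
        if best is None or inertia < best[0]:
            best = (inertia, centroids, labels, i_conv)
    inertia, centroids, labels, i_conv = best
    return ClusterModel(k=k, centroids=centroids, labels=labels,
                        inertia=inertia, i_conv=i_conv)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score (b − a) / max(a, b).

    Points in singleton clusters contribute 0, as do points where a = b = 0
    (coincident degenerate clusters).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two non-empty clusters")
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    n = len(points)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton convention: 0
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def bootstrap_jaccard(points: np.ndarray, k: int, B: int = 100,
                      rng: np.random.Generator | int | None = 0,
                      n_init: int = 10) -> float:
    """Mean bootstrap Jaccard stability of a k-means++ solution.

    A reference model is fitted on the full data; for each of ``B`` bootstrap
    resamples the model is refitted and every reference cluster is matched to
    the bootstrap cluster with greatest Jaccard overlap on the shared (unique
    resampled) points. The mean best-match Jaccard over clusters and resamples
    is returned. Degenerate resamples with fewer distinct points than k are
    redrawn.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(rng)
    n = len(points)
    ref = fit_kmeans(points, k, rng, n_init=n_init)
    means = []
    for _ in range(B):
        while True:
            idx = rng.integers(n, size=n)
            uniq = np.unique(idx)
            if len(np.unique(points[uniq], axis=0)) >= k:
                break
        boot = fit_kmeans(points[idx], k, rng, n_init=n_init)
        boot_labels_uniq = boot.predict(points[uniq])
        ref_labels_uniq = ref.labels[uniq]
        per_cluster = []
        for r in range(k):
            in_ref = ref_labels_uniq == r
            if not in_ref.any():
                continue
            best = 0.0
            for c in range(k):
                in_boot = boot_labels_uniq == c
                inter = np.sum(in_ref & in_boot)
                union = np.sum(in_ref | in_boot)
                if union:
                    best = max(best, inter / union)
            per_cluster.append(best)
        means.append(float(np.mean(per_cluster)))
    return float(np.mean(means))


def pairwise_centroid_distances(centroids: np.ndarray) -> np.ndarray:
    """Symmetric centroid distance matrix (zero diagonal)."""
    centroids = np.asarray(centroids, dtype=float)
    return np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))


def cluster_quality(points: np.ndarray, model: ClusterModel,
                    n_boot: int = 0,
                    rng: np.random.Generator | int | None = 0) -> ClusterQuality:
    """Per-cluster compactness and separation metrics.

    ``d_c`` is the mean Euclidean distance to the own centroid, the diameter
    its maximum; per-feature d_c is the mean absolute deviation on each axis.
    Bootstrap Jaccard is computed only when ``n_boot`` > 0.
    """
    points = np.asarray(points, dtype=float)
    k = model.k
    d_c = np.zeros(k)
    diam = np.zeros(k)
    d_cf = np.zeros((k, points.shape[1]))
    for j in range(k):
        members = points[model.labels == j]
        dists = np.sqrt(((members - model.centroids[j]) ** 2).sum(axis=1))
        d_c[j] = dists.mean()
        diam[j] = dists.max()
        d_cf[j] = np.abs(members - model.centroids[j]).mean(axis=0)
    jac = bootstrap_jaccard(points, k, n_boot, rng) if n_boot else None
    return ClusterQuality(
        d_c=d_c,
        diameter=diam,
        d_cc=pairwise_centroid_distances(model.centroids),
        d_c_per_feature=d_cf,
        silhouette=silhouette(points, model.labels),
        jaccard=jac,
    )


def label_morphologies(model: ClusterModel, axis: int = 1) -> dict[int, str]:
    """Name the k = 3 clusters by their stabilization-point coordinate.

    Highest centroid on the stabilization axis → OHYPER (persistent rise),
    lowest → OHYPO (sustained deficit), middle → iOHYPO (initial deficit).
    Ties on the ranking coordinate are ambiguous and raise.
    """
    if model.k != 3:
        raise ValueError("morphology labelling is defined for k = 3")
    coord = model.centroids[:, axis]
    if len(np.unique(coord)) != 3:
        raise ValueError("ambiguous morphology: tied stabilization coordinates")
    order = np.argsort(coord)  # low, mid, high
    return {int(order[0]): "OHYPO", int(order[1]): "iOHYPO", int(order[2]): "OHYPER"}
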