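"""Size-constrained k-means on the embedding, and silhouette selection of k.

Plain k-means can hand back tiny splinter clusters on embeddings with a
few stray points.  The constrained variant enforces a minimum cluster
size (default ceil(sqrt(n)/2)): whenever a fit returns clusters below
the threshold, k is increased by one and refit so the stray points get
their own cluster, which is then merged into the non-tiny cluster with
the nearest centroid — repeated until exactly k adequately-sized
clusters remain or a retry cap is hit.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import ClusterLabels, Embedding, ParameterError

__all__ = ["constrained_kmeans", "select_k_silhouette"]

logger = logging.getLogger(__name__)

_RETRY_CAP = 10


def _coords(Y) -> np.ndarray:
    return Y.coordinates if isinstance(Y, Embedding) else np.asarray(Y, float)


def _merge_tiny(
    labels0: np.ndarray, centers: np.ndarray, tiny: np.ndarray
) -> np.ndarray:
    """Reassign each tiny cluster to the non-tiny cluster with nearest centroid."""
    labels = labels0.copy()
    nontiny = np.flatnonzero(~tiny)
    for c in np.flatnonzero(tiny):
        d = np.linalg.norm(centers[nontiny] - centers[c], axis=1)
        target = nontiny[np.argmin(d)]  # argmin ties -> lowest cluster index
        labels[labels0 == c] = target
    return labels


def constrained_kmeans(
    Y,
    k: int,
    replicates: int = 20,
    min_size: int | None = None,
    seed: int = 0,
    constrained: bool = True,
) -> ClusterLabels:
    """k-means with ``replicates`` k-means++ starts and a minimum-size rule.

    Parameters
    ----------
    Y:
        Embedding or plain (n, r) coordinate array.
    k:
        Number of clusters requested (>= 2).
    min_size:
        Minimum admissible cluster size; default ceil(sqrt(n)/2).  Set
        ``constrained=False`` for plain k-means (useful when genuinely
        small clusters are expected).
    """
    X = _coords(Y)
    n = X.shape[0]
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if n < 2 * k:
        raise ParameterError(f"need n >= 2k points, got n={n}, k={k}")
    if min_size is None:
        min_size = math.ceil(math.sqrt(n) / 2) if constrained else 0
    if constrained and k * min_size > n:
        raise ParameterError(
            f"infeasible: k={k} clusters of size >= {min_size} need "
            f"{k * min_size} > n={n} points"
        )

    def fit(k_cur: int) -> tuple[np.ndarray, np.ndarray]:
        km = KMeans(
            n_clusters=k_cur, n_init=replicates, random_state=seed & 0x7FFFFFFF
        ).fit(X)
        return km.labels_, km.cluster_centers_

    if not constrained:
        labels, _ = fit(k)
        return ClusterLabels(labels=_relabel(labels), k=k, source="estimated")

    k_cur = k
    labels = centers = None
    for _ in range(_RETRY_CAP):
        labels, centers = fit(k_cur)
        sizes = np.bincount(labels, minlength=k_cur)
        tiny = sizes < min_size
        n_nontiny = int(np.sum(~tiny))
        if n_nontiny == k:
            if tiny.any():
                labels = _merge_tiny(labels, centers, tiny)
            labels = _relabel(labels)
            return ClusterLabels(labels=labels, k=k, source="estimated")
        if n_nontiny > k:
            break  # overshoot: no way to reach exactly k by growing k further
        k_cur += 1
    warnings.warn(
        f"minimum-size constraint not satisfiable with exactly k={k} clusters "
        "within the retry cap; returning best labels",
        stacklevel=2,
    )
    sizes = np.bincount(labels, minlength=len(centers))
    tiny = sizes < min_size
    if tiny.any() and (~tiny).any():
        labels = _merge_tiny(labels, centers, tiny)
    labels = _relabel(labels)
    return ClusterLabels(labels=labels, k=int(labels.max()), source="estimated")


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map labels onto consecutive 1..k preserving first-appearance order."""
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


def select_k_silhouette(
    Y,
    k_candidates,
    seed: int = 0,
    replicates: int = 20,
    min_size: int | None = None,
    constrained: bool = True,
    return_scores: bool = False,
):
    """Choose k among candidates by maximal mean silhouette width.

    Runs constrained k-means per candidate and scores the labels with the
    Euclidean silhouette in the embedding coordinates.  Ties break to the
    smallest k.
    """
    candidates = list(k_candidates)
    if not candidates:
        raise ParameterError("k_candidates must be non-empty")
    if any(k < 2 for k in candidates):
        raise ParameterError("every candidate k must be >= 2")
    X = _coords(Y)
    scores: dict[int, float] = {}
    for k in sorted(set(candidates)):
        labels = constrained_kmeans(
            Y, k, replicates=replicates, min_size=min_size, seed=seed,
            constrained=constrained,
        )
        if labels.k < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(X, labels.labels))
        logger.info("silhouette(k=%d) = %.4f", k, scores[k])
    best = max(scores, key=lambda k: (scores[k], -k))
    if return_scores:
        return best, scores
    return best
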