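"""Clustering-quality and geometric-fidelity statistics.

Cluster quality against ground truth: adjusted Rand index (ARI), entropy
of cluster purity (ECP) and entropy of cluster accuracy (ECA).  Geometric
fidelity of an embedding: the geometric perturbation pi, the
scale-optimal relative Frobenius discrepancy between the cluster-mean
distance matrices of the original data and the embedding,

    pi(X, Y, l) = min_c ||D_mu,X - c D_mu,Y||_F^2 / ||D_mu,X||_F^2,
    c* = <D_mu,X, D_mu,Y> / ||D_mu,Y||_F^2,

where D_mu,. is the n x n matrix whose (i, j) entry is the distance
between the means of the clusters containing points i and j.  Finally the
elongation score G1, the sample skewness of k-th nearest-neighbor
distances (k = 10 log n), flags elongated/anisotropic data for which a
larger path-metric power p tends to help.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon_entropy
from sklearn.metrics import adjusted_rand_score

from ._neighbors import pairwise_distances
from .datatypes import ClusterLabels, DataMatrix, Embedding, ParameterError

__all__ = [
    "adjusted_rand_index",
    "entropy_metrics",
    "geometric_perturbation",
    "elongation_score",
    "GeometricPerturbation",
    "ElongationScore",
]


@dataclass
class GeometricPerturbation:
    pi: float
    c_star: float


@dataclass
class ElongationScore:
    G1: float
    k_nn: int
    mean_dist: float
    sd: float


def _label_vector(labels) -> np.ndarray:
    if isinstance(labels, ClusterLabels):
        return labels.labels
    return np.asarray(labels)


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}")


def adjusted_rand_index(truth, pred) -> float:
    """Chance-corrected Rand index; 1 iff the partitions coincide."""
    t, p = _label_vector(truth), _label_vector(pred)
    _check_lengths(t, p)
    return float(adjusted_rand_score(t, p))


def entropy_metrics(truth, pred, base: float = math.e, weighted: bool = False):
    """(ECP, ECA): mean within-cluster / within-class label entropies.

    ECP averages, over predicted clusters, the Shannon entropy of the
    true-label distribution inside the cluster; ECA averages, over true
    classes, the entropy of the predicted labels inside the class.  Both
    are 0 exactly for a perfect partition.  ``weighted=True`` weights the
    average by cluster (resp. class) size instead of uniformly.
    """
    t, p = _label_vector(truth), _label_vector(pred)
    _check_lengths(t, p)

    def _mean_entropy(group_by: np.ndarray, of: np.ndarray) -> float:
        ents, sizes = [], []
        for g in np.unique(group_by):
            inside = of[group_by == g]
            _, counts = np.unique(inside, return_counts=True)
            ents.append(_shannon_entropy(counts, base=base))
            sizes.append(inside.size)
        w = np.asarray(sizes, float) if weighted else np.ones(len(ents))
        return float(np.average(ents, weights=w))

    ecp = _mean_entropy(group_by=p, of=t)
    eca = _mean_entropy(group_by=t, of=p)
    return ecp, eca


def _cluster_means(X: np.ndarray, labels: np.ndarray, space: str) -> np.ndarray:
    means = []
    for lab in np.unique(labels):
        members = X[labels == lab]
        if members.size == 0:
            raise ValueError(f"cluster {lab} is empty in {space}")
        means.append(members.mean(axis=0))
    return np.asarray(means)


def geometric_perturbation(X, Y, truth) -> GeometricPerturbation:
    """Scale-optimal discrepancy between cluster-mean geometries of X and Y.

    Computed in the k x k cluster-level form with cluster-pair count
    weights n_a * n_b, which equals the n x n point-level definition
    without materializing an n x n matrix.  pi = 0 iff the embedding's
    cluster-mean distances are proportional to the original ones.
    """
    Xv = X.values if isinstance(X, DataMatrix) else np.asarray(X, float)
    Yv = Y.coordinates if isinstance(Y, Embedding) else np.asarray(Y, float)
    labels = _label_vector(truth)
    _check_lengths(np.asarray(Xv), labels)
    _check_lengths(np.asarray(Yv), labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ParameterError("geometric perturbation requires >= 2 clusters")
    DX = pairwise_distances(_cluster_means(Xv, labels, "X"))
    DY = pairwise_distances(_cluster_means(Yv, labels, "Y"))
    W = np.outer(counts.astype(float), counts.astype(float))
    den_y = float((W * DY * DY).sum())
    if den_y == 0.0:
        raise ValueError(
            "all cluster means coincide in the embedding; the optimal scale "
            "c* is undefined (degenerate concentric geometry)"
        )
    den_x = float((W * DX * DX).sum())
    if den_x == 0.0:
        raise ValueError("all cluster means coincide in X; pi is undefined")
    c_star = float((W * DX * DY).sum()) / den_y
    resid = DX - c_star * DY
    pi = float((W * resid * resid).sum()) / den_x
    return GeometricPerturbation(pi=pi, c_star=c_star)


def elongation_score(X, k_nn: int | None = None) -> ElongationScore:
    """Sample skewness G1 of k-th nearest-neighbor distances.

    k defaults to round(10 * ln n), clamped to [1, n-1]; the k-th
    neighbor excludes the point itself.  With d_i the distances, dbar
    their mean and s their sample standard deviation,

        G1 = n / ((n - 1)(n - 2)) * sum_i ((d_i - dbar) / s)^3.

    Right-skewed neighbor distances (a long low-density tail) give
    G1 > 0 and indicate elongated data.
    """
    Xv = X.values if isinstance(X, DataMatrix) else np.asarray(X, float)
    n = Xv.shape[0]
    if n < 3:
        raise ParameterError("elongation score requires n >= 3")
    if k_nn is None:
        k_nn = int(round(10 * math.log(n)))
    k_nn = max(1, min(k_nn, n - 1))
    D = pairwise_distances(Xv)
    # k-th smallest among the n-1 non-self distances of each row
    D_sorted = np.sort(D, axis=1)
    d = D_sorted[:, k_nn]  # column 0 is the self distance 0
    dbar = float(d.mean())
    s = float(d.std(ddof=1))
    if s == 0.0:
        warnings.warn("all k-NN distances equal; G1 set to 0", stacklevel=2)
        return ElongationScore(G1=0.0, k_nn=k_nn, mean_dist=dbar, sd=s)
    g1 = n / ((n - 1) * (n - 2)) * float(np.sum(((d - dbar) / s) ** 3))
    return ElongationScore(G1=g1, k_nn=k_nn, mean_dist=dbar, sd=s)
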