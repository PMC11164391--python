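"""Deterministic Euclidean pairwise distances and KNN sets.

Neighbor ties are broken by lowest index (stable argsort), which makes
every stage of the pipeline reproducible bit-for-bit.  Distances are
computed exactly (scipy cdist) for small problems and via the BLAS
Gram-matrix identity for large ones, where the ~1e-8 relative rounding
of the fast route is irrelevant next to sampling noise.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

# above this many multiply-adds the exact kernel becomes the bottleneck
_EXACT_FLOP_BUDGET = 2e9


def pairwise_distances(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance matrix between rows of X and Y (default X)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.shape[0] * Y.shape[0] * X.shape[1] <= _EXACT_FLOP_BUDGET:
        return cdist(X, Y)
    sq = (X * X).sum(axis=1)[:, None] + (Y * Y).sum(axis=1)[None, :] - 2.0 * (X @ Y.T)
    np.maximum(sq, 0.0, out=sq)
    D = np.sqrt(sq)
    if Y is X:
        np.fill_diagonal(D, 0.0)
    return D


def knn_indices(
    X: np.ndarray, k: int, include_self: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k nearest neighbors of each row.

    With ``include_self`` the point itself (distance 0) counts as its own
    first neighbor; otherwise the self column is dropped before taking k.
    Ties are broken by lowest index.
    """
    n = X.shape[0]
    if not 1 <= k <= (n if include_self else n - 1):
        raise ValueError(f"k={k} out of range for n={n}")
    D = pairwise_distances(X)
    order = np.argsort(D, axis=1, kind="stable")
    if include_self:
        idx = order[:, :k]
    else:
        rows = np.arange(n)[:, None]
        keep = order != rows  # drop the self column wherever it sorted
        idx = order[keep].reshape(n, n - 1)[:, :k]
    return idx, D[np.arange(n)[:, None], idx]
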