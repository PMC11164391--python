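"""p-power-weighted path metrics on a K2-nearest-neighbor graph.

The p-power path metric between two cells is

    l_p(a, b) = inf over paths (x_0=a, ..., x_s=b) of
                ( sum_i ||x_{i+1} - x_i||_2^p )^(1/p),

restricted to paths in the symmetrized K2NN graph.  At p = 1 on a
complete graph this is Euclidean distance; on a KNN graph it
approximates geodesic distance; as p grows it approaches the bottleneck
("largest single hop") distance and becomes density-sensitive: points
joined through dense regions get closer.  Shortest paths are computed
with Dijkstra's algorithm on edge weights ||x_i - x_j||^p, and the total
weight is rooted back by 1/p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from ._neighbors import knn_indices
from .datatypes import DataMatrix, ParameterError, PathDistanceMatrix

__all__ = [
    "WeightedGraph",
    "build_knn_graph",
    "path_distances",
    "landmark_path_distances",
]

logger = logging.getLogger(__name__)


@dataclass
class WeightedGraph:
    """Symmetrized K2NN graph with p-powered Euclidean edge weights."""

    weights: csr_matrix  # symmetric, weight = ||x_i - x_j||^p
    p: float
    K2: int

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges (i < j, weight); mainly for tests and export."""
        coo = self.weights.tocoo()
        return [
            (int(i), int(j), float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
            if i < j
        ]


def build_knn_graph(X: DataMatrix, K2: int, p: float = 2.0) -> WeightedGraph:
    """Build the union-symmetrized K2NN graph with weights ||xi - xj||^p.

    Edge (i, j) is present iff i is a K2-nearest neighbor of j or vice
    versa (self excluded), so every node has degree >= K2.  K2 >= n is
    clamped to n - 1 with a warning, matching the default K2 = min(n, 500).
    """
    n = X.n
    if p < 1:
        raise ParameterError(f"p must be >= 1, got {p}")
    if K2 < 1:
        raise ParameterError(f"K2 must be >= 1, got {K2}")
    if K2 >= n:
        logger.warning("K2=%d >= n=%d; clamping to n-1", K2, n)
        K2 = n - 1
    idx, dist = knn_indices(X.values, K2, include_self=False)
    rows = np.repeat(np.arange(n), K2)
    data = dist.ravel() ** p
    # duplicate points: keep the zero-weight edge representable in the
    # sparse graph (an exact 0 would be dropped by CSR arithmetic)
    data[data == 0.0] = 1e-300
    W = csr_matrix((data, (rows, idx.ravel())), shape=(n, n))
    W = W.maximum(W.T)  # union symmetrization; weights agree on both arcs
    return WeightedGraph(weights=W, p=p, K2=K2)


def _finalize(Dp: np.ndarray, G: WeightedGraph) -> tuple[np.ndarray, bool]:
    connected = bool(np.all(np.isfinite(Dp)))
    if not connected:
        ncomp, _ = connected_components(G.weights, directed=False)
        logger.warning(
            "KNN graph is disconnected (%d components); unreachable pairs "
            "have infinite path distance",
            ncomp,
        )
    with np.errstate(invalid="ignore"):
        D = Dp ** (1.0 / G.p)
    return D, connected


def path_distances(G: WeightedGraph) -> PathDistanceMatrix:
    """All-pairs path-metric distances via Dijkstra from every source."""
    Dp = dijkstra(G.weights, directed=False)
    D, connected = _finalize(Dp, G)
    # per-source Dijkstra output is symmetric up to float summation order;
    # kept as-is so landmark rows equal full-matrix rows exactly
    np.fill_diagonal(D, 0.0)
    return PathDistanceMatrix(values=D, p=G.p, K2=G.K2, connected=connected)


def landmark_path_distances(
    X: DataMatrix,
    q: int,
    K2: int,
    p: float = 2.0,
    seed: int = 0,
    graph: WeightedGraph | None = None,
) -> PathDistanceMatrix:
    """Path distances from q random landmarks to all n points.

    Landmarks are drawn uniformly without replacement (seeded) and the
    graph is the same symmetrized K2NN graph on the full data as in full
    mode, so each landmark row equals the corresponding row of the full
    matrix exactly.
    """
    n = X.n
    if not 1 <= q <= n:
        raise ParameterError(f"q={q} must lie in 1..{n}")
    rng = np.random.default_rng(seed)
    landmarks = np.sort(rng.choice(n, size=q, replace=False))
    G = graph if graph is not None else build_knn_graph(X, K2=K2, p=p)
    Dp = dijkstra(G.weights, directed=False, indices=landmarks)
    D, connected = _finalize(Dp, G)
    D[np.arange(q), landmarks] = 0.0
    return PathDistanceMatrix(
        values=D, p=G.p, K2=G.K2, connected=connected, landmark_indices=landmarks
    )


def bottleneck_distances(G: WeightedGraph) -> np.ndarray:
    """All-pairs minimax ("bottleneck edge") Euclidean distances.

    The p -> infinity limit of the path metric; exposed for diagnostics
    and used as an oracle in tests.  Computed on the same edge set by a
    Floyd-Warshall-style minimax recursion, so only suitable for small n.
    """
    W = G.weights.toarray() ** (1.0 / G.p)  # back to Euclidean lengths
    n = W.shape[0]
    B = np.where(G.weights.toarray() > 0, W, np.inf)
    np.fill_diagonal(B, 0.0)
    for k in range(n):
        np.minimum(B, np.maximum(B[:, k][:, None], B[k, :][None, :]), out=B)
    return B


def export_distances(D: PathDistanceMatrix, path, cell_ids=None) -> None:
    """Write a distance matrix as CSV with cell identifiers."""
    import pandas as pd

    ids = cell_ids if cell_ids is not None else [str(i) for i in range(D.n)]
    rows = (
        [ids[i] for i in D.landmark_indices] if D.is_landmark else ids
    )
    pd.DataFrame(D.values, index=rows, columns=ids).to_csv(path)
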