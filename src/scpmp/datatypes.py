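"""Core containers shared across the scPMP pipeline.

The pipeline passes a small set of typed arrays between stages: the
cell-by-feature matrix, the path-distance matrix together with the
parameters that produced it, the MDS embedding with its spectrum, and
integer cluster labels.  Each container validates its own invariants at
construction so that stage boundaries fail early and loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DataMatrix",
    "PathDistanceMatrix",
    "Embedding",
    "ClusterLabels",
    "GeneratorSpec",
    "RunConfig",
    "ParameterError",
]


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


def _check_ids(ids: Optional[Sequence[str]], n: int, what: str) -> Optional[list]:
    if ids is None:
        return None
    ids = list(ids)
    if len(ids) != n:
        raise ValueError(f"{what}: expected {n} identifiers, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what}: identifiers must be unique")
    return ids


@dataclass
class DataMatrix:
    """An n x d matrix of cells (rows) by features (columns).

    Values must be finite; the pipeline assumes normalization happened
    upstream and treats the matrix as plain coordinates in R^d.
    """

    values: np.ndarray
    cell_ids: Optional[list] = None
    feature_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix requires a 2-D array")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError(f"DataMatrix requires n >= 2 and d >= 1, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DataMatrix must not contain NaN or infinite values")
        self.cell_ids = _check_ids(self.cell_ids, n, "cell_ids")
        self.feature_ids = _check_ids(self.feature_ids, d, "feature_ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class PathDistanceMatrix:
    """Pairwise (or landmark-to-all) p-power-weighted path distances.

    ``values`` is n x n in full mode or q x n in landmark mode, in which
    case ``landmark_indices`` records which rows of the full matrix the q
    rows correspond to.  ``connected`` is False when the underlying KNN
    graph is disconnected; unreachable pairs are ``inf``.
    """

    values: np.ndarray
    p: float
    K2: int
    connected: bool = True
    landmark_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance matrix must be 2-D")
        if self.p < 1:
            raise ParameterError(f"p must be >= 1, got {self.p}")
        if self.landmark_indices is not None:
            self.landmark_indices = np.asarray(self.landmark_indices, dtype=int)
            if self.landmark_indices.shape[0] != self.values.shape[0]:
                raise ValueError("one landmark index per row required")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def is_landmark(self) -> bool:
        return self.landmark_indices is not None

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Classical-MDS coordinates with the spectrum that produced them.

    ``eigenvalues`` holds the descending spectrum of the double-centered
    matrix B (the leading block when only the top of the spectrum was
    computed); column i of ``coordinates`` is scale(lambda_i) * v_i with
    scale = sqrt (default) or identity on lambda ("eigenvalue" mode).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    r: int
    scaling_mode: str = "sqrt_eigenvalue"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scaling_mode not in ("sqrt_eigenvalue", "eigenvalue"):
            raise ParameterError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.coordinates.shape[1] != self.r:
            raise ValueError("coordinate dimension must equal r")
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be sorted in descending order")

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class ClusterLabels:
    """Length-n integer labels in {1..k}."""

    labels: np.ndarray
    k: int
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.source not in ("estimated", "ground_truth"):
            raise ParameterError(f"unknown label source {self.source!r}")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")

    @property
    def n(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic benchmark draw.

    ``extra`` holds generator-specific shape parameters (ball centers,
    covariances, eigenvalue triples, ...); every default lives there so a
    benchmark is fully described by its spec.
    """

    name: str
    n: int
    k: int
    noise_sd: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < self.k:
            raise ParameterError("need at least one point per cluster")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Defaults follow the method's published defaults: K1 = 12 neighbors for
    local-average denoising, K2 = min(n, 500) for the path-metric graph,
    embedding dimension searched in [3, 39] with eigenvalue floor
    tau = 0.01, k-means with 20 replicates.
    """

    p: float = 2.0
    K1: int = 12
    K2: Optional[int] = None  # resolved to min(n, 500)
    r_min: int = 3
    r_max: int = 39
    tau: float = 0.01
    k: object = "auto"  # int or "auto"
    k_candidates: tuple = tuple(range(2, 10))
    replicates: int = 20
    landmarks: Optional[int] = None
    seed: int = 0
    scaling_mode: str = "sqrt_eigenvalue"
    min_size: Optional[int] = None  # resolved to ceil(sqrt(n)/2)
    constrained: bool = True
    denoise: bool = True

    def resolved_K2(self, n: int) -> int:
        return min(n, 500) if self.K2 is None else self.K2

    def resolved_min_size(self, n: int) -> int:
        if not self.constrained:
            return 0
        return math.ceil(math.sqrt(n) / 2) if self.min_size is None else self.min_size
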