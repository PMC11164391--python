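"""Local-averaging denoising.

Before path metrics are computed each cell is replaced by the mean of its
K1 nearest neighbors (itself included), which shrinks off-manifold noise
while leaving the sampled geometry in place.  K1 = 1 is therefore the
identity and larger K1 trades variance for bias.
"""

from __future__ import annotations

import numpy as np

from ._neighbors import knn_indices
from .datatypes import DataMatrix, ParameterError

__all__ = ["local_average"]


def local_average(X_noisy: DataMatrix, K1: int = 12) -> DataMatrix:
    """Replace each row by the arithmetic mean of its K1 nearest rows.

    Parameters
    ----------
    X_noisy:
        Input matrix; rows are cells.
    K1:
        Neighborhood size under Euclidean distance.  The neighborhood of a
        point contains the point itself, so ``K1=1`` returns the input
        unchanged.  Distance ties are broken by lowest index.
    """
    n = X_noisy.n
    if K1 < 1:
        raise ParameterError(f"K1 must be >= 1, got {K1}")
    if K1 > n:
        raise ParameterError(f"K1={K1} exceeds the number of cells n={n}")
    idx, _ = knn_indices(X_noisy.values, K1, include_self=True)
    denoised = X_noisy.values[idx].mean(axis=1)
    return DataMatrix(
        values=denoised,
        cell_ids=X_noisy.cell_ids,
        feature_ids=X_noisy.feature_ids,
    )
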