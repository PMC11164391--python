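"""Classical multidimensional scaling of path distances.

Torgerson's construction: square the distances, double-center,

    B = -1/2 J D^(2) J,      J = I - (1/n) 1 1^T,

and embed with the top eigenpairs of B.  The embedding dimension r is
chosen at the largest eigenratio lambda_i / lambda_{i+1} within an
admissible window (r_min <= i <= r_max and lambda_i / lambda_1 >= tau),
i.e. at the most pronounced spectral gap among "large" eigenvalues.

Two column scalings are supported: ``sqrt_eigenvalue`` (sqrt(lambda_i) *
v_i, the classical choice that reproduces distances on Euclidean input)
and ``eigenvalue`` (lambda_i * v_i).  A landmark fast path embeds q
landmark points by full MDS and places the remaining points by
distance-based triangulation against the landmarks.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .datatypes import Embedding, ParameterError, PathDistanceMatrix

__all__ = [
    "double_center",
    "select_dimension",
    "embed",
    "embed_distances",
    "landmark_embed",
]

logger = logging.getLogger(__name__)


def _as_square_array(D) -> np.ndarray:
    vals = D.values if isinstance(D, PathDistanceMatrix) else np.asarray(D, float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("expected a square distance matrix")
    return vals


def double_center(D) -> np.ndarray:
    """B = -1/2 J D^(2) J from a square, finite distance matrix."""
    vals = _as_square_array(D)
    if not np.all(np.isfinite(vals)):
        raise ValueError(
            "distance matrix contains infinite entries (disconnected KNN "
            "graph); increase K2 or remove isolated cells before MDS"
        )
    S = vals**2
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    B = -0.5 * (S - row - col + S.mean())
    return (B + B.T) / 2.0


def select_dimension(
    eigenvalues: np.ndarray,
    r_min: int = 3,
    r_max: int = 39,
    tau: float = 0.01,
) -> int:
    """Pick r at the largest admissible eigenratio lambda_i / lambda_{i+1}.

    Indices i run 1-based over the descending spectrum, restricted to
    r_min <= i <= r_max (r_max additionally capped at len - 1) and to
    "large" eigenvalues lambda_i / lambda_1 >= tau.  A gap onto a
    nonpositive eigenvalue counts as infinite.  Ties break to smallest i;
    with no admissible index, fall back to r_min with a warning.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < r_min + 1:
        raise ParameterError(f"need at least r_min+1={r_min + 1} eigenvalues")
    if lam[0] <= 0:
        raise ValueError("leading eigenvalue must be positive")
    hi = min(r_max, lam.size - 1)
    best_i, best_ratio = None, -np.inf
    for i in range(r_min, hi + 1):  # 1-based index i
        li, lnext = lam[i - 1], lam[i]
        if li <= 0 or li / lam[0] < tau:
            continue
        ratio = np.inf if lnext <= 0 else li / lnext
        # strict > keeps the smallest i on exact ties
        if best_i is None or ratio > best_ratio:
            best_i, best_ratio = i, ratio
    if best_i is None:
        warnings.warn(
            f"no admissible embedding dimension in [{r_min}, {hi}] "
            f"(all lambda_i/lambda_1 < tau={tau}); falling back to r={r_min}",
            stacklevel=2,
        )
        return r_min
    return best_i


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _scale_columns(V: np.ndarray, lam: np.ndarray, mode: str) -> np.ndarray:
    lam = np.clip(lam, 0.0, None)
    if mode == "sqrt_eigenvalue":
        return V * np.sqrt(lam)
    if mode == "eigenvalue":
        return V * lam
    raise ParameterError(f"unknown scaling_mode {mode!r}")


def embed(B: np.ndarray, r: int, scaling_mode: str = "sqrt_eigenvalue") -> Embedding:
    """Top-r spectral embedding of a double-centered matrix B."""
    B = np.asarray(B, dtype=float)
    if r < 1:
        raise ParameterError(f"r must be >= 1, got {r}")
    lam, V = np.linalg.eigh(B)
    lam, V = lam[::-1], V[:, ::-1]  # descending
    # positive up to spectral rounding noise
    n_pos = int(np.sum(lam > 1e-12 * max(lam[0], 0.0) * len(lam)))
    if r > n_pos:
        if n_pos == 0:  # B = 0: legitimate degenerate input, all-zero embedding
            lam_r, V_r = lam[:r], V[:, :r]
        else:
            warnings.warn(
                f"r={r} exceeds the {n_pos} positive eigenvalues; reducing",
                stacklevel=2,
            )
            r, lam_r, V_r = n_pos, lam[:n_pos], V[:, :n_pos]
    else:
        lam_r, V_r = lam[:r], V[:, :r]
    Y = _scale_columns(_fix_signs(V_r), lam_r, scaling_mode)
    return Embedding(coordinates=Y, eigenvalues=lam, r=r, scaling_mode=scaling_mode)


def embed_distances(
    D,
    r: int | None = None,
    r_min: int = 3,
    r_max: int = 39,
    tau: float = 0.01,
    scaling_mode: str = "sqrt_eigenvalue",
) -> Embedding:
    """Full classical MDS of a distance matrix with automatic r selection."""
    B = double_center(D)
    lam = np.linalg.eigvalsh(B)[::-1]
    if r is None:
        r = select_dimension(lam, r_min=r_min, r_max=min(r_max, len(lam) - 1), tau=tau)
    return embed(B, r, scaling_mode=scaling_mode)


def landmark_embed(
    D_landmarks: PathDistanceMatrix,
    r: int | None = None,
    r_min: int = 3,
    r_max: int = 39,
    tau: float = 0.01,
    scaling_mode: str = "sqrt_eigenvalue",
) -> Embedding:
    """Landmark MDS: full MDS on the q x q landmark block, triangulate the rest.

    Every point j (landmarks included) is placed from its squared
    distances delta_j to the landmarks via

        y_j = -1/2 Lambda^{-1/2} V^T (delta_j - mean_column(Delta^(2))),

    which for a landmark reproduces its block-MDS coordinate exactly, so
    q = n recovers full classical MDS.
    """
    if not D_landmarks.is_landmark:
        raise ParameterError("landmark_embed requires a landmark distance matrix")
    q, n = D_landmarks.values.shape
    block = D_landmarks.values[:, D_landmarks.landmark_indices]
    B = double_center(block)
    lam_full = np.linalg.eigvalsh(B)[::-1]
    if r is None:
        r = select_dimension(
            lam_full, r_min=r_min, r_max=min(r_max, q - 1), tau=tau
        )
    if q <= r:
        raise ParameterError(f"need q > r landmarks, got q={q}, r={r}")
    lam, V = np.linalg.eigh(B)
    lam, V = lam[::-1][:r], _fix_signs(V[:, ::-1][:, :r])
    n_pos = int(np.sum(lam > 1e-12 * max(lam_full[0], 0.0) * q))
    if n_pos < r:
        warnings.warn(
            f"r={r} exceeds the {n_pos} positive landmark eigenvalues; reducing",
            stacklevel=2,
        )
        r, lam, V = n_pos, lam[:n_pos], V[:, :n_pos]
    if not np.all(np.isfinite(D_landmarks.values)):
        raise ValueError("landmark distances contain infinite entries")
    sq = D_landmarks.values**2  # q x n
    centered = -0.5 * (sq - (block**2).mean(axis=1, keepdims=True))
    # sqrt-eigenvalue coordinates from the triangulation formula
    Y = (V / np.sqrt(lam)).T @ centered  # r x n
    Y = Y.T
    if scaling_mode == "eigenvalue":
        Y = Y * np.sqrt(lam)
    elif scaling_mode != "sqrt_eigenvalue":
        raise ParameterError(f"unknown scaling_mode {scaling_mode!r}")
    return Embedding(
        coordinates=Y, eigenvalues=lam_full, r=r, scaling_mode=scaling_mode
    )
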