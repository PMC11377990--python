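"""K-nearest-neighbour graphs and normalized Laplacians.

The dense GIP similarity matrices are sparsified through a mutual-KNN mask
before being used as manifold regularizers: an edge weight survives in full
when the two nodes are in each other's K-neighbourhoods, at half weight when
the relation is one-sided, and is dropped otherwise.  The resulting weight
matrix feeds a symmetric normalized Laplacian D^(-1/2) (D - W) D^(-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "GraphRegularizers",
    "knn_mask",
    "sparsify",
    "normalized_laplacian",
    "build_graph_regularizers",
]


@dataclass
class GraphRegularizers:
    """KNN masks, sparsified weights and normalized Laplacians for both sides."""

    K: int
    Nm: np.ndarray
    Nd: np.ndarray
    GM_hat: np.ndarray
    GD_hat: np.ndarray
    Lm_tilde: np.ndarray
    Ld_tilde: np.ndarray


def knn_mask(S: np.ndarray, K: int) -> np.ndarray:
    """Mutual/one-sided K-nearest-neighbour mask with entries in {0, 0.5, 1}.

    ``NK(i)`` is the set of K largest off-diagonal entries of row ``i`` (self
    excluded, ties broken towards the lower index).  The mask entry is 1 when
    each node is in the other's neighbourhood, 0 when neither is, and 0.5
    when the relation is one-sided.  The diagonal is 0.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ParameterError("similarity matrix must be square")
    if K <= 0:
        raise ParameterError(f"K must be positive, got {K}")
    if K >= n:
        raise ParameterError(f"K={K} must be smaller than the number of nodes n={n}")
    work = S.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort of -S breaks ties towards the lower index
    order = np.argsort(-work, axis=1, kind="stable")
    member = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), K)
    member[rows, order[:, :K].ravel()] = True
    mask = np.where(member & member.T, 1.0, np.where(member | member.T, 0.5, 0.0))
    np.fill_diagonal(mask, 0.0)
    return mask


def sparsify(S: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product of similarity and KNN mask (sparsified weights)."""
    S = np.asarray(S, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if S.shape != mask.shape:
        raise ParameterError(f"shape mismatch: S {S.shape} vs mask {mask.shape}")
    return S * mask


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian ``D^(-1/2) (D - W) D^(-1/2)``.

    Zero-degree nodes use the pseudo-inverse convention ``D^(-1/2) = 0``, so
    their Laplacian row and column are identically zero.  For a symmetric
    non-negative ``W`` the result is symmetric PSD with eigenvalues in [0, 2].
    """
    W = np.asarray(W, dtype=float)
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.diag(deg) - W
    Lt = dinv_sqrt[:, None] * L * dinv_sqrt[None, :]
    return 0.5 * (Lt + Lt.T)


def build_graph_regularizers(GM: np.ndarray, GD: np.ndarray, K: int) -> GraphRegularizers:
    """Build masks, sparsified weights and normalized Laplacians for both sides."""
    Nm = knn_mask(GM, K)
    Nd = knn_mask(GD, K)
    GM_hat = sparsify(GM, Nm)
    GD_hat = sparsify(GD, Nd)
    return GraphRegularizers(
        K=K,
        Nm=Nm,
        Nd=Nd,
        GM_hat=GM_hat,
        GD_hat=GD_hat,
        Lm_tilde=normalized_laplacian(GM_hat),
        Ld_tilde=normalized_laplacian(GD_hat),
    )
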