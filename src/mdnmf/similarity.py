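"""Gaussian interaction profile (GIP) kernel similarity.

Two entities that interact with similar partner sets are assigned high
similarity: for binary interaction profiles ``IP_i`` (rows of the
association matrix for microbes, columns for diseases)

    S[i, j] = exp(-gamma * ||IP_i - IP_j||^2),
    gamma   = gamma' / mean_i ||IP_i||^2,

so the bandwidth adapts to the average profile density.  With binary
profiles ``||IP_i - IP_j||^2`` is the Hamming distance between the two
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import DegenerateInputError
from .io import AssociationData

__all__ = ["GipKernels", "interaction_profiles", "gip_kernel", "gip_kernels", "write_kernel"]


@dataclass
class GipKernels:
    """GIP similarity matrices for both sides of the bipartite network.

    ``GM`` is microbe x microbe, ``GD`` disease x disease; ``gamma_m`` /
    ``gamma_d`` are the normalized bandwidths actually used, derived from the
    raw bandwidths ``gamma_m_prime`` / ``gamma_d_prime`` (default 1).
    """

    GM: np.ndarray
    GD: np.ndarray
    gamma_m: float
    gamma_d: float
    gamma_m_prime: float = 1.0
    gamma_d_prime: float = 1.0


def interaction_profiles(data: AssociationData) -> tuple[np.ndarray, np.ndarray]:
    """Microbe profiles (rows of A) and disease profiles (columns of A)."""
    return data.A.copy(), data.A.T.copy()


def gip_kernel(profiles: np.ndarray, gamma_prime: float = 1.0) -> tuple[np.ndarray, float]:
    """Gaussian interaction profile kernel over a set of profiles.

    Parameters
    ----------
    profiles : ndarray of shape (n, p)
        One interaction profile per row.
    gamma_prime : float
        Raw bandwidth; the effective bandwidth is
        ``gamma_prime / mean_i ||profile_i||^2``.

    Returns
    -------
    S : ndarray of shape (n, n)
        Symmetric similarity matrix with unit diagonal, entries in (0, 1].
    gamma : float
        The effective bandwidth used.

    Raises
    ------
    DegenerateInputError
        If every profile is all-zero (the bandwidth denominator vanishes).
        A *single* all-zero profile among non-zero ones is fine — this is
        exactly the state produced by masking out one entity's associations.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise DegenerateInputError("need at least one profile")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise DegenerateInputError("all interaction profiles are zero; bandwidth undefined")
    gamma = gamma_prime / mean_sq_norm
    if profiles.shape[0] == 1:
        return np.ones((1, 1)), gamma
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    S = np.exp(-gamma * sq_dists)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S, gamma


def gip_kernels(
    data: AssociationData, gamma_m_prime: float = 1.0, gamma_d_prime: float = 1.0
) -> GipKernels:
    """GIP kernels for the microbe side and the disease side of ``data``."""
    mp, dp = interaction_profiles(data)
    GM, gamma_m = gip_kernel(mp, gamma_m_prime)
    GD, gamma_d = gip_kernel(dp, gamma_d_prime)
    return GipKernels(GM, GD, gamma_m, gamma_d, gamma_m_prime, gamma_d_prime)


def write_kernel(S: np.ndarray, names: list[str], path) -> None:
    """Export a square similarity matrix as TSV with names as header/index."""
    n = len(names)
    if S.shape != (n, n):
        raise DegenerateInputError(f"kernel shape {S.shape} does not match {n} names")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            fh.write(name + "\t" + "\t".join(f"{v:.17g}" for v in S[i]) + "\n")
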