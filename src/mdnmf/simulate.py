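"""Synthetic association matrices with planted low-rank block structure.

Real microbe-disease catalogues are sparse binary bipartite networks in
which communities of microbes share disease spectra.  The generator plants
that structure directly: microbes and diseases are partitioned into
``n_blocks`` co-clusters and a pair is associated with probability
``within_block_prob`` inside its co-cluster and ``background_prob``
elsewhere.  Setting the two probabilities equal yields a structureless null
matrix for calibration runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .io import AssociationData

__all__ = ["PlantedConfig", "planted_blocks", "planted_exact", "hmdad_shaped", "disbiome_shaped", "block_labels"]


@dataclass
class PlantedConfig:
    """Planted co-cluster model parameters.

    ``within_block_prob >= background_prob``; equality gives the null model
    (no planted signal).
    """

    m: int = 20
    d: int = 10
    n_blocks: int = 2
    within_block_prob: float = 0.6
    background_prob: float = 0.02
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        for p in (self.within_block_prob, self.background_prob):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if self.within_block_prob < self.background_prob:
            raise ParameterError("within_block_prob must be >= background_prob")
        if self.n_blocks < 1 or self.n_blocks > min(self.m, self.d):
            raise ParameterError("n_blocks out of range")


def block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous block assignment of n items into n_blocks near-equal parts."""
    return np.concatenate(
        [np.full(len(part), b) for b, part in enumerate(np.array_split(np.arange(n), n_blocks))]
    )


def _names(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _within_mask(cfg: PlantedConfig, rng: np.random.Generator) -> np.ndarray:
    mb = block_labels(cfg.m, cfg.n_blocks)
    db = block_labels(cfg.d, cfg.n_blocks)
    if cfg.shuffle:
        mb = rng.permutation(mb)
        db = rng.permutation(db)
    return mb[:, None] == db[None, :]


def planted_blocks(cfg: PlantedConfig) -> AssociationData:
    """Bernoulli sample from the planted co-cluster model (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    within = _within_mask(cfg, rng)
    p = np.where(within, cfg.within_block_prob, cfg.background_prob)
    A = (rng.random((cfg.m, cfg.d)) < p).astype(float)
    return AssociationData(_names("m", cfg.m), _names("d", cfg.d), A)


def planted_exact(
    m: int, d: int, n_blocks: int, n_ones: int, seed: int = 0
) -> AssociationData:
    """Planted matrix with an exact association count.

    Ones are sampled without replacement from within-block pairs first
    (shuffled), overflowing into background pairs only when the blocks are
    exhausted, so the planted signal is as strong as the count allows.
    """
    if not 0 < n_ones <= m * d:
        raise ParameterError(f"n_ones={n_ones} out of range (1, {m * d}]")
    rng = np.random.default_rng(seed)
    cfg = PlantedConfig(m=m, d=d, n_blocks=n_blocks, within_block_prob=1.0,
                        background_prob=0.0, seed=seed)
    within = _within_mask(cfg, rng)
    inside = np.flatnonzero(within.ravel())
    outside = np.flatnonzero(~within.ravel())
    picked = rng.permutation(inside)[:n_ones]
    if n_ones > inside.size:
        extra = rng.permutation(outside)[: n_ones - inside.size]
        picked = np.concatenate([picked, extra])
    A = np.zeros(m * d)
    A[picked] = 1.0
    return AssociationData(_names("m", m), _names("d", d), A.reshape(m, d))


def hmdad_shaped(seed: int = 0) -> AssociationData:
    """292 microbes x 39 diseases with exactly 450 associations (density 3.95%),
    drawn from a 4-block planted model."""
    return planted_exact(292, 39, 4, 450, seed)


def disbiome_shaped(seed: int = 0) -> AssociationData:
    """1052 microbes x 218 diseases with exactly 4351 associations (density
    1.90%), drawn from a 6-block planted model."""
    return planted_exact(1052, 218, 6, 4351, seed)
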