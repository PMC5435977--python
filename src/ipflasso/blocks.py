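"""Block (modality) structure and per-modality penalty factors.

A *block* is a group of predictor columns sharing one data modality
(e.g. clinical covariates, gene expression, methylation).  Each block m
carries a penalty factor lam_m / lam_1 relative to the first (reference)
block; the vector of factors is invariant under multiplication by a
positive scalar, so its canonical form has first entry 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BlockStructure:
    """Partition of the p predictor columns into M disjoint modalities.

    Parameters
    ----------
    blocks : list of integer index arrays (0-based), disjoint, covering 0..p-1.
    names : optional block labels; defaults to block1..blockM.
    """

    blocks: tuple
    names: tuple = ()

    def __init__(self, blocks, names=None):
        blocks = tuple(np.asarray(b, dtype=np.intp) for b in blocks)
        if len(blocks) == 0:
            raise ValueError("need at least one block")
        for b in blocks:
            if b.size == 0:
                raise ValueError("empty block")
        all_idx = np.concatenate(blocks)
        p = all_idx.size
        uniq, counts = np.unique(all_idx, return_counts=True)
        if uniq.size != p:
            dup = uniq[counts > 1][0]
            raise ValueError(
                f"blocks overlap (column {dup + 1}, 1-based, appears in more than one block)"
            )
        if all_idx.min() != 0 or all_idx.max() != p - 1:
            raise ValueError("blocks must cover exactly columns 0..p-1")
        if names is None:
            names = tuple(f"block{i + 1}" for i in range(len(blocks)))
        else:
            names = tuple(names)
            if len(names) != len(blocks):
                raise ValueError("one name per block required")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "names", names)

    @classmethod
    def from_sizes(cls, sizes, names=None) -> "BlockStructure":
        """Contiguous blocks of the given sizes, in column order."""
        sizes = [int(s) for s in sizes]
        edges = np.cumsum([0] + sizes)
        return cls([np.arange(edges[i], edges[i + 1]) for i in range(len(sizes))], names)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_features(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.blocks])

    def membership(self) -> np.ndarray:
        """Length-p vector giving the block index of each column."""
        m = np.empty(self.n_features, dtype=np.intp)
        for i, b in enumerate(self.blocks):
            m[b] = i
        return m

    def expand(self, per_block: np.ndarray) -> np.ndarray:
        """Spread a length-M vector to a length-p per-feature vector."""
        per_block = np.asarray(per_block, dtype=float)
        if per_block.shape != (self.n_blocks,):
            raise ValueError("need one value per block")
        return per_block[self.membership()]


@dataclass(frozen=True)
class PenaltyFactors:
    """Positive per-modality penalty multipliers (lam_m / lam_1).

    Multiplying all factors by a positive scalar leaves the fitted model
    unchanged; :meth:`canonical` fixes the scale by dividing by the first
    entry so the reference modality has factor exactly 1.
    """

    factors: np.ndarray

    def __init__(self, factors):
        factors = np.asarray(factors, dtype=float).copy()
        if factors.ndim != 1 or factors.size == 0:
            raise ValueError("factors must be a non-empty 1-d vector")
        if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
            raise ValueError("all penalty factors must be finite and > 0")
        factors.flags.writeable = False
        object.__setattr__(self, "factors", factors)

    def canonical(self) -> "PenaltyFactors":
        return PenaltyFactors(self.factors / self.factors[0])

    @property
    def n_blocks(self) -> int:
        return self.factors.size

    def per_feature(self, blocks: BlockStructure) -> np.ndarray:
        """Per-column penalty weights w_j = pf_m for column j in block m."""
        if self.n_blocks != blocks.n_blocks:
            raise ValueError("penalty factor length must match block count")
        return blocks.expand(self.canonical().factors)

    def __eq__(self, other):
        return isinstance(other, PenaltyFactors) and np.array_equal(self.factors, other.factors)

    def __repr__(self):
        return f"PenaltyFactors({np.array2string(self.factors, separator=', ')})"


def pow2_candidates(kmin: int = -3, kmax: int = 3) -> list:
    """Two-modality candidate grid (1, 2^k), k = kmin..kmax.

    The default range k in {-3,...,3} yields 7 candidates, including the
    uniform-penalty vector (1, 1) at k = 0.
    """
    return [PenaltyFactors([1.0, 2.0 ** k]) for k in range(kmin, kmax + 1)]
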