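"""Block-truncation-coding intensity features and inter-block similarity.

The coarse detection stage summarizes each subblock by a 4-vector of
conditional intensity means obtained by thresholding the block twice: first
at its grand mean, then each side at its own side-mean.  The similarity
``S`` between two blocks is the normalized correlation of their
mean-absolute-deviation profiles; it is invariant to adding a constant to
either block, which is what makes it useful under drifting illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BlockFeature:
    """BTC intensity feature of one subblock.

    ``mu_ht >= mu_hb >= mu >= mu_lt >= mu_lb`` always holds; ``mu``,
    ``mu_h`` and ``mu_l`` are the intermediate thresholds, kept for
    diagnostics.
    """

    mu_ht: float
    mu_hb: float
    mu_lt: float
    mu_lb: float
    mu: float
    mu_h: float
    mu_l: float

    @property
    def vector(self) -> np.ndarray:
        """The 4-component feature (mu_ht, mu_hb, mu_lt, mu_lb)."""
        return np.array([self.mu_ht, self.mu_hb, self.mu_lt, self.mu_lb])


def btc_feature(block: np.ndarray) -> BlockFeature:
    """Compute the BTC feature vector of an intensity block.

    Pixels >= the block mean form the high side, the rest the low side;
    each side is split again at its own mean (>= goes up).  Degenerate
    blocks collapse: an all-equal block yields four copies of the mean, and
    a side whose pixels are all equal yields two copies of the side mean.
    """
    x = np.asarray(block, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty block")
    mu = float(x.mean())
    if np.ptp(x) == 0.0:
        return BlockFeature(mu, mu, mu, mu, mu, mu, mu)
    high = x[x >= mu]
    low = x[x < mu]
    mu_h = float(high.mean())
    mu_l = float(low.mean())
    if np.ptp(high) == 0.0:
        mu_ht = mu_hb = mu_h
    else:
        mu_ht = float(high[high >= mu_h].mean())
        mu_hb = float(high[high < mu_h].mean())
    if np.ptp(low) == 0.0:
        mu_lt = mu_lb = mu_l
    else:
        mu_lt = float(low[low >= mu_l].mean())
        mu_lb = float(low[low < mu_l].mean())
    return BlockFeature(mu_ht, mu_hb, mu_lt, mu_lb, mu, mu_h, mu_l)


def block_similarity(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Similarity S in [0, 1] of the intensity structure of two blocks.

    Each block is reduced to the vector of absolute deviations of its pixels
    (raster order) from the block mean; S is the cosine of the angle between
    the two deviation vectors.  Two constant blocks are defined maximally
    similar (S = 1); a constant block against a non-constant one is
    maximally dissimilar (S = 0).
    """
    a = np.asarray(block_a, dtype=float).ravel()
    b = np.asarray(block_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("blocks must have the same shape")
    u_a = np.abs(a - a.mean())
    u_b = np.abs(b - b.mean())
    na = np.linalg.norm(u_a)
    nb = np.linalg.norm(u_b)
    if na == 0.0 and nb == 0.0:
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(min(abs(u_a @ u_b) / (na * nb), 1.0))
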