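"""Per-pixel texture background model (fine stage).

Inside the rough object region each pixel keeps a FIFO of its last K
background texture patterns.  A pixel whose current pattern is close (in
bit-vector Euclidean distance, i.e. the square root of the Hamming
distance) to any remembered pattern is background and refreshes the FIFO;
anything else — including a pixel seen inside the rough region for the
first time, which has no temporal evidence yet — is object and leaves the
model untouched.

Two equivalent implementations are provided: a scalar, object-per-pixel API
(:class:`PixelTextureModel` and friends) that states the contract, and
:class:`PixelModelGrid`, a vectorized whole-frame version used by the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lbp import TexturePattern

BACKGROUND = "background"
OBJECT = "object"


@dataclass
class PixelStageConfig:
    """Tunables of the fine stage.

    K
        Texture-history depth per pixel.
    T_D
        Distance threshold: background iff some stored pattern is at
        bit-vector Euclidean distance < T_D.  The default 1.2 accepts
        patterns differing in at most 1 bit (1 < 1.2 < sqrt(2)).
    """

    K: int = 3
    T_D: float = 1.2

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.T_D <= 0:
            raise ValueError("T_D must be positive")


@dataclass
class PixelTextureModel:
    """FIFO of recent background texture patterns at one pixel (newest first)."""

    history: list[TexturePattern] = field(default_factory=list)
    initialized_at: int = -1


def texture_distance(h: TexturePattern, h_j: TexturePattern) -> float:
    """Euclidean distance between two patterns' bit vectors (= sqrt(Hamming))."""
    if h.P != h_j.P:
        raise ValueError(f"pattern lengths differ: {h.P} vs {h_j.P}")
    return float(np.sqrt(sum((a - b) ** 2 for a, b in zip(h.bits, h_j.bits))))


def classify_pixel(
    model: PixelTextureModel,
    h: TexturePattern,
    cfg: PixelStageConfig,
    frame_index: int | None = None,
) -> str:
    """Label a pixel from its texture pattern.

    Background iff the minimum distance from ``h`` to a stored pattern is
    below ``cfg.T_D``.  A model whose only history entry comes from this
    frame's own initialization carries no temporal evidence and classifies
    as object.
    """
    if not model.history:
        raise ValueError("pixel model has empty history")
    if (
        frame_index is not None
        and model.initialized_at == frame_index
        and len(model.history) == 1
    ):
        return OBJECT
    d_min = min(texture_distance(h, entry) for entry in model.history)
    return BACKGROUND if d_min < cfg.T_D else OBJECT


def update_pixel_model(
    model: PixelTextureModel, h: TexturePattern, cfg: PixelStageConfig
) -> PixelTextureModel:
    """FIFO-insert ``h`` (newest first), dropping the oldest at capacity.

    Call only for pixels classified background this frame; object pixels
    never refresh their history.
    """
    model.history = [h] + model.history[: cfg.K - 1]
    return model


class PixelModelGrid:
    """Vectorized per-pixel texture models for a whole frame.

    Stores LBP codes as integers and computes bit distances via popcount of
    XOR, which is exactly the squared bit-vector Euclidean distance of the
    scalar API.
    """

    def __init__(self, shape: tuple[int, int], cfg: PixelStageConfig):
        self.cfg = cfg
        self.shape = shape
        self.history = np.zeros((cfg.K,) + shape, dtype=np.uint32)
        self.depth = np.zeros(shape, dtype=np.int16)  # valid history length

    def initialize(self, codes: np.ndarray) -> None:
        """Seed every pixel's history with its first-frame texture pattern.

        Giving each pixel a genuine background pattern up front means an
        arriving object is compared against remembered background texture
        rather than against itself.
        """
        if codes.shape != self.shape:
            raise ValueError("code shape does not match model grid")
        self.history[0] = codes.astype(np.uint32)
        self.depth[:] = 1

    def observe(
        self, rough_mask: np.ndarray, codes: np.ndarray, frame_index: int
    ) -> np.ndarray:
        """Process one frame's rough object region; return the refined object mask.

        Pixels outside ``rough_mask`` are untouched (their models persist, so
        re-entry into a later rough region is warm).  Inside it, pixels with
        no model yet are initialized from the current pattern and flagged
        object; the rest classify against their history, and only
        background-classified pixels push the current pattern into the FIFO.
        """
        rough_mask = np.asarray(rough_mask, dtype=bool)
        if rough_mask.shape != self.shape or codes.shape != self.shape:
            raise ValueError("mask/code shape does not match model grid")
        codes = codes.astype(np.uint32)

        fresh = rough_mask & (self.depth == 0)
        seen = rough_mask & (self.depth > 0)

        # threshold on squared distance = number of differing bits
        max_bits = int(np.floor(self.cfg.T_D**2))
        if self.cfg.T_D**2 == max_bits:  # strict inequality D < T_D
            max_bits -= 1
        is_bg = np.zeros(self.shape, dtype=bool)
        if np.any(seen):
            d2_min = np.full(self.shape, np.iinfo(np.int32).max, dtype=np.int64)
            for k in range(self.cfg.K):
                valid = seen & (self.depth > k)
                if not np.any(valid):
                    break
                d2 = np.bitwise_count(codes ^ self.history[k]).astype(np.int64)
                d2_min = np.where(valid & (d2 < d2_min), d2, d2_min)
            is_bg = seen & (d2_min <= max_bits)

        # FIFO push for background pixels
        if np.any(is_bg):
            for k in range(self.cfg.K - 1, 0, -1):
                self.history[k][is_bg] = self.history[k - 1][is_bg]
            self.history[0][is_bg] = codes[is_bg]
            self.depth[is_bg] = np.minimum(self.depth[is_bg] + 1, self.cfg.K)

        # initialize fresh pixels (object this frame, no temporal evidence)
        if np.any(fresh):
            self.history[0][fresh] = codes[fresh]
            self.depth[fresh] = 1

        return rough_mask & ~is_bg
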