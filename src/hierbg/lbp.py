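"""Moderated local binary pattern (LBP) texture features.

The fine detection stage describes each pixel by the signs of the
differences between P neighbors sampled on a circle of radius R and the
center pixel.  Because near-flat underwater regions make those differences
hover around zero, a moderation offset ``beta`` is added inside the sign so
that ties and tiny negative differences count as "not darker"; the
resulting P-bit code is invariant to adding any constant to the whole
image, which is the property that makes the descriptor robust to
illumination drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class LBPConfig:
    """Neighborhood geometry and moderation offset of the LBP operator."""

    P: int = 16
    R: float = 2.0
    beta: float = 3.0

    def __post_init__(self):
        if self.P < 4:
            raise ValueError("P must be >= 4")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class TexturePattern:
    """A P-bit texture code with its bit vector (bit p weighted 2**p)."""

    bits: tuple[int, ...]

    @property
    def P(self) -> int:
        return len(self.bits)

    @property
    def code(self) -> int:
        return int(sum(b << p for p, b in enumerate(self.bits)))

    @classmethod
    def from_code(cls, code: int, P: int) -> "TexturePattern":
        if not 0 <= code < (1 << P):
            raise ValueError(f"code {code} out of range for P={P}")
        return cls(tuple((code >> p) & 1 for p in range(P)))


def neighbor_offsets(P: int, R: float) -> np.ndarray:
    """(dx, dy) sampling offsets for neighbor p at angle 2*pi*p/P.

    Sampling starts east of the center and proceeds counterclockwise
    (y grows downward, so dy = -R sin(theta)).  The canonical P=8, R=1
    configuration uses the classical 3x3 integer neighborhood
    (E, NE, N, NW, W, SW, S, SE); otherwise offsets are exact circle
    positions with coordinates within 1e-9 of an integer snapped to it.
    """
    if P == 8 and R == 1:
        return np.array(
            [(1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1)],
            dtype=float,
        )
    offs = np.empty((P, 2))
    for p in range(P):
        theta = 2.0 * math.pi * p / P
        offs[p] = (R * math.cos(theta), -R * math.sin(theta))
    near = np.round(offs)
    snap = np.abs(offs - near) < 1e-9
    offs[snap] = near[snap]
    return offs


def sample_neighbors(frame: np.ndarray, x: int, y: int, P: int, R: float) -> np.ndarray:
    """Intensities of the P circle neighbors of pixel (x=col, y=row).

    Off-grid positions are bilinearly interpolated; positions outside the
    frame read from an edge-replicated extension.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if not (0 <= y < h and 0 <= x < w):
        raise ValueError(f"center ({x}, {y}) outside frame of shape {frame.shape}")
    offs = neighbor_offsets(P, R)
    rows = y + offs[:, 1]
    cols = x + offs[:, 0]
    return map_coordinates(frame, [rows, cols], order=1, mode="nearest")


def sign_indicator(diff: float, beta: float) -> int:
    """Moderated sign bit s(diff + beta): 1 if diff + beta >= 0, else 0."""
    return 1 if diff + beta >= 0 else 0


def lbp_pattern(frame: np.ndarray, x: int, y: int, cfg: LBPConfig) -> TexturePattern:
    """Moderated LBP texture pattern of pixel (x=col, y=row)."""
    g_c = float(np.asarray(frame, dtype=float)[y, x])
    neighbors = sample_neighbors(frame, x, y, cfg.P, cfg.R)
    bits = tuple(sign_indicator(g_p - g_c, cfg.beta) for g_p in neighbors)
    return TexturePattern(bits)


def lbp_codes(frame: np.ndarray, cfg: LBPConfig) -> np.ndarray:
    """Moderated LBP codes of every pixel of ``frame`` (vectorized).

    Returns a (H, W) uint32 array; entry (y, x) equals
    ``lbp_pattern(frame, x, y, cfg).code``.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    offs = neighbor_offsets(cfg.P, cfg.R)
    pad = int(math.ceil(cfg.R))
    padded = np.pad(frame, pad, mode="edge")
    codes = np.zeros((h, w), dtype=np.uint32)
    integral = np.all(offs == np.round(offs))
    if integral:
        ioffs = offs.astype(int)
        for p, (dx, dy) in enumerate(ioffs):
            neigh = padded[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
            codes |= ((neigh - frame + cfg.beta) >= 0).astype(np.uint32) << np.uint32(p)
    else:
        rr, cc = np.mgrid[0:h, 0:w]
        for p, (dx, dy) in enumerate(offs):
            neigh = map_coordinates(
                frame, [rr.ravel() + dy, cc.ravel() + dx], order=1, mode="nearest"
            ).reshape(h, w)
            codes |= ((neigh - frame + cfg.beta) >= 0).astype(np.uint32) << np.uint32(p)
    return codes
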