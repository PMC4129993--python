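"""Frame-sequence I/O and the nonoverlapping subblock grid.

Frames are held as 2-D ``float64`` arrays of grayscale intensities on the
8-bit [0, 255] scale; binary masks are 2-D boolean arrays of the same shape.
Quantization to integers happens only when writing to disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

_FRAME_EXTENSIONS = {".png", ".pgm", ".ppm", ".pbm", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

#: BT.601 luma weights for R, G, B.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(color_frame: np.ndarray) -> np.ndarray:
    """Convert a 3-channel (H, W, 3) raster to a grayscale intensity frame.

    Uses the BT.601 luma combination 0.299 R + 0.587 G + 0.114 B and clips
    to [0, 255].
    """
    arr = np.asarray(color_frame, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a (H, W, 3) array, got shape {arr.shape}")
    return np.clip(arr @ _LUMA_WEIGHTS, 0.0, 255.0)


def _natural_key(name: str) -> tuple:
    """Sort key that orders embedded integers numerically (f2 < f10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _as_frame(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            return to_grayscale(arr)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as a frame")
    return np.clip(arr.astype(float), 0.0, 255.0)


def load_sequence(path: str | Path) -> list[np.ndarray]:
    """Load an ordered frame sequence.

    ``path`` may be a directory of numbered raster images (ordered by a
    numeric-aware sort of their filenames) or a single multi-frame container
    (e.g. an animated GIF or multi-page TIFF).  Color frames are converted
    with :func:`to_grayscale`.

    Raises ``FileNotFoundError`` for a missing path and ``ValueError`` for
    empty input or frames of inconsistent shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in _FRAME_EXTENSIONS),
            key=lambda f: _natural_key(f.name),
        )
        if not files:
            raise ValueError(f"no raster frames found in {path}")
        frames = [_as_frame(iio.imread(f)) for f in files]
    else:
        try:
            frames = [_as_frame(a) for a in iio.imiter(path)]
        except Exception:
            frames = [_as_frame(iio.imread(path))]
        if not frames:
            raise ValueError(f"no frames readable from {path}")
    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise ValueError(f"frame {i} has shape {f.shape}, expected {shape}")
    return frames


@dataclass
class BlockGrid:
    """A frame tiled into nonoverlapping M x N subblocks.

    The source frame is edge-replicated up to the next multiple of the block
    size; ``pad_rows``/``pad_cols`` record how much padding was added so that
    masks built at block resolution can be cropped back to the frame.
    """

    blocks: np.ndarray  # (grid_h, grid_w, M, N)
    block_height: int
    block_width: int
    pad_rows: int
    pad_cols: int
    frame_height: int
    frame_width: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.blocks.shape[:2]


def partition_blocks(frame: np.ndarray, block_height: int, block_width: int) -> BlockGrid:
    """Partition ``frame`` into nonoverlapping ``block_height x block_width`` tiles.

    The frame is padded by edge replication (last row/column repeated) up to
    the next multiple of the block size, so border blocks carry no artificial
    high-contrast structure.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a nonempty 2-D array")
    if block_height < 2 or block_width < 2:
        raise ValueError("block size must be at least 2 x 2")
    h, w = frame.shape
    gh = -(-h // block_height)
    gw = -(-w // block_width)
    pad_rows = gh * block_height - h
    pad_cols = gw * block_width - w
    padded = np.pad(frame, ((0, pad_rows), (0, pad_cols)), mode="edge")
    blocks = padded.reshape(gh, block_height, gw, block_width).swapaxes(1, 2)
    return BlockGrid(
        blocks=blocks,
        block_height=block_height,
        block_width=block_width,
        pad_rows=pad_rows,
        pad_cols=pad_cols,
        frame_height=h,
        frame_width=w,
    )


def reassemble(grid: BlockGrid) -> np.ndarray:
    """Invert :func:`partition_blocks`, cropping any padding."""
    gh, gw = grid.grid_shape
    padded = grid.blocks.swapaxes(1, 2).reshape(
        gh * grid.block_height, gw * grid.block_width
    )
    return padded[: grid.frame_height, : grid.frame_width]


def upsample_block_labels(labels: np.ndarray, grid: BlockGrid) -> np.ndarray:
    """Paint each block's boolean label over its M x N pixels, cropped to frame size."""
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != grid.grid_shape:
        raise ValueError("label grid does not match block grid shape")
    full = np.repeat(
        np.repeat(labels, grid.block_height, axis=0), grid.block_width, axis=1
    )
    return full[: grid.frame_height, : grid.frame_width]


def write_masks(masks, path: str | Path, prefix: str = "mask") -> list[Path]:
    """Write binary masks as 8-bit PNGs (0 = background, 255 = foreground)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, mask in enumerate(masks):
        out = path / f"{prefix}_{i:05d}.png"
        iio.imwrite(out, (np.asarray(mask, dtype=bool) * np.uint8(255)))
        written.append(out)
    return written


def load_masks(path: str | Path) -> list[np.ndarray]:
    """Read masks written by :func:`write_masks` back as boolean arrays."""
    return [f > 127 for f in load_sequence(path)]
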