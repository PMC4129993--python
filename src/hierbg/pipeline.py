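"""Hierarchical detector: coarse block stage feeding a fine pixel stage.

Per frame, every subblock is classified against its weighted multi-vector
intensity model; the union of object-labeled blocks is the rough object
region.  Only inside that region are per-pixel LBP texture models consulted
to carve the accurate object contour.  Background regions identified by the
block stage are trusted outright: they get no pixel processing and their
pixel models are left untouched, and block models themselves only absorb
appearance when they are labeled background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import binary_opening

from .blocks import OBJECT, BlockModel, BlockModelConfig, classify_and_update, init_model
from .btc import btc_feature
from .frames import BlockGrid, partition_blocks, upsample_block_labels
from .lbp import LBPConfig, lbp_codes
from .pixels import PixelModelGrid, PixelStageConfig


@dataclass
class DetectorConfig:
    """Full configuration of the hierarchical detector."""

    block_height: int = 8
    block_width: int = 8
    block: BlockModelConfig = field(default_factory=BlockModelConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    pixel: PixelStageConfig = field(default_factory=PixelStageConfig)
    #: optional binary-opening cleanup of the refined mask; off by default
    morphological_cleanup: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        cfg = cls()
        blk = dict(d.get("block", {}))
        size = blk.pop("size", None)
        if size is not None:
            cfg.block_height, cfg.block_width = int(size[0]), int(size[1])
        cfg.block = BlockModelConfig(**blk)
        cfg.lbp = LBPConfig(**d.get("lbp", {}))
        cfg.pixel = PixelStageConfig(**d.get("pixel", {}))
        cfg.morphological_cleanup = bool(d.get("morphological_cleanup", False))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class DetectionResult:
    """Per-frame output: block-resolution rough mask and refined pixel mask.

    The refined foreground is always a subset of the rough foreground,
    since the pixel stage only examines the rough object region.
    """

    rough_mask: np.ndarray
    refined_mask: np.ndarray


@dataclass
class DetectorState:
    """All mutable state of the detector between frames."""

    config: DetectorConfig
    frame_shape: tuple[int, int]
    grid: BlockGrid
    block_models: list[list[BlockModel]]
    pixel_grid: PixelModelGrid
    frame_index: int


def init(first_frame: np.ndarray, config: DetectorConfig | None = None) -> tuple[DetectorState, DetectionResult]:
    """Initialize detector state from the first frame.

    Every block model starts with the first frame's feature at full weight,
    so frame 1 is all-background by construction and its result carries
    empty masks.  Every pixel's texture history is seeded with its
    first-frame pattern.
    """
    config = config or DetectorConfig()
    first_frame = np.asarray(first_frame, dtype=float)
    grid = partition_blocks(first_frame, config.block_height, config.block_width)
    gh, gw = grid.grid_shape
    models = [
        [
            init_model(btc_feature(grid.blocks[i, j]), grid.blocks[i, j], config.block)
            for j in range(gw)
        ]
        for i in range(gh)
    ]
    pixel_grid = PixelModelGrid(first_frame.shape, config.pixel)
    pixel_grid.initialize(lbp_codes(first_frame, config.lbp))
    state = DetectorState(
        config=config,
        frame_shape=first_frame.shape,
        grid=grid,
        block_models=models,
        pixel_grid=pixel_grid,
        frame_index=1,
    )
    empty = np.zeros(first_frame.shape, dtype=bool)
    return state, DetectionResult(rough_mask=empty, refined_mask=empty.copy())


def step(state: DetectorState, frame: np.ndarray) -> DetectionResult:
    """Process one frame, updating ``state`` in place.

    All block decisions complete before any pixel processing; the pixel
    stage consumes the finished rough region.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state.frame_shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match detector shape {state.frame_shape}"
        )
    state.frame_index += 1
    t = state.frame_index
    cfg = state.config
    grid = partition_blocks(frame, cfg.block_height, cfg.block_width)
    gh, gw = grid.grid_shape
    labels = np.zeros((gh, gw), dtype=bool)
    for i in range(gh):
        for j in range(gw):
            label = classify_and_update(
                state.block_models[i][j], grid.blocks[i, j], cfg.block, t
            )
            labels[i, j] = label == OBJECT

    rough = upsample_block_labels(labels, grid)
    if np.any(rough):
        codes = lbp_codes(frame, cfg.lbp)
        refined = state.pixel_grid.observe(rough, codes, t)
    else:
        refined = np.zeros_like(rough)
    if cfg.morphological_cleanup and np.any(refined):
        refined = binary_opening(refined, structure=np.ones((3, 3), dtype=bool))
    return DetectionResult(rough_mask=rough, refined_mask=refined)


def detect_sequence(
    frames, config: DetectorConfig | None = None
) -> list[DetectionResult]:
    """Run the detector over an ordered frame sequence.

    Frame 1 initializes the models and emits an all-background result, so
    the output has one result per input frame.  Deterministic: identical
    frames and configuration give bit-identical masks.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    state, first = init(frames[0], config)
    results = [first]
    for frame in frames[1:]:
        results.append(step(state, frame))
    return results
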