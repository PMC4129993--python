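"""Detection-quality criteria and the single-Gaussian per-pixel baseline.

``C_good`` is the fraction of the true object region covered by the
detection (completeness); ``C_false`` is the fraction of the true
background region wrongly detected (false-alarm ratio).  The baseline is
the classic per-pixel running Gaussian background model with selective
update, used as the reference the hierarchical detector is compared
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def c_good(detected: np.ndarray, truth: np.ndarray) -> float:
    """|detected ∩ object| / |object|; undefined (raises) for empty truth."""
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError("mask shapes differ")
    n_obj = int(truth.sum())
    if n_obj == 0:
        raise ValueError("C_good is undefined for an empty true object region")
    return float((detected & truth).sum() / n_obj)


def c_false(detected: np.ndarray, truth: np.ndarray) -> float:
    """|detected ∩ background| / |background|; undefined for empty background."""
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError("mask shapes differ")
    bg = ~truth
    n_bg = int(bg.sum())
    if n_bg == 0:
        raise ValueError("C_false is undefined for an all-foreground truth")
    return float((detected & bg).sum() / n_bg)


@dataclass
class EvalReport:
    """Per-frame (C_good, C_false) pairs and their sequence means.

    ``per_frame`` holds one pair per frame; C_good is NaN on frames whose
    true object region is empty, and such frames are excluded from
    ``mean_c_good`` (but still counted in ``mean_c_false``).
    """

    per_frame: list[tuple[float, float]]
    mean_c_good: float
    mean_c_false: float


def evaluate(detected_masks, truth_masks) -> EvalReport:
    """Score a detected-mask sequence against ground truth."""
    detected_masks = list(detected_masks)
    truth_masks = list(truth_masks)
    if len(detected_masks) != len(truth_masks):
        raise ValueError("detected and truth sequences differ in length")
    per_frame: list[tuple[float, float]] = []
    goods: list[float] = []
    falses: list[float] = []
    for det, tru in zip(detected_masks, truth_masks):
        cf = c_false(det, tru)
        falses.append(cf)
        if np.asarray(tru, dtype=bool).sum() == 0:
            per_frame.append((math.nan, cf))
        else:
            cg = c_good(det, tru)
            goods.append(cg)
            per_frame.append((cg, cf))
    mean_good = float(np.mean(goods)) if goods else math.nan
    mean_false = float(np.mean(falses)) if falses else math.nan
    return EvalReport(per_frame=per_frame, mean_c_good=mean_good, mean_c_false=mean_false)


def gaussian_baseline_detect(
    frames,
    lam: float = 2.5,
    rate: float = 0.05,
    sigma_floor: float = 2.0,
) -> list[np.ndarray]:
    """Classic per-pixel running Gaussian background subtraction.

    Each pixel keeps a mean and variance.  A pixel is foreground when its
    intensity deviates from the mean by more than ``lam`` standard
    deviations; mean and variance follow exponential moving averages (rate
    ``rate``) updated only on background-classified pixels, with the
    variance floored at ``sigma_floor**2``.  The first frame initializes
    the model and emits an all-background mask.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    var_floor = sigma_floor**2
    first = np.asarray(frames[0], dtype=float)
    mean = first.copy()
    var = np.full(first.shape, var_floor)
    masks = [np.zeros(first.shape, dtype=bool)]
    for frame in frames[1:]:
        x = np.asarray(frame, dtype=float)
        if x.shape != first.shape:
            raise ValueError("inconsistent frame shapes")
        resid = x - mean
        fg = np.abs(resid) > lam * np.sqrt(var)
        bg = ~fg
        mean = np.where(bg, (1.0 - rate) * mean + rate * x, mean)
        var = np.where(bg, (1.0 - rate) * var + rate * resid**2, var)
        var = np.maximum(var, var_floor)
        masks.append(fg)
    return masks
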