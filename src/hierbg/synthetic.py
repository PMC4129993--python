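"""Seeded synthetic underwater-like scenes with exact ground-truth masks.

The generator emulates the two factors that make underwater background
subtraction hard — a global illumination drift across the sequence and a
localized, temporally oscillating "ripple" region — plus moving objects
that are deliberately low-contrast in mean intensity but carry strong
fine-scale texture, the regime where intensity-only detectors miss object
parts while texture still carries signal.

Everything is deterministic given the seed; truth masks mark the exact
rendered object support each frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class ObjectSpec:
    """One moving textured object.

    ``shape`` is ``"disk"`` (``size`` = radius in pixels) or ``"rectangle"``
    (``size`` = (height, width)).  ``start`` is the (row, col) center at
    frame 1 and ``velocity`` the per-frame (row, col) displacement.  The
    object's intensity is ``background_mean + intensity_offset +
    texture_contrast * field`` where ``field`` is a unit-variance fine-scale
    random texture rigidly translating with the object.
    """

    shape: str
    size: float | tuple[float, float]
    start: tuple[float, float]
    velocity: tuple[float, float]
    intensity_offset: float = 20.0
    texture_contrast: float = 50.0
    texture_scale: float = 1.0


@dataclass(frozen=True)
class IlluminationSpec:
    """Global illumination drift: ``additive_ramp`` adds a linearly
    interpolated offset (intensity units) from ``start_gain`` to
    ``end_gain``; ``multiplicative_ramp`` multiplies by the interpolated
    gain; ``none`` leaves frames untouched."""

    mode: str = "none"
    start_gain: float = 0.0
    end_gain: float = 0.0


@dataclass(frozen=True)
class RippleSpec:
    """Temporally oscillating background region (a traveling intensity wave
    confined to ``region`` = (row0, row1, col0, col1))."""

    region: tuple[int, int, int, int] | None = None
    amplitude: float = 0.0
    period: float = 8.0
    wavelength: float = 96.0


@dataclass(frozen=True)
class SceneConfig:
    height: int = 96
    width: int = 96
    n_frames: int = 60
    seed: int = 0
    background_mean: float = 100.0
    background_contrast: float = 12.0
    background_texture_scale: float = 3.0
    noise_sigma: float = 0.0
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    ripple: RippleSpec = field(default_factory=RippleSpec)
    objects: tuple[ObjectSpec, ...] = ()


@dataclass
class SyntheticScene:
    frames: list[np.ndarray]
    truth: list[np.ndarray]
    config: SceneConfig


def _unit_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Smoothed white noise, renormalized to zero mean / unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="wrap")
    return (f - f.mean()) / f.std()


def _object_support(obj: ObjectSpec, center: tuple[float, float], shape) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[0:h, 0:w]
    cr, cx = center
    if obj.shape == "disk":
        return (rr - cr) ** 2 + (cc - cx) ** 2 <= float(obj.size) ** 2
    if obj.shape == "rectangle":
        sh, sw = obj.size  # type: ignore[misc]
        return (np.abs(rr - cr) <= sh / 2.0) & (np.abs(cc - cx) <= sw / 2.0)
    raise ValueError(f"unknown object shape {obj.shape!r}")


def _check_in_frame(obj: ObjectSpec, cfg: SceneConfig) -> None:
    if obj.shape == "disk":
        half_h = half_w = float(obj.size)
    else:
        half_h, half_w = obj.size[0] / 2.0, obj.size[1] / 2.0  # type: ignore[index]
    for t in (0, cfg.n_frames - 1):
        r = obj.start[0] + t * obj.velocity[0]
        c = obj.start[1] + t * obj.velocity[1]
        if not (
            half_h <= r <= cfg.height - 1 - half_h
            and half_w <= c <= cfg.width - 1 - half_w
        ):
            raise ValueError(f"object leaves the frame at frame {t + 1}: {obj}")


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render a scene: static textured background plate, illumination ramp,
    ripple oscillation, moving textured objects, sensor noise; clipped to
    [0, 255]."""
    if cfg.n_frames < 2:
        raise ValueError("a scene needs at least 2 frames")
    if cfg.ripple.region is not None:
        r0, r1, c0, c1 = cfg.ripple.region
        if not (0 <= r0 < r1 <= cfg.height and 0 <= c0 < c1 <= cfg.width):
            raise ValueError(f"invalid ripple region {cfg.ripple.region}")
    for obj in cfg.objects:
        _check_in_frame(obj, cfg)

    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    plate = cfg.background_mean + cfg.background_contrast * _unit_field(
        rng, shape, cfg.background_texture_scale
    )
    obj_fields = [_unit_field(rng, shape, o.texture_scale) for o in cfg.objects]

    frames: list[np.ndarray] = []
    truth: list[np.ndarray] = []
    for t in range(cfg.n_frames):
        frac = t / (cfg.n_frames - 1)
        img = plate.copy()
        ill = cfg.illumination
        if ill.mode == "additive_ramp":
            img += ill.start_gain + frac * (ill.end_gain - ill.start_gain)
        elif ill.mode == "multiplicative_ramp":
            img *= ill.start_gain + frac * (ill.end_gain - ill.start_gain)
        elif ill.mode != "none":
            raise ValueError(f"unknown illumination mode {ill.mode!r}")
        rip = cfg.ripple
        if rip.region is not None and rip.amplitude > 0:
            r0, r1, c0, c1 = rip.region
            cols = np.arange(c0, c1)
            wave = rip.amplitude * np.sin(
                2.0 * np.pi * (t / rip.period - cols / rip.wavelength)
            )
            img[r0:r1, c0:c1] += wave[np.newaxis, :]
        mask = np.zeros(shape, dtype=bool)
        for obj, fld in zip(cfg.objects, obj_fields):
            center = (
                obj.start[0] + t * obj.velocity[0],
                obj.start[1] + t * obj.velocity[1],
            )
            support = _object_support(obj, center, shape)
            # texture translates rigidly with the object (integer shift)
            dr = round(center[0] - obj.start[0])
            dc = round(center[1] - obj.start[1])
            tex = np.roll(fld, (dr, dc), axis=(0, 1))
            img[support] = (
                cfg.background_mean + obj.intensity_offset + obj.texture_contrast * tex[support]
            )
            mask |= support
        if cfg.noise_sigma > 0:
            img += rng.normal(0.0, cfg.noise_sigma, shape)
        frames.append(np.clip(img, 0.0, 255.0))
        truth.append(mask)
    return SyntheticScene(frames=frames, truth=truth, config=cfg)


# --- standard suite -------------------------------------------------------

_DEGRADED_ILLUMINATION = IlluminationSpec(mode="additive_ramp", start_gain=0.0, end_gain=12.0)
_DEGRADED_RIPPLE = RippleSpec(region=(56, 88, 8, 88), amplitude=8.0, period=8.0, wavelength=96.0)
_DEGRADED_NOISE = 2.0

_CLOSE_OBJECT = ObjectSpec(
    shape="disk", size=12.0, start=(24.0, 24.0), velocity=(0.9, 0.9),
    intensity_offset=20.0, texture_contrast=50.0,
)
_DISTANT_OBJECT = ObjectSpec(
    shape="disk", size=2.5, start=(30.0, 60.0), velocity=(0.8, -0.3),
    intensity_offset=45.0, texture_contrast=35.0,
)
_MULTI_OBJECTS = (
    ObjectSpec(
        shape="disk", size=10.0, start=(22.0, 60.0), velocity=(0.9, -0.5),
        intensity_offset=20.0, texture_contrast=50.0,
    ),
    ObjectSpec(
        shape="rectangle", size=(14.0, 14.0), start=(60.0, 20.0), velocity=(-0.5, 0.9),
        intensity_offset=-25.0, texture_contrast=45.0,
    ),
)

_FAMILIES = {
    "static": ((), 101),
    "close": ((_CLOSE_OBJECT,), 102),
    "distant": ((_DISTANT_OBJECT,), 103),
    "multi": (_MULTI_OBJECTS, 104),
}


def standard_suite() -> dict[str, SceneConfig]:
    """Fixed, seeded scene configurations: four families ("static", "close",
    "distant", "multi"), each in a "clean" and a "degraded" (illumination
    ramp + ripple + noise) variant.  Keys are ``"<family>_<variant>"``."""
    suite: dict[str, SceneConfig] = {}
    for family, (objects, seed) in _FAMILIES.items():
        base = SceneConfig(seed=seed, objects=objects)
        suite[f"{family}_clean"] = base
        suite[f"{family}_degraded"] = replace(
            base,
            noise_sigma=_DEGRADED_NOISE,
            illumination=_DEGRADED_ILLUMINATION,
            ripple=_DEGRADED_RIPPLE,
        )
    return suite
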