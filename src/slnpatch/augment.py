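"""Stochastic patch augmentation and dataset normalization statistics.

The suite mirrors a color-heavy histopathology augmentation protocol:
grayscale/HSV recolorization with a uniformly sampled saturation in [1, 180],
Gaussian noise with mean sampled uniformly in [0, 10], salt-and-pepper noise
with per-pixel corruption probability sampled uniformly in [0, 1], RGB channel
separation, and contrast/brightness jitter ``alpha * x + beta`` with
``alpha ~ U(0, 10)`` and ``beta ~ U(0, 10)``. Each enabled transform fires
independently with a configurable apply probability and the transforms
compose in the order listed above. All outputs are clipped to [0, 255] uint8.

Augmentation is applied on the fly during training; the dataset size is
unchanged. Note that the sampled ``alpha`` may be < 1 (darkening) or near 0
(destructive); the printed default range is kept but configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb, rgb2gray

__all__ = [
    "AugmentationConfig",
    "ChannelStats",
    "apply_augmentations",
    "contrast_brightness",
    "gray_hsv_recolor",
    "gaussian_noise",
    "salt_pepper",
    "channel_separate",
    "sample_plan",
    "compute_channel_stats",
]

_SAT_SCALE = (1.0, 180.0)


def _check_rgb(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB patch, got shape {patch.shape}")
    return patch


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class AugmentationConfig:
    enable_recolor: bool = True
    enable_gaussian_noise: bool = True
    enable_salt_pepper: bool = True
    enable_channel_separate: bool = True
    enable_contrast_brightness: bool = True
    saturation_range: tuple[float, float] = (1.0, 180.0)
    gauss_mean_range: tuple[float, float] = (0.0, 10.0)
    gauss_sd: float = 5.0
    saltpepper_prob_range: tuple[float, float] = (0.0, 1.0)
    contrast_alpha_range: tuple[float, float] = (0.0, 10.0)
    brightness_beta_range: tuple[float, float] = (0.0, 10.0)
    recolor_hue: float = 0.75
    per_transform_apply_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "saturation_range",
            "gauss_mean_range",
            "saltpepper_prob_range",
            "contrast_alpha_range",
            "brightness_beta_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} low must be <= high, got ({lo}, {hi})")
        lo, hi = self.saltpepper_prob_range
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError("saltpepper_prob_range must lie within [0,1]")
        if not (0.0 <= self.per_transform_apply_prob <= 1.0):
            raise ValueError("per_transform_apply_prob must be in [0,1]")
        if self.gauss_sd < 0:
            raise ValueError("gauss_sd must be non-negative")


def contrast_brightness(patch: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Per-channel linear intensity map ``clip(alpha * x + beta, 0, 255)``."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    patch = _check_rgb(patch)
    return _to_uint8(alpha * patch.astype(float) + beta)


def gray_hsv_recolor(patch: np.ndarray, saturation_value: float, hue: float = 0.75) -> np.ndarray:
    """Grayscale the patch, then recolorize it at a uniform saturation.

    The sampled ``saturation_value`` lives on the [1, 180] scale and is mapped
    linearly to HSV saturation [0, 1]; the scale minimum therefore reproduces
    the plain 3-channel grayscale image. The luminance ordering of pixels is
    preserved (grayscale becomes the HSV value channel).
    """
    lo, hi = _SAT_SCALE
    if not (lo <= saturation_value <= hi):
        raise ValueError(f"saturation_value must be in [{lo}, {hi}]")
    patch = _check_rgb(patch)
    gray = rgb2gray(patch)  # float in [0,1]
    s = (saturation_value - lo) / (hi - lo)
    hsv = np.empty(patch.shape, dtype=float)
    hsv[..., 0] = hue
    hsv[..., 1] = s
    hsv[..., 2] = gray
    return _to_uint8(hsv2rgb(hsv) * 255.0)


def gaussian_noise(patch: np.ndarray, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise (then clip). ``sd = 0`` is a pure intensity shift."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    patch = _check_rgb(patch)
    noise = rng.normal(mean, sd, size=patch.shape) if sd > 0 else mean
    return _to_uint8(patch.astype(float) + noise)


def salt_pepper(patch: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each pixel independently with probability ``p`` by 0 or 255
    (equal odds), applied to all three channels of the pixel at once."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0,1]")
    patch = _check_rgb(patch).copy()
    h, w = patch.shape[:2]
    corrupt = rng.random((h, w)) < p
    salt = rng.random((h, w)) < 0.5
    patch[corrupt & salt] = 255
    patch[corrupt & ~salt] = 0
    return patch


def channel_separate(patch: np.ndarray, channel: str) -> np.ndarray:
    """Keep one RGB channel, replicated to all three."""
    idx = {"R": 0, "G": 1, "B": 2}.get(channel)
    if idx is None:
        raise ValueError(f"channel must be one of R/G/B, got {channel!r}")
    patch = _check_rgb(patch)
    return np.repeat(patch[..., idx : idx + 1], 3, axis=2)


def sample_plan(config: AugmentationConfig, rng: np.random.Generator) -> dict:
    """Draw one realization of the stochastic transform plan.

    Every enabled transform draws an independent apply gate and its
    parameters from the configured uniform ranges; disabled transforms are
    never applied. Exposed separately so the sampling distributions are
    directly testable.
    """
    gate = config.per_transform_apply_prob
    plan: dict = {}
    if config.enable_recolor:
        plan["recolor"] = {
            "apply": bool(rng.random() < gate),
            "saturation": float(rng.uniform(*config.saturation_range)),
        }
    if config.enable_gaussian_noise:
        plan["gaussian"] = {
            "apply": bool(rng.random() < gate),
            "mean": float(rng.uniform(*config.gauss_mean_range)),
        }
    if config.enable_salt_pepper:
        plan["salt_pepper"] = {
            "apply": bool(rng.random() < gate),
            "p": float(rng.uniform(*config.saltpepper_prob_range)),
        }
    if config.enable_channel_separate:
        plan["channel"] = {
            "apply": bool(rng.random() < gate),
            "channel": ("R", "G", "B")[rng.integers(3)],
        }
    if config.enable_contrast_brightness:
        plan["contrast"] = {
            "apply": bool(rng.random() < gate),
            "alpha": float(rng.uniform(*config.contrast_alpha_range)),
            "beta": float(rng.uniform(*config.brightness_beta_range)),
        }
    return plan


def apply_augmentations(patch: np.ndarray, config: AugmentationConfig, rng_state) -> np.ndarray:
    """Compose the enabled transforms, each firing independently.

    ``rng_state`` may be an integer seed or a ``numpy.random.Generator``; the
    output is fully determined by (patch, config, rng_state). Transforms
    compose in a fixed order: recolorization, Gaussian noise, salt-and-pepper,
    channel separation, contrast/brightness.
    """
    patch = _check_rgb(patch)
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    plan = sample_plan(config, rng)
    out = patch
    if plan.get("recolor", {}).get("apply"):
        out = gray_hsv_recolor(out, plan["recolor"]["saturation"], hue=config.recolor_hue)
    if plan.get("gaussian", {}).get("apply"):
        out = gaussian_noise(out, plan["gaussian"]["mean"], config.gauss_sd, rng)
    if plan.get("salt_pepper", {}).get("apply"):
        out = salt_pepper(out, plan["salt_pepper"]["p"], rng)
    if plan.get("channel", {}).get("apply"):
        out = channel_separate(out, plan["channel"]["channel"])
    if plan.get("contrast", {}).get("apply"):
        out = contrast_brightness(out, plan["contrast"]["alpha"], plan["contrast"]["beta"])
    return out


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/SD of intensities after scaling to (0, 1)."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(not (0.0 <= m <= 1.0) for m in self.mean) or any(s < 0 for s in self.sd):
            raise ValueError("means must be in [0,1] and sds non-negative")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"mean": list(self.mean), "sd": list(self.sd)}))
        return path


def compute_channel_stats(tiles: np.ndarray) -> ChannelStats:
    """Population mean/SD over all pixels of all tiles, on the (0, 1) scale.

    ``tiles`` is an (N, H, W, 3) uint8 stack (see ``patches.patch_pixels``).
    """
    tiles = np.asarray(tiles)
    if tiles.size == 0:
        raise ValueError("cannot compute statistics of an empty tile stack")
    if tiles.ndim != 4 or tiles.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) tiles, got shape {tiles.shape}")
    scaled = tiles.astype(np.float64) / 255.0
    mean = scaled.mean(axis=(0, 1, 2))
    sd = scaled.std(axis=(0, 1, 2))
    return ChannelStats(mean=tuple(mean.tolist()), sd=tuple(sd.tolist()))
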