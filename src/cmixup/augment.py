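"""Stochastic view generation: weakened colour, strengthened geometry.

Medical endoscopy images carry diagnostic information in colour, so the view
pipeline deliberately softens the colour augmentations standard in siamese
self-supervised learning — no grayscale conversion, no Gaussian blur, and
brightness/contrast/saturation jitter at magnitude 0.25 rather than 0.4 — and
compensates with stronger geometry: horizontal *and* vertical flips, plus a
randomly chosen affine perturbation (translation, rotation, or scaling).

All operations act on channel-first float images in [0, 1] and preserve that
range and the square output size.  Jitter is multiplicative: each of
brightness, contrast, saturation draws a factor uniformly from
[1 − s, 1 + s]; hue is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = ["AugmentConfig", "ViewPair", "augment_view", "make_view_pair"]


@dataclass(frozen=True)
class AugmentConfig:
    resize_to: int = 512
    crop: bool = True
    crop_scale: tuple[float, float] = (0.6, 1.0)  # area fraction of the source
    jitter_strength: float = 0.25
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    apply_affine_p: float = 0.5
    max_translate: float = 0.1   # fraction of the side
    max_rotate: float = 30.0     # degrees
    scale_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self):
        if self.jitter_strength < 0:
            raise ValueError("jitter_strength must be non-negative")
        for p in (self.hflip_p, self.vflip_p, self.apply_affine_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.resize_to <= 0:
            raise ValueError("resize_to must be positive")


@dataclass(frozen=True)
class ViewPair:
    """Two independent augmentations of one source image."""

    x_i: np.ndarray
    x_j: np.ndarray


def _resize_chw(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[1] == size and img.shape[2] == size:
        return img
    out = resize(img, (img.shape[0], size, size), order=1,
                 mode="reflect", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _random_resized_crop(img, cfg, rng):
    """Square crop with area fraction drawn from crop_scale, resized back."""
    _, h, w = img.shape
    area_frac = rng.uniform(*cfg.crop_scale)
    side = max(1, int(round(np.sqrt(area_frac) * min(h, w))))
    top = int(rng.integers(0, h - side + 1))
    left = int(rng.integers(0, w - side + 1))
    return img[:, top : top + side, left : left + side]


def _color_jitter(img, strength, rng):
    """Brightness, contrast, saturation — multiplicative, fixed order."""
    b, c, s = rng.uniform(1 - strength, 1 + strength, size=3)
    img = img * b
    gray = img.mean(axis=0, keepdims=True)
    img = gray.mean() + (img - gray.mean()) * c
    img = gray + (img - gray) * s
    return img


def _random_affine(img, cfg, rng):
    """Apply exactly one of translation / rotation / scaling."""
    _, h, w = img.shape
    kind = rng.integers(0, 3)
    if kind == 0:
        tx = rng.uniform(-cfg.max_translate, cfg.max_translate) * w
        ty = rng.uniform(-cfg.max_translate, cfg.max_translate) * h
        tform = AffineTransform(translation=(tx, ty))
    elif kind == 1:
        theta = np.deg2rad(rng.uniform(-cfg.max_rotate, cfg.max_rotate))
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        shift = AffineTransform(translation=-center)
        rot = AffineTransform(rotation=theta)
        tform = shift + rot + AffineTransform(translation=center)
    else:
        factor = rng.uniform(*cfg.scale_range)
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        shift = AffineTransform(translation=-center)
        zoom = AffineTransform(scale=factor)
        tform = shift + zoom + AffineTransform(translation=center)
    out = np.stack(
        [warp(ch, tform.inverse, order=1, mode="reflect", preserve_range=True)
         for ch in img]
    )
    return out


def augment_view(
    source: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic view of ``source``: crop → flips → jitter → affine.

    With every probability 0, jitter 0 and crop disabled (or crop_scale
    (1, 1)), the output is exactly the resized source.
    """
    img = source
    if cfg.crop and cfg.crop_scale != (1.0, 1.0):
        img = _random_resized_crop(img, cfg, rng)
    img = _resize_chw(img, cfg.resize_to)
    if cfg.hflip_p > 0 and rng.random() < cfg.hflip_p:
        img = img[:, :, ::-1]
    if cfg.vflip_p > 0 and rng.random() < cfg.vflip_p:
        img = img[:, ::-1, :]
    if cfg.jitter_strength > 0:
        img = _color_jitter(img, cfg.jitter_strength, rng)
    if cfg.apply_affine_p > 0 and rng.random() < cfg.apply_affine_p:
        img = _random_affine(img, cfg, rng)
    return np.ascontiguousarray(np.clip(img, 0.0, 1.0))


def make_view_pair(
    source: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> ViewPair:
    """Two independently augmented views of one source image."""
    return ViewPair(
        x_i=augment_view(source, cfg, rng),
        x_j=augment_view(source, cfg, rng),
    )
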