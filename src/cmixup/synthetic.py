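"""Seeded synthetic multi-class image corpora.

Stands in for a gastrointestinal-endoscopy image collection at desk scale:
each latent class carries a distinguishable colour-and-texture signature (a
base hue plus an oriented sinusoidal stripe pattern with class-specific
frequency), while nuisance variation — stripe phase/translation, brightness
jitter, additive pixel noise — varies per image.  The class signal is strong
enough that a least-squares linear probe on raw pixels recovers it, which is
what makes representation-learning experiments on the corpus interpretable.

Images are channel-first float arrays in [0, 1].  Generation is a pure
function of the spec (including its integer seed): identical specs produce
bit-identical corpora.
"""

from __future__ import annotations

import colorsys
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SyntheticCorpusSpec", "generate_corpus", "corpus_summary", "export_corpus"]


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    n_classes: int = 4
    images_per_class: int = 50  # size of the largest class
    image_size: int = 32
    unlabeled_fraction: float = 0.0
    imbalance_ratio: float = 1.0  # largest class count / smallest class count
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes <= 0 or self.images_per_class <= 0:
            raise ValueError("n_classes and images_per_class must be positive")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8 pixels")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ValueError("unlabeled_fraction must lie in [0, 1)")
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _class_counts(spec: SyntheticCorpusSpec) -> np.ndarray:
    """Per-class sizes interpolated from images_per_class down to
    images_per_class / imbalance_ratio (rounded), largest class first."""
    top = spec.images_per_class
    bottom = top / spec.imbalance_ratio
    counts = np.rint(np.linspace(top, bottom, spec.n_classes)).astype(int)
    return np.maximum(counts, 1)


def _class_signature(k: int, n_classes: int) -> tuple[np.ndarray, float, float]:
    """Base RGB colour, stripe frequency (cycles/image), stripe angle."""
    hue = k / n_classes
    rgb = np.array(colorsys.hsv_to_rgb(hue, 0.6, 0.7))
    freq = 2.0 + 2.0 * k  # cycles across the image
    angle = np.pi * k / max(n_classes, 1)
    return rgb, freq, angle


def _render(spec: SyntheticCorpusSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    rgb, freq, angle = _class_signature(k, spec.n_classes)
    yy, xx = np.mgrid[0:size, 0:size] / size
    # nuisance: random stripe phase (equivalently translation) and brightness
    phase = rng.uniform(0, 2 * np.pi)
    brightness = rng.uniform(0.85, 1.15)
    axis = np.cos(angle) * xx + np.sin(angle) * yy
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * freq * axis + phase)
    img = rgb[:, None, None] * (0.6 + 0.4 * stripes)[None, :, :]
    img = img * brightness
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[np.ndarray], list[tuple[np.ndarray, int]]]:
    """Generate (unlabeled pool, labeled set of (image, class index)).

    A fraction ``unlabeled_fraction`` of the generated images (uniformly at
    random over the whole corpus) is routed to the unlabeled pool with its
    label dropped; the remainder keeps its label.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for k, count in enumerate(_class_counts(spec)):
        for _ in range(count):
            images.append(_render(spec, k, rng))
            labels.append(k)
    n = len(images)
    n_unlabeled = int(np.floor(spec.unlabeled_fraction * n))
    order = rng.permutation(n)
    unlabeled = [images[i] for i in order[:n_unlabeled]]
    labeled = [(images[i], labels[i]) for i in order[n_unlabeled:]]
    return unlabeled, labeled


def corpus_summary(labeled: list[tuple[np.ndarray, int]]) -> dict[int, int]:
    """Per-class image counts of a labeled set."""
    if not labeled:
        raise ValueError("labeled set is empty")
    return dict(sorted(Counter(label for _, label in labeled).items()))


def export_corpus(
    unlabeled: list[np.ndarray],
    labeled: list[tuple[np.ndarray, int]],
    root: str | Path,
    class_names: list[str] | None = None,
) -> Path:
    """Write the corpus as PNGs in the class-per-subfolder layout the
    dataset reader expects; unlabeled images go under ``unlabeled/``."""
    from PIL import Image

    root = Path(root)
    def save(img: np.ndarray, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr.transpose(1, 2, 0)).save(path)

    for i, img in enumerate(unlabeled):
        save(img, root / "unlabeled" / f"img_{i:05d}.png")
    for i, (img, label) in enumerate(labeled):
        name = class_names[label] if class_names else f"class_{label:02d}"
        save(img, root / "labeled" / name / f"img_{i:05d}.png")
    return root
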