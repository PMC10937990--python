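"""Reading class-per-subfolder image datasets and the train/test split.

The reader targets the HyperKvasir labeled-image layout (one subfolder per
class, PNG/JPEG inside).  Seven classes whose sample counts fall below 10% of
the largest class are dropped by default to contain class imbalance; the trim
list is configuration, with that set as the default.  All images are decoded
to 3-channel RGB, resized to a square, and scaled to float [0, 1] in
channel-first layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TRIMMED_CLASSES",
    "DatasetSpec",
    "load_labeled",
    "load_unlabeled",
    "split_train_test",
]

#: Classes removed by default: each holds < 10% of the largest class's samples.
DEFAULT_TRIMMED_CLASSES = (
    "ileum",
    "hemorrhoids",
    "ulcerative-colitis-grade-0-1",
    "ulcerative-colitis-grade-1-2",
    "ulcerative-colitis-grade-2-3",
    "barretts",
    "barretts-short-segment",
)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class DatasetSpec:
    """Where a labeled dataset lives and how to read it.

    ``class_names`` defaults to the sorted retained subfolder names; class
    indices are positions in that sorted list.
    """

    root: str | Path
    trimmed_classes: tuple[str, ...] = DEFAULT_TRIMMED_CLASSES
    resize_to: int = 512
    class_names: list[str] | None = None

    def __post_init__(self):
        if self.resize_to <= 0:
            raise ValueError("resize_to must be positive")
        self.root = Path(self.root)


def _decode(path: Path, resize_to: int) -> np.ndarray | None:
    """PNG/JPEG -> float32 CHW array in [0,1], or None if undecodable."""
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((resize_to, resize_to), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, UnidentifiedImageError, ValueError):
        return None
    return arr.transpose(2, 0, 1)


def discover_classes(spec: DatasetSpec) -> list[str]:
    """Sorted retained class names under the dataset root."""
    if not spec.root.is_dir():
        raise FileNotFoundError(f"dataset root {spec.root} does not exist")
    if spec.class_names is not None:
        names = list(spec.class_names)
    else:
        names = [p.name for p in spec.root.iterdir() if p.is_dir()]
    trimmed = set(spec.trimmed_classes)
    return sorted(n for n in names if n not in trimmed)


def load_labeled(spec: DatasetSpec) -> list[tuple[np.ndarray, int]]:
    """Load every readable image of every retained class.

    Unreadable files are skipped with a logged warning; an empty retained
    class is a configuration error.
    """
    classes = discover_classes(spec)
    if not classes:
        raise ValueError(f"no retained classes under {spec.root}")
    out: list[tuple[np.ndarray, int]] = []
    n_skipped = 0
    for idx, name in enumerate(classes):
        folder = spec.root / name
        loaded_any = False
        for path in sorted(folder.rglob("*")):
            if path.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            img = _decode(path, spec.resize_to)
            if img is None:
                n_skipped += 1
                logger.warning("skipping unreadable image %s", path)
                continue
            out.append((img, idx))
            loaded_any = True
        if not loaded_any:
            raise ValueError(f"retained class {name!r} contains no readable images")
    logger.info("loaded %d images over %d classes (%d skipped)",
                len(out), len(classes), n_skipped)
    return out


def load_unlabeled(root: str | Path, resize_to: int) -> list[np.ndarray]:
    """Recursively load every readable PNG/JPEG under ``root``."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"unlabeled root {root} does not exist")
    out: list[np.ndarray] = []
    for path in sorted(root.rglob("*")):
        if path.suffix.lower() not in _IMAGE_SUFFIXES:
            continue
        img = _decode(path, resize_to)
        if img is None:
            logger.warning("skipping unreadable image %s", path)
            continue
        out.append(img)
    return out


def split_train_test(
    labeled: list,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 0,
    stratified: bool = False,
) -> tuple[list, list]:
    """Random 4:1 (by default) train/test partition.

    The test share is floor(n · test/(train+test)); the remainder goes to
    train.  ``stratified=True`` applies the same rule within each class
    (items must then be (image, label) pairs).
    """
    tr, te = ratio
    if tr <= 0 or te <= 0:
        raise ValueError("ratio parts must be positive")
    n = len(labeled)
    if n < tr + te:
        raise ValueError(f"need at least {tr + te} items to split, got {n}")
    rng = np.random.default_rng(seed)
    if stratified:
        by_class: dict[int, list[int]] = {}
        for i, (_, label) in enumerate(labeled):
            by_class.setdefault(label, []).append(i)
        test_idx: list[int] = []
        for idxs in by_class.values():
            perm = rng.permutation(len(idxs))
            k = int(len(idxs) * te) // (tr + te)
            test_idx.extend(idxs[j] for j in perm[:k])
        test_set = set(test_idx)
        train = [labeled[i] for i in range(n) if i not in test_set]
        test = [labeled[i] for i in sorted(test_set)]
        return train, test
    n_test = n * te // (tr + te)
    perm = rng.permutation(n)
    test = [labeled[i] for i in perm[:n_test]]
    train = [labeled[i] for i in perm[n_test:]]
    return train, test
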