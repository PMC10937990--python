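"""Backbones and the siamese projection/prediction heads.

Two backbones are provided:

* ``tiny_cnn`` — three conv/BN/ReLU blocks with pooling, for desk-scale runs
  on small synthetic images (32–64 px).
* ``resnet50`` — the standard bottleneck ResNet-50, trained from scratch (the
  self-supervised protocol never uses pretrained weights).  Practical only for
  real runs; tests exercise it with a single small forward pass.

The projector is a 3-layer MLP with batch norm after every linear (no ReLU
after the last, following the siamese-network convention); the predictor is a
bottleneck MLP ``d -> hidden -> d``, with an optional single-linear variant.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv2d,
    Flatten,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)
from .tensor import Tensor

__all__ = [
    "TinyCNN",
    "ResNet50",
    "Projector",
    "Predictor",
    "SiameseNet",
    "build_backbone",
]


class TinyCNN(Module):
    """3-block convnet: 3->16->32->64 channels, global average pooled."""

    feature_dim = 64

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.blocks = Sequential(
            Conv2d(3, 16, 3, rng, padding=1), BatchNorm(16), ReLU(), MaxPool2d(2),
            Conv2d(16, 32, 3, rng, padding=1), BatchNorm(32), ReLU(), MaxPool2d(2),
            Conv2d(32, 64, 3, rng, padding=1), BatchNorm(64), ReLU(),
            GlobalAvgPool(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.blocks(x)


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch: int, width: int, rng, stride: int = 1):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = Conv2d(in_ch, width, 1, rng)
        self.bn1 = BatchNorm(width)
        self.conv2 = Conv2d(width, width, 3, rng, stride=stride, padding=1)
        self.bn2 = BatchNorm(width)
        self.conv3 = Conv2d(width, out_ch, 1, rng)
        self.bn3 = BatchNorm(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, rng, stride=stride),
                                   BatchNorm(out_ch))
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        identity = self.down(x) if self.down is not None else x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class ResNet50(Module):
    feature_dim = 2048

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = Sequential(
            Conv2d(3, 64, 7, rng, stride=2, padding=3), BatchNorm(64), ReLU(),
            MaxPool2d(2),
        )
        layers: list[Module] = []
        in_ch = 64
        for width, blocks, stride in ((64, 3, 1), (128, 4, 2),
                                      (256, 6, 2), (512, 3, 2)):
            for b in range(blocks):
                layers.append(_Bottleneck(in_ch, width, rng,
                                          stride=stride if b == 0 else 1))
                in_ch = width * _Bottleneck.expansion
        self.stages = Sequential(*layers)
        self.pool = GlobalAvgPool()

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.stages(self.stem(x)))


class Projector(Module):
    """Projection MLP f's head: `depth` linear+BN blocks onto `out_dim`."""

    def __init__(self, in_dim: int, out_dim: int, rng, depth: int = 3):
        super().__init__()
        mods: list[Module] = []
        d = in_dim
        for i in range(depth):
            last = i == depth - 1
            mods += [Linear(d, out_dim, rng, bias=not last), BatchNorm(out_dim)]
            if not last:
                mods.append(ReLU())
            d = out_dim
        self.net = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Predictor(Module):
    """Prediction MLP h: out_dim -> hidden -> out_dim bottleneck.

    ``single_layer=True`` replaces it with one linear map.
    """

    def __init__(self, dim: int, hidden: int, rng, single_layer: bool = False):
        super().__init__()
        if single_layer:
            self.net = Sequential(Linear(dim, dim, rng))
        else:
            self.net = Sequential(
                Linear(dim, hidden, rng, bias=False), BatchNorm(hidden), ReLU(),
                Linear(hidden, dim, rng),
            )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def build_backbone(name: str, rng: np.random.Generator) -> Module:
    if name == "tiny_cnn":
        return TinyCNN(rng)
    if name == "resnet50":
        return ResNet50(rng)
    raise ValueError(f"unknown backbone {name!r} (choose tiny_cnn or resnet50)")


class SiameseNet(Module):
    """Backbone + projector (= f) and predictor (= h) with shared weights."""

    def __init__(self, backbone: Module, projector: Projector, predictor: Predictor):
        super().__init__()
        self.backbone = backbone
        self.projector = projector
        self.predictor = predictor

    def project(self, x: Tensor) -> Tensor:
        """z = f(x): encoder features through the projection MLP."""
        return self.projector(self.backbone(x))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z = self.project(x)
        p = self.predictor(z)
        return p, z
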