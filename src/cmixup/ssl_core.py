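"""The siamese objective and the mixed positive view.

Given two augmentations x_i (anchor) and x_j of one image, the positive view
is the convex combination

    x̃_j = λ·x_i + (1 − λ)·x_j,      λ ∈ [0, 0.5],

so the positive starts close to the anchor when λ is allowed to be large
early in training and approaches the plain second view as the curriculum
drives λ toward 0.  Both views pass through the shared encoder-plus-projector
f and predictor h, and the loss is the symmetrized negative cosine similarity
with a stop-gradient on each projection:

    L = −½·[ cos(p_i, stopgrad z̃_j) + cos(p̃_j, stopgrad z_i) ]

At λ = 0 this is exactly the plain siamese (SimSiam) objective on (x_i, x_j).
The stop-gradient is what prevents the trivial constant-embedding solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curriculum import MixCoefficient
from .nn import Predictor, Projector, SiameseNet, Tensor, build_backbone

__all__ = [
    "EncoderSpec",
    "MixedViewPair",
    "EmbeddingQuad",
    "build_model",
    "mix_views",
    "forward_quad",
    "negative_cosine",
    "simsiam_loss",
    "cmixup_loss",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture hyperparameters of f (backbone + projector) and h."""

    backbone: str = "resnet50"
    projector_out_dim: int = 2048
    predictor_hidden_dim: int = 512
    projector_depth: int = 3
    predictor_single_layer: bool = False


def build_model(spec: EncoderSpec, rng: np.random.Generator) -> SiameseNet:
    backbone = build_backbone(spec.backbone, rng)
    projector = Projector(backbone.feature_dim, spec.projector_out_dim, rng,
                          depth=spec.projector_depth)
    predictor = Predictor(spec.projector_out_dim, spec.predictor_hidden_dim, rng,
                          single_layer=spec.predictor_single_layer)
    return SiameseNet(backbone, projector, predictor)


@dataclass(frozen=True)
class MixedViewPair:
    """Anchor view, mixed positive view, and the coefficient that made it."""

    x_i: np.ndarray
    x_tilde_j: np.ndarray
    lam: MixCoefficient


@dataclass(frozen=True)
class EmbeddingQuad:
    """p_i, z_i (anchor) and p̃_j, z̃_j (mixed positive), as graph tensors."""

    p_i: Tensor
    z_i: Tensor
    p_tilde_j: Tensor
    z_tilde_j: Tensor


def mix_views(
    x_i: np.ndarray, x_j: np.ndarray, lam: MixCoefficient | float
) -> MixedViewPair:
    """Form x̃_j = λ·x_i + (1−λ)·x_j; the anchor passes through untouched.

    Convexity keeps the mixture inside the valid [0, 1] pixel range.  λ may
    also be an array of per-sample coefficients broadcastable over a batch.
    """
    if x_i.shape != x_j.shape:
        raise ValueError(f"view shapes differ: {x_i.shape} vs {x_j.shape}")
    coeff = lam if isinstance(lam, MixCoefficient) else MixCoefficient(np.nan, lam)
    lam_value = np.asarray(coeff.lam)
    if lam_value.ndim > 0:  # per-sample: broadcast over (N, C, H, W)
        lam_value = lam_value.reshape(-1, *([1] * (x_i.ndim - 1)))
    x_tilde_j = lam_value * x_i + (1.0 - lam_value) * x_j
    return MixedViewPair(x_i=x_i, x_tilde_j=x_tilde_j, lam=coeff)


def forward_quad(model: SiameseNet, pair: MixedViewPair) -> EmbeddingQuad:
    """Run both views through the shared f and h.

    Images are batched as (N, C, H, W); single images (C, H, W) are promoted
    to a batch of one.
    """
    def batch(x: np.ndarray) -> Tensor:
        return Tensor(x[None] if x.ndim == 3 else x)

    p_i, z_i = model(batch(pair.x_i))
    p_j, z_j = model(batch(pair.x_tilde_j))
    for name, t in (("p_i", p_i), ("z_i", z_i),
                    ("p_tilde_j", p_j), ("z_tilde_j", z_j)):
        if not np.all(np.isfinite(t.data)):
            bad = int(np.argwhere(~np.isfinite(t.data).all(axis=1)).ravel()[0])
            raise FloatingPointError(f"non-finite {name} at batch index {bad}")
    return EmbeddingQuad(p_i=p_i, z_i=z_i, p_tilde_j=p_j, z_tilde_j=z_j)


def _l2_normalize(v: Tensor) -> Tensor:
    norm_sq = (v * v).sum(axis=-1, keepdims=True)
    if np.any(norm_sq.data <= 0):
        raise ValueError("zero-norm vector in cosine similarity")
    return v / (norm_sq ** 0.5)


def negative_cosine(p: Tensor | np.ndarray, z: Tensor | np.ndarray) -> Tensor:
    """−cos(p, stopgrad z), batch-averaged; in [−1, 1].

    z enters under stop-gradient: no parameter gradient flows through it.
    """
    p = p if isinstance(p, Tensor) else Tensor(p)
    z = z if isinstance(z, Tensor) else Tensor(z)
    p_hat = _l2_normalize(p)
    z_hat = _l2_normalize(z.detach())
    return -(p_hat * z_hat).sum(axis=-1).mean()


def simsiam_loss(p_1, z_1, p_2, z_2) -> Tensor:
    """Plain siamese loss: −½ cos(p1, sg z2) − ½ cos(p2, sg z1)."""
    return 0.5 * negative_cosine(p_1, z_2) + 0.5 * negative_cosine(p_2, z_1)


def cmixup_loss(quad: EmbeddingQuad) -> Tensor:
    """Mixed-view loss: −½[cos(p_i, sg z̃_j) + cos(p̃_j, sg z_i)]."""
    return simsiam_loss(quad.p_i, quad.z_i, quad.p_tilde_j, quad.z_tilde_j)
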