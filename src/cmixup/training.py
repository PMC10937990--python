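"""Pretraining and fine-tuning loops.

Pretraining (label-free): per batch, two augmented views are drawn for every
source image, the positive view is mixed with the anchor using a coefficient
sampled from the curriculum-scheduled Beta distribution, and the symmetrized
stop-gradient cosine objective is minimized with SGD (momentum 0.9, weight
decay 1e-4, initial learning rate 0.01) under a cosine-decay learning-rate
schedule.  The curriculum advances once per epoch; λ is redrawn per batch.

Fine-tuning: a linear classification head on the pretrained backbone.
``full_finetune`` updates every weight by SGD on the cross-entropy;
``linear_probe`` freezes the backbone and fits a multinomial logistic
regression on its features — the standard frozen-representation quality
measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, make_view_pair
from .curriculum import CurriculumConfig, sample_lambda, schedule_trace, schedule_value
from .nn import SGD, BatchNorm, Linear, SiameseNet, Tensor
from .ssl_core import EncoderSpec, build_model, cmixup_loss, forward_quad, mix_views

__all__ = [
    "PretrainConfig",
    "FinetuneConfig",
    "cosine_lr",
    "pretrain",
    "finetune",
    "embedding_std",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
    "Classifier",
]


@dataclass
class PretrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    curriculum: CurriculumConfig = field(default_factory=CurriculumConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FinetuneConfig:
    epochs: int = 100
    batch_size: int = 64
    lr: float = 0.001
    weight_decay: float = 0.0
    momentum: float = 0.9
    mode: str = "full_finetune"  # or "linear_probe"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("full_finetune", "linear_probe"):
            raise ValueError("mode must be 'full_finetune' or 'linear_probe'")


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from base_lr at epoch 0 to 0 at the final epoch."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return base_lr * (1.0 + np.cos(np.pi * epoch / total_epochs)) / 2.0


def pretrain(
    pool: list[np.ndarray],
    model: SiameseNet,
    cfg: PretrainConfig,
) -> tuple[SiameseNet, list[float], list[float], list[float]]:
    """Self-supervised pretraining on an unlabeled pool.

    Returns (model, per-epoch mean loss trace, visited α-schedule trace,
    per-batch λ draws).  The pool carries no labels by construction, so
    pretraining cannot consume any.
    """
    if not pool:
        raise ValueError("unlabeled pool is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    curriculum = cfg.curriculum
    if curriculum.total_steps != cfg.epochs:
        curriculum = CurriculumConfig(**{**asdict(curriculum),
                                         "total_steps": cfg.epochs})
    loss_trace: list[float] = []
    alpha_trace: list[float] = []
    lam_trace: list[float] = []
    n = len(pool)
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.epochs)
        alpha_t = schedule_value(curriculum, epoch)
        alpha_trace.append(alpha_t)
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pairs = [make_view_pair(pool[i], cfg.augment, rng) for i in idx]
            x_i = np.stack([p.x_i for p in pairs])
            x_j = np.stack([p.x_j for p in pairs])
            if curriculum.lambda_granularity == "sample":
                lam = sample_lambda(alpha_t, curriculum.cap, rng,
                                    cap_mode=curriculum.cap_mode, size=len(idx))
                lam_trace.extend(float(v) for v in lam)
            else:
                coeff = sample_lambda(alpha_t, curriculum.cap, rng,
                                      cap_mode=curriculum.cap_mode)
                lam = coeff.lam
                lam_trace.append(float(lam))
            mixed = mix_views(x_i, x_j, lam)
            quad = forward_quad(model, mixed)
            loss = cmixup_loss(quad)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        loss_trace.append(float(np.mean(epoch_losses)))
    return model, loss_trace, alpha_trace, lam_trace


def embedding_std(model: SiameseNet, images: list[np.ndarray]) -> float:
    """Collapse diagnostic: mean per-dimension std of L2-normalized projections.

    A healthy siamese run keeps this well above ~1/sqrt(dim)-ish scales; a
    collapsed run drives it toward 0.
    """
    model.eval()
    z = model.project(Tensor(np.stack(images))).data
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    model.train()
    return float(z.std(axis=0).mean())


def extract_features(model: SiameseNet, images: list[np.ndarray],
                     batch_size: int = 64) -> np.ndarray:
    """Backbone features (pre-projector) in eval mode, batched."""
    model.eval()
    feats = []
    for start in range(0, len(images), batch_size):
        x = Tensor(np.stack(images[start : start + batch_size]))
        feats.append(model.backbone(x).data)
    model.train()
    return np.concatenate(feats)


class Classifier:
    """A classification head over a siamese backbone.

    ``predict`` maps a list/array of CHW images to class indices; exactly a
    resize-free deterministic forward pass (eval mode, no augmentation).
    """

    def __init__(self, model: SiameseNet, n_classes: int, mode: str,
                 head: Linear | None = None, sk_head=None):
        self.model = model
        self.n_classes = n_classes
        self.mode = mode
        self.head = head
        self.sk_head = sk_head

    def logits(self, images: np.ndarray) -> np.ndarray:
        self.model.eval()
        feats = self.model.backbone(Tensor(np.asarray(images)))
        if self.head is not None:
            out = self.head(feats).data
        else:
            out = self.sk_head.decision_function(feats.data)
        self.model.train()
        return out

    def predict(self, images) -> np.ndarray:
        images = np.stack(images) if isinstance(images, list) else np.asarray(images)
        if self.mode == "linear_probe" and self.sk_head is not None:
            feats = extract_features(self.model, list(images))
            return np.asarray(self.sk_head.predict(feats))
        out = self.logits(images)
        if out.ndim == 1:  # binary decision_function
            return (out > 0).astype(int)
        return out.argmax(axis=1)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    # stable log-softmax: shift by the rowwise max (treated as constant)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    log_probs = z - log_norm
    picked = log_probs * Tensor(np.eye(logits.shape[1])[labels])
    return -(picked.sum(axis=1).mean())


def finetune(
    model: SiameseNet,
    train_set: list[tuple[np.ndarray, int]],
    cfg: FinetuneConfig,
    n_classes: int | None = None,
) -> tuple[Classifier, dict[str, list[float]]]:
    """Attach a classification head and train on labeled data.

    Returns the classifier and a history dict with per-epoch ``loss`` and
    ``train_accuracy`` (empty lists for a 0-epoch run, which leaves the head
    at initialization).
    """
    if not train_set:
        raise ValueError("training set is empty")
    labels = np.array([y for _, y in train_set])
    images = [x for x, _ in train_set]
    k = int(labels.max()) + 1 if n_classes is None else n_classes
    if labels.max() >= k:
        raise ValueError(f"label {labels.max()} out of range for {k} classes")
    history: dict[str, list[float]] = {"loss": [], "train_accuracy": []}
    rng = np.random.default_rng(cfg.seed)

    if cfg.mode == "linear_probe":
        from sklearn.linear_model import LogisticRegression

        feats = extract_features(model, images, batch_size=cfg.batch_size)
        probe = LogisticRegression(max_iter=max(cfg.epochs * 10, 200),
                                   random_state=cfg.seed)
        if cfg.epochs > 0:
            probe.fit(feats, labels)
            acc = float((probe.predict(feats) == labels).mean())
            history["train_accuracy"].append(acc)
        else:
            # untrained probe: uniform head predicting class 0
            probe.classes_ = np.arange(k)
            probe.coef_ = np.zeros((k, feats.shape[1]))
            probe.intercept_ = np.zeros(k)
        return Classifier(model, k, cfg.mode, sk_head=probe), history

    head = Linear(model.backbone.feature_dim, k, rng)
    params = list(model.backbone.parameters()) + list(head.parameters())
    opt = SGD(params, lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    n = len(images)
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        epoch_loss, n_correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = Tensor(np.stack([images[i] for i in idx]))
            y = labels[idx]
            logits = head(model.backbone(x))
            loss = _cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss.append(float(loss.data))
            n_correct += int((logits.data.argmax(axis=1) == y).sum())
        history["loss"].append(float(np.mean(epoch_loss)))
        history["train_accuracy"].append(n_correct / n)
    return Classifier(model, k, cfg.mode, head=head), history


def save_checkpoint(path: str | Path, model: SiameseNet,
                    config: dict | None = None,
                    traces: dict[str, list[float]] | None = None) -> Path:
    """Weights as an .npz archive; config and traces in a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"config": config or {}, "traces": traces or {}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path, model: SiameseNet) -> SiameseNet:
    with np.load(Path(path)) as state:
        model.load_state_dict(dict(state))
    return model
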