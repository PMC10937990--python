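"""Curriculum scheduling of the Mixup strength.

The mixing coefficient λ of the positive view is drawn from a symmetric
Beta(α_t, α_t) whose concentration α_t follows a monotone non-increasing
curriculum over training: it starts at ``alpha_max`` (draws concentrated near
0 and 1, i.e. the mixed view frequently resembles the anchor — easy) and
decays to ``alpha_min`` (draws collapse onto {0, 1}; with the cap below, the
mixed view is essentially the independent second view — hard, the plain
Mixup regime).

Because Beta(α, α) with α < 1 is U-shaped, half of the raw draws exceed 1/2
and would make the *anchor* the majority ingredient of the "positive" view.
A hard cap ``lam = min(raw, cap)`` with cap ≤ 0.5 guarantees the second view
always contributes at least half of the mixture.

Schedulers (over step index i in [0, T]):

* ``constant``       — α_t = alpha_max throughout.
* ``linear``         — α_t = alpha_max − (alpha_max − alpha_min) · i/T.
* ``cosine_anneal``  — α_t = alpha_min + (alpha_max − alpha_min) · (1 + cos(π i/T))/2.
* ``step``           — piecewise-constant decay over ``step_size`` equal
  intervals: α_t = alpha_max − (alpha_max − alpha_min) · ⌊i·S/T⌋/S, clamped
  to [alpha_min, alpha_max]; the clamp makes the terminal value alpha_min, so
  the trace takes step_size + 1 distinct values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurriculumConfig",
    "MixCoefficient",
    "schedule_value",
    "sample_lambda",
    "schedule_trace",
]

_SCHEDULERS = ("step", "linear", "cosine_anneal", "constant")


@dataclass(frozen=True)
class CurriculumConfig:
    """Bounds and shape of the α-schedule.

    Defaults are the standard operating point: α in [1e-4, 0.2], an 8-interval
    step scheduler, and a hard λ-cap of 0.5.
    """

    alpha_max: float = 0.2
    alpha_min: float = 1e-4
    scheduler: str = "step"
    step_size: int = 8
    total_steps: int = 100
    cap: float = 0.5
    lambda_granularity: str = "batch"  # or "sample"
    cap_mode: str = "clip"  # or "reflect": lam = min(raw, 1 - raw)

    def __post_init__(self):
        if not (0 < self.alpha_min <= self.alpha_max):
            raise ValueError("require 0 < alpha_min <= alpha_max")
        if not (0 < self.cap <= 0.5):
            raise ValueError("cap must lie in (0, 0.5]")
        if self.step_size < 1 or self.total_steps < 1:
            raise ValueError("step_size and total_steps must be >= 1")
        if self.scheduler not in _SCHEDULERS:
            raise ValueError(
                f"unknown scheduler {self.scheduler!r}; choose from {_SCHEDULERS}"
            )
        if self.lambda_granularity not in ("batch", "sample"):
            raise ValueError("lambda_granularity must be 'batch' or 'sample'")
        if self.cap_mode not in ("clip", "reflect"):
            raise ValueError("cap_mode must be 'clip' or 'reflect'")


@dataclass(frozen=True)
class MixCoefficient:
    """The scheduled concentration α_t and the capped draw λ it produced."""

    alpha_t: float
    lam: float


def schedule_value(cfg: CurriculumConfig, step_index: int) -> float:
    """Scheduled Beta concentration α_t at ``step_index`` ∈ [0, total_steps]."""
    i, T = step_index, cfg.total_steps
    if not 0 <= i <= T:
        raise ValueError(f"step_index {i} outside [0, {T}]")
    hi, lo = cfg.alpha_max, cfg.alpha_min
    span = hi - lo
    if cfg.scheduler == "constant":
        return hi
    if cfg.scheduler == "linear":
        return hi - span * i / T
    if cfg.scheduler == "cosine_anneal":
        return lo + span * (1.0 + np.cos(np.pi * i / T)) / 2.0
    # step: plateaus of equal width; clamp pins the final plateau at alpha_min
    S = cfg.step_size
    value = hi - span * (i * S // T) / S
    return float(min(max(value, lo), hi))


def schedule_trace(cfg: CurriculumConfig) -> np.ndarray:
    """The full α-trajectory, one value per step index 0..total_steps."""
    return np.array([schedule_value(cfg, i) for i in range(cfg.total_steps + 1)])


def sample_lambda(
    alpha_t: float,
    cap: float,
    rng: np.random.Generator,
    cap_mode: str = "clip",
    size: int | None = None,
) -> MixCoefficient | np.ndarray:
    """Draw λ ~ Beta(α_t, α_t) and cap it.

    ``clip`` takes min(raw, cap); ``reflect`` folds the U-shape onto [0, 1/2]
    via min(raw, 1 − raw) before clipping at ``cap``.  With ``size`` given, an
    array of per-sample coefficients is returned instead of a single
    :class:`MixCoefficient`.
    """
    if alpha_t <= 0:
        raise ValueError("alpha_t must be positive")
    raw = rng.beta(alpha_t, alpha_t, size=size)
    if cap_mode == "reflect":
        raw = np.minimum(raw, 1.0 - raw)
    lam = np.minimum(raw, cap)
    if size is None:
        return MixCoefficient(alpha_t=float(alpha_t), lam=float(lam))
    return lam
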