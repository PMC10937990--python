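"""Run configuration: one YAML file, strict keys, paper-setting defaults.

Every field defaults to the standard operating point (512-px resize, colour
jitter 0.25, α scheduled from 0.2 down to 1e-4 by an 8-interval step
scheduler with λ-cap 0.5, SGD 0.01/1e-4/0.9 with cosine decay for
pretraining, 0.001/0 with batch 64 for 100 fine-tuning epochs), so an empty
config file is a valid, fully specified run.  Unknown keys are rejected with
a message naming them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .curriculum import CurriculumConfig
from .ssl_core import EncoderSpec
from .synthetic import SyntheticCorpusSpec
from .training import FinetuneConfig, PretrainConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class DataSection:
    labeled_root: str | None = None
    unlabeled_root: str | None = None
    resize_to: int = 512
    trimmed_classes: list[str] | None = None
    split_seed: int = 0
    split_ratio: tuple[int, int] = (4, 1)
    stratified: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs"
    synthetic: SyntheticCorpusSpec = field(default_factory=SyntheticCorpusSpec)
    data: DataSection = field(default_factory=DataSection)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    curriculum: CurriculumConfig = field(default_factory=CurriculumConfig)
    model: EncoderSpec = field(default_factory=EncoderSpec)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)

    def resolved_pretrain(self) -> PretrainConfig:
        """Pretrain config with the shared augment/curriculum/model sections
        and the global seed folded in."""
        return dataclasses.replace(
            self.pretrain,
            curriculum=self.curriculum,
            augment=self.augment,
            encoder=self.model,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))


_SECTIONS = {
    "synthetic": SyntheticCorpusSpec,
    "data": DataSection,
    "augment": AugmentConfig,
    "curriculum": CurriculumConfig,
    "model": EncoderSpec,
    "pretrain": PretrainConfig,
    "finetune": FinetuneConfig,
}
_TUPLE_KEYS = {"crop_scale", "scale_range", "split_ratio", "trimmed_classes"}


def _build_section(cls, raw: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{name}': {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_KEYS and v is not None else v
        for k, v in raw.items()
    }
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Parse a YAML run config; ``overrides`` (section -> {key: value})
    take precedence over file values."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root of {path} must be a mapping")
    for section, values in (overrides or {}).items():
        if isinstance(values, dict):
            raw.setdefault(section, {}).update(values)
        else:
            raw[section] = values

    top_known = {"seed", "output_dir", *_SECTIONS}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)} "
                          f"(known: {sorted(top_known)})")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    for section, cls in _SECTIONS.items():
        if section in raw:
            sec_raw = raw[section] or {}
            if not isinstance(sec_raw, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            kwargs[section] = _build_section(cls, sec_raw, section)
    return RunConfig(**kwargs)
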