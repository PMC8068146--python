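"""Training configuration with YAML round-trip serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .model import ModelConfig
from .synthetic import AugmentSpec, default_augmentations


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    class_weights: tuple = (0.8, 1.0, 1.2)
    aux_lambda: float = 0.4
    optimizer: str = "adam"
    base_lr: float = 0.01
    batch_size: int = 4
    epochs: int = 100
    seed: int = 0
    augmentations: list = field(default_factory=default_augmentations)
    checkpoint_dir: str = "checkpoints"
    log_dir: str = "logs"

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        if self.aux_lambda < 0:
            raise ValueError("aux_lambda must be nonnegative")
        self.class_weights = tuple(self.class_weights)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_dict(cfg: TrainConfig) -> dict:
    return _listify(asdict(cfg))


def _backbone_from_dict(d: dict) -> BackboneConfig:
    d = dict(d)
    if d.get("blocks_per_stage") is not None:
        d["blocks_per_stage"] = tuple(d["blocks_per_stage"])
    return BackboneConfig(**d)


def _model_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["backbone"] = _backbone_from_dict(d["backbone"])
    d["mpm_grid_sizes"] = tuple(d["mpm_grid_sizes"])
    return ModelConfig(**d)


def config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["model"] = _model_from_dict(d["model"])
    d["class_weights"] = tuple(d["class_weights"])
    d["augmentations"] = [AugmentSpec(**a) for a in d.get("augmentations", [])]
    return TrainConfig(**d)


def save_config(cfg: TrainConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> TrainConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
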