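"""Run configuration: training hyperparameters and paths, YAML round-trip.

Defaults follow the reference training recipe: Adam at learning rate 0.001,
50 epochs, batch size 32, a seeded 7:1:2 train/validation/test split and a
224 x 224 network input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    data_dir: str = "data"
    input_size: int = 224
    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    split: tuple = (0.7, 0.1, 0.2)
    device: str = "cpu"
    augment: bool = False
    checkpoint_dir: str = "checkpoints"
    output_dir: str = "outputs"
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        self.split = tuple(float(f) for f in self.split)
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer!r}")
        if isinstance(self.model, dict):
            self.model = ModelConfig.from_dict(self.model)
        if self.model.input_size != self.input_size:
            self.model.input_size = self.input_size

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["split"] = list(self.split)
        d["model"] = self.model.to_dict()
        for key in ("semantic_channels", "detail_channels", "decoder_channels",
                    "num_heads", "dilation_rates"):
            d["model"][key] = list(d["model"][key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
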