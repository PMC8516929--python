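"""Pipeline configuration: YAML-backed, with the published defaults.

The four published model configurations are expressible: two-stage x10/224,
one-stage x10/224, one-stage x20/224, and one-stage x20/512. Defaults follow
the published training recipe (k=16, N=256, batch size 32, Adam betas
0.9/0.999, lr decay 0.95 every 2 epochs, patience 2/10, threshold 0.5, 1000
bootstrap iterations).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluation import EvalConfig
from .training import HardMiningConfig, OptimizerConfig

__all__ = ["TissueConfig", "ModelConfig", "PipelineConfig"]

MODES = ("one_stage", "two_stage")


@dataclass
class TissueConfig:
    working_downsample: int = 32
    min_tissue_fraction: float = 0.25

    def validate(self) -> None:
        if self.working_downsample < 1:
            raise ValueError("working_downsample must be >= 1")
        if not 0 <= self.min_tissue_fraction <= 1:
            raise ValueError("min_tissue_fraction must lie in [0, 1]")


@dataclass
class ModelConfig:
    """Toy backbone shape and validation sampling."""

    channels: tuple[int, ...] = (8, 16, 32)
    n_val_tiles: int = 256

    def validate(self) -> None:
        if not self.channels or any(c < 1 for c in self.channels):
            raise ValueError("channels must be positive")


@dataclass
class PipelineConfig:
    mode: str = "one_stage"
    magnification: float = 20.0
    tile_size: int = 224
    stride: int | None = None  # None -> stride = tile size
    tissue: TissueConfig = field(default_factory=TissueConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    mining: HardMiningConfig = field(default_factory=HardMiningConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.magnification <= 0 or self.tile_size <= 0:
            raise ValueError("magnification and tile_size must be positive")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        self.tissue.validate()
        self.optimizer.validate()
        self.mining.validate()
        self.eval.validate()
        self.model.validate()

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["channels"] = list(self.model.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("tissue", TissueConfig),
            ("optimizer", OptimizerConfig),
            ("mining", HardMiningConfig),
            ("eval", EvalConfig),
            ("model", ModelConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if isinstance(d.get("model"), ModelConfig):
            d["model"].channels = tuple(d["model"].channels)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, uri: str | Path) -> None:
        Path(uri).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, uri: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(uri).read_text()))

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in checkpoints."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
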