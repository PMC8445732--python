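"""YAML pipeline configuration with a single master seed.

The master seed is fanned out deterministically to every random consumer
(scene generation, fold splitting, GAN training, U-net training) via fixed
offsets, so one (config, seed) pair reproduces the whole experiment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
import yaml

from .experiment import ExperimentConfig
from .gan import TrainConfig
from .segmentation import SegParams

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


REQUIRED_FIELDS = ("n_normal", "n_npdr", "n_pdr", "image_size", "k_folds")


@dataclass
class PipelineConfig:
    """Everything `run-all` needs besides the master seed."""

    n_normal: int = 10
    n_npdr: int = 10
    n_pdr: int = 10
    image_size: int = 128
    k_folds: int = 5
    skip_gan: bool = True
    np_mode: str = "suspected"
    peripheral_only: bool = False
    disc_macula_frac: float = 0.15
    gan: TrainConfig = field(default_factory=TrainConfig)
    seg: SegParams = field(default_factory=SegParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        for name in REQUIRED_FIELDS:
            if name not in raw:
                raise ConfigError(f"config is missing required field: {name!r}")
        gan_cfg = TrainConfig(**raw.pop("gan", {}))
        seg_cfg = SegParams(**raw.pop("seg", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("gan", "seg")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(gan=gan_cfg, seg=seg_cfg, **raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            k_folds=self.k_folds,
            skip_gan=self.skip_gan,
            np_mode=self.np_mode,
            gan=self.gan,
            seg=self.seg,
        )
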