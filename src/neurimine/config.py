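"""Nested pipeline configuration, YAML round-trip, and seed derivation.

One global seed drives every stage: each stage's RNG seed is derived from the
global seed and the stage name (CRC-32 mix), so partial re-runs of any stage
are reproducible independently of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .enhance import EnhanceConfig
from .metrics import MetricsConfig
from .mining import IterationConfig, MiningConfig
from .phantom import PhantomConfig
from .pseudolabel import LabelConfig
from .segnet import NetworkConfig, TrainConfig

__all__ = ["PipelineConfig", "derive_seed", "load_config", "save_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Every named scalar of the pipeline, one block per stage."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    labels: LabelConfig = field(default_factory=LabelConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    iteration: IterationConfig = field(default_factory=IterationConfig)
    enhancement: EnhanceConfig = field(default_factory=EnhanceConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    out_dir: str = "neurimine_run"
    # user-data mode: when set, the phantom block is ignored
    input_image: str | None = None
    input_swc: str | None = None
    gold_swc: str | None = None
    trace_threshold: float | None = None  # None: Otsu on the enhanced image

    @classmethod
    def desk(cls, seed: int = 0, out_dir: str = "neurimine_run") -> "PipelineConfig":
        """CPU-scale profile: 8-channel network, 32-cubed patches, short
        training schedule — the configuration exercised by the test suite."""
        return cls(
            network=NetworkConfig.desk(input_patch=32),
            training=TrainConfig(patch_size=32, max_epochs=20, patches_per_epoch=24,
                                 lr=0.05, lr_halving_epochs=8),
            seed=seed,
            out_dir=out_dir,
        )


_BLOCKS = {
    "phantom": PhantomConfig,
    "labels": LabelConfig,
    "network": NetworkConfig,
    "training": TrainConfig,
    "mining": MiningConfig,
    "iteration": IterationConfig,
    "enhancement": EnhanceConfig,
    "metrics": MetricsConfig,
}

_TUPLE_FIELDS = {"shape", "radius_range", "spacing", "augmentations"}


def _coerce(cls, data: dict):
    kwargs = {}
    names = {f.name for f in fields(cls)}
    for k, v in data.items():
        if k not in names:
            raise ValueError(f"unknown {cls.__name__} field: {k}")
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = _coerce(_BLOCKS[key], value or {})
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)

    def clean(obj):
        if is_dataclass(obj):
            obj = asdict(obj)
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    path.write_text(yaml.safe_dump(clean(config), sort_keys=False))
    return path
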