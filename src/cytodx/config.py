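"""Pipeline configuration: YAML round-trip with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .classify import EnsembleConfig
from .fixtures import SceneSpec
from .overlap import OverlapConfig
from .postprocess import PostprocessConfig
from .preprocess import PreprocessConfig
from .segment import SegmentConfig
from .select import AnnealingConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of the full seven-stage pipeline."""

    input_dir: str = "scenes"
    output_dir: str = "run"
    seed: int = 0
    train_fraction: float = 0.8  # image-level split; train/test images disjoint
    run_selection: bool = False  # SA-ANN is the slow stage; off by default
    scene: SceneSpec = field(default_factory=SceneSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    select: AnnealingConfig = field(default_factory=AnnealingConfig)
    classify: EnsembleConfig = field(default_factory=EnsembleConfig)


def _from_dict(cls: type, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise ValueError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls, name))
        if target is not None:
            kwargs[name] = _from_dict(target, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (PipelineConfig, "scene"): SceneSpec,
    (PipelineConfig, "preprocess"): PreprocessConfig,
    (PipelineConfig, "segment"): SegmentConfig,
    (PipelineConfig, "postprocess"): PostprocessConfig,
    (PipelineConfig, "overlap"): OverlapConfig,
    (PipelineConfig, "select"): AnnealingConfig,
    (PipelineConfig, "classify"): EnsembleConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data, "")


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
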