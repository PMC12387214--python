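"""Run configuration: one YAML-serializable object tying all stages together.

Defaults reproduce the published training setup (Adam at 1e-4, batch 32,
plateau factor 0.5 / patience 5, early-stop patience 15, λ=0.01, dropout
0.5, 150×150 inputs). Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .architecture import ArchitectureSpec
from .pipeline import AugmentationConfig, SmoteConfig
from .synthetic import GeneratorConfig
from .training import TrainingConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {
    "architecture": ArchitectureSpec,
    "smote": SmoteConfig,
    "augmentation": AugmentationConfig,
    "training": TrainingConfig,
    "generator": GeneratorConfig,
}


@dataclass
class RunConfig:
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    data_dir: str = "synthetic_fundus"
    out_dir: str = "runs"
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    split_first: bool = False
    balance: bool = True
    smote_feature_size: int | None = None
    cam_layer: str = "block4"
    seed: int = 0

    def __post_init__(self):
        self.split_fractions = tuple(float(f) for f in self.split_fractions)
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        for key in _SECTIONS:
            section = d[key]
            for k, v in section.items():
                if isinstance(v, tuple):
                    section[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for key, section_cls in _SECTIONS.items():
            if key in data:
                section = data.pop(key) or {}
                fields_known = set(section_cls.__dataclass_fields__)
                bad = set(section) - fields_known
                if bad:
                    raise ValueError(
                        f"unknown keys in section {key!r}: {sorted(bad)}"
                    )
                kwargs[key] = section_cls(**section)
        kwargs.update(data)
        return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML (or JSON — a YAML subset) run configuration; missing keys
    fall back to the published defaults, an empty file yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
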