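"""Run configuration: every pipeline tunable in one validated structure.

A run config can be built in code or loaded from YAML. Unknown keys are
rejected rather than silently ignored, so a typo in a config file fails
fast instead of running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError, ValidationError
from .features import FeatureConfig
from .gstats import StatConfig
from .segmentation import SegmentationConfig
from .signals import FilterSpec

__all__ = ["ManifestEntry", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ManifestEntry:
    """One input recording: file path plus subject metadata."""

    path: str
    subject: str
    group: str
    trial: int = 1


@dataclass
class RunConfig:
    fs_target: float = 1000.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    refilter_derivatives: bool = True
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    manifest: list[ManifestEntry] = field(default_factory=list)
    out_dir: str = "reachkin_out"
    precision: int = 6  # significant digits in CSV artifacts
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs_target <= 0:
            raise ParameterError("fs_target must be positive")
        if self.precision < 1:
            raise ParameterError("precision must be >= 1")

    @property
    def float_format(self) -> str:
        return f"%.{self.precision}g"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SECTION_TYPES = {
    "filter": FilterSpec,
    "segmentation": SegmentationConfig,
    "features": FeatureConfig,
    "stats": StatConfig,
}


def _build_section(cls: type, data: dict[str, Any], name: str) -> Any:
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    # YAML lists become tuples where the dataclass expects them
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(source: str | Path | dict[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or an equivalent mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")

    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValidationError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "manifest":
            entries = []
            for item in value:
                entries.append(_build_section(ManifestEntry, item, "manifest entry"))
            kwargs[key] = entries
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
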