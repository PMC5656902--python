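"""Run-wide configuration for the command-line surface."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .steric_descriptors import ConeParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable parameters shared by the CLI subcommands.

    Thresholds are the class boundaries applied by the catalyst classifier;
    they must be ordered (small bound below large bound).
    """

    cone: ConeParams = field(default_factory=ConeParams)
    scan_step: float = 10.0
    temperature: float = 298.15
    area_large_threshold: float = 70.0
    area_small_threshold: float = 36.0
    proximal_small_threshold: float = 3.0
    proximal_large_threshold: float = 26.0
    concordance_tolerance: float = 10.0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.area_small_threshold >= self.area_large_threshold:
            raise ValueError("area thresholds out of order")
        if self.proximal_small_threshold >= self.proximal_large_threshold:
            raise ValueError("proximal thresholds out of order")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        cone = data.pop("cone", {})
        return cls(cone=ConeParams(**cone), **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
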