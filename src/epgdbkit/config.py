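"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import IO

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    min_cds: int = 10
    weight_base: float = 2.0
    zero_is_none: bool = True
    coverage_mode: str = "per_reaction"
    plausibility_threshold: float = 0.75
    ranked_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cds < 1:
            raise ConfigurationError("min_cds must be a positive integer")
        if self.weight_base <= 1:
            raise ConfigurationError("weight_base must exceed 1")
        if not 0 <= self.plausibility_threshold <= 1:
            raise ConfigurationError("plausibility_threshold must lie in [0, 1]")
        if self.coverage_mode not in ("per_reaction", "per_pathway"):
            raise ConfigurationError(f"unknown coverage_mode {self.coverage_mode!r}")

    @classmethod
    def from_yaml(cls, source: IO[str] | str) -> "RunConfig":
        data = yaml.safe_load(source if isinstance(source, str) else source.read()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
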