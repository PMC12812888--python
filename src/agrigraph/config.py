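"""Run configuration: one validated object wiring every stage.

Defaults are the framework's standard operating point: 1200-token chunks
with a 200-token overlap (the overlap spans a few sentences so facts that
straddle a boundary stay intact in one window), Leiden at resolution 1.0
with a fixed seed, a 2-level community hierarchy, a 512-token cap on
element-summary inputs, and a global-query decision threshold θ = 3 on the
0-5 relevance scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from agrigraph.errors import ConfigError
from agrigraph.prompts import DEFAULT_ENTITY_TYPES


@dataclass(frozen=True)
class RunConfig:
    chunk_size: int = 1200
    overlap: int = 200
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    resolution: float = 1.0
    seed: int = 0
    max_levels: int = 2
    token_cap: int = 512
    leaf_budget: int = 4000
    theta: int = 3
    max_partials: int = 20
    embedding_dim: int = 256
    provider: str = "stub"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.chunk_size:
            raise ConfigError("require 0 <= overlap < chunk_size")
        if not 0 <= self.theta <= 5:
            raise ConfigError("theta must be within [0, 5]")
        if self.max_levels < 1 or self.token_cap < 1 or self.embedding_dim < 1:
            raise ConfigError("max_levels, token_cap and embedding_dim must be >= 1")
        if not self.entity_types:
            raise ConfigError("entity_types must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["entity_types"] = list(self.entity_types)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot load config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "entity_types" in raw:
            raw["entity_types"] = tuple(raw["entity_types"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
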