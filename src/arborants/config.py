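"""Run configuration: YAML schema shared by the CLI and the analysis scripts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .spatial import DEFAULT_RADII

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(Exception):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    Either ``data_dir`` (a directory holding trees.csv, nest_matrix.csv,
    forage_matrix.csv, species.csv) or ``preset`` (a synthetic scenario
    name, or "two-plot-study") must be given.  ``exclusions`` adds
    species codes to the spatial exclusion list on top of the dataset's
    own flags.
    """

    data_dir: str | None = None
    preset: str | None = None
    out_dir: str = "results"
    plots: list[str] | None = None
    radii: list[float] = field(default_factory=lambda: list(DEFAULT_RADII))
    n_perm: int = 100
    seed: int | None = None
    exclusions: list[str] = field(default_factory=list)
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require_seed: bool = False) -> None:
        if self.data_dir is None and self.preset is None:
            raise ConfigError("config must set either data_dir or preset")
        if self.n_perm < 2:
            raise ConfigError("n_perm must be >= 2")
        if any(r <= 0 for r in self.radii):
            raise ConfigError("radii must be positive")
        if require_seed and self.seed is None:
            raise ConfigError("a random seed is required for permutation runs")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
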