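"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .droplet import DEFAULT_DROPLET_VOLUME_UL
from .errors import ValidationError


@dataclass(frozen=True)
class RunConfig:
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    n_droplets: int = 15000
    n_replicates: int = 2
    min_total_conc: float = 5.0
    sigma_multiplier: float = 3.0  # the three-sigma rule
    seed: int = 0
    ambiguity_margin: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "droplet_volume_ul",
            "n_droplets",
            "n_replicates",
            "min_total_conc",
            "sigma_multiplier",
            "ambiguity_margin",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"RunConfig.{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value document; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        merged = {k: v for k, v in data.items() if k in known}
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**merged)
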