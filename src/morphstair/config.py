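"""Run configuration: everything needed to reproduce a simulated study.

A run is fully determined by its config (including the rng seed); configs
round-trip through YAML so that every emitted result bundle can be re-run
bit-identically from the config file it contains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .observers import CohortConfig, GroupParams, RTParams
from .staircase import DEFAULT_BURN_IN, DEFAULT_START_ML
from .design import DEFAULT_GRID

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    experiment: str = "exp2"  # "exp1" or "exp2"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    start_ml: int = DEFAULT_START_ML
    burn_in_rounds: int = DEFAULT_BURN_IN
    rt_cutoff_ms: float = 6000.0
    min_trials_per_ml: int = 4
    matching_strategy: str = "global"
    min_group_size: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"experiment must be 'exp1' or 'exp2', got {self.experiment!r}")
        if self.start_ml not in DEFAULT_GRID:
            raise ValueError(f"start_ml must be on the morph grid, got {self.start_ml}")
        if self.burn_in_rounds < 0 or self.burn_in_rounds >= 24:
            raise ValueError(f"burn_in_rounds out of range: {self.burn_in_rounds}")
        if self.rt_cutoff_ms <= 0:
            raise ValueError(f"rt_cutoff_ms must be positive, got {self.rt_cutoff_ms}")
        if self.min_trials_per_ml < 1:
            raise ValueError(f"min_trials_per_ml must be >= 1, got {self.min_trials_per_ml}")
        if self.matching_strategy not in ("global", "greedy"):
            raise ValueError(f"unknown matching_strategy: {self.matching_strategy!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("ci", "nh"):
                if isinstance(c.get(key), dict):
                    c[key] = GroupParams(**c[key])
            if isinstance(c.get("rt"), dict):
                c["rt"] = RTParams(**c["rt"])
            d["cohort"] = CohortConfig(**c)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
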