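"""Pipeline configuration: every tunable numeric constant in one place.

Defaults encode the published screening regime: 0.85 read-level and 0.97
full-length clustering cutoffs, OTU size >= 10, >= 3 primer mismatches,
design window of the first 100 nt, 16-20 nt primers at 45-52 degC, a
degeneracy cap of 32, the >1200 bp full-length filter, and the 0.75
identity (0.25 distance) phylum boundary. Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .otus import ScreeningCriteria

__all__ = ["DesignSettings", "DistanceSettings", "PipelineConfig"]


@dataclass
class DesignSettings:
    window: int = 100
    min_length: int = 16
    max_length: int = 20
    tm_min: float = 45.0
    tm_max: float = 52.0
    tm_method: str = "wallace"
    degeneracy_cap: int = 32
    specificity_max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not 10 <= self.min_length <= self.max_length <= 40:
            raise ValueError("primer lengths must satisfy 10 <= min <= max <= 40")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min > tm_max")
        if self.window < self.min_length:
            raise ValueError("design window shorter than min primer length")


@dataclass
class DistanceSettings:
    gap_runs_as_one: bool = True
    ignore_terminal_gaps: bool = True
    max_gap_frac: float = 0.5
    min_full_length: int = 1200
    identity_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold < 1:
            raise ValueError("identity_threshold must be in (0, 1)")
        if not 0 <= self.max_gap_frac <= 1:
            raise ValueError("max_gap_frac must be in [0, 1]")


@dataclass
class PipelineConfig:
    max_offset: int = 0
    max_ambiguous_frac: float = 0.10
    read_cluster_cutoff: float = 0.85
    full_length_cutoff: float = 0.97
    identity_mode: str = "one_way"
    screening: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    design: DesignSettings = field(default_factory=DesignSettings)
    distance: DistanceSettings = field(default_factory=DistanceSettings)
    seed: int = 0
    output_dir: str = "ssumine_out"

    def __post_init__(self) -> None:
        if not 0 <= self.max_offset <= 5:
            raise ValueError("max_offset must be in [0, 5]")
        for name in ("read_cluster_cutoff", "full_length_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screening"]["novelty_ranks"] = list(self.screening.novelty_ranks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "screening" in d and isinstance(d["screening"], dict):
            s = dict(d["screening"])
            if "novelty_ranks" in s:
                s["novelty_ranks"] = tuple(s["novelty_ranks"])
            d["screening"] = ScreeningCriteria(**s)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = DesignSettings(**d["design"])
        if "distance" in d and isinstance(d["distance"], dict):
            d["distance"] = DistanceSettings(**d["distance"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
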