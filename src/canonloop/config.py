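"""Run configuration: the pipeline's tunable constants in one place.

Defaults reproduce the published settings: 1.0 Å TCR-only clustering
threshold (joint-mode thresholds per CDR pair), minimum cluster size 5,
six unique sequences for a valid joint class, 2.8 Å resolution cutoff,
B-factor cutoff 80, 1.37 Å peptide-bond continuity cutoff, and the P_c
assignment thresholds.  Config files are flat TOML key = value pairs;
explicit keyword overrides win over file values.
"""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .clustering import JOINT_EPS, JOINT_MIN_UNIQUE_SEQUENCES, MIN_STRUCTURES, TCR_ONLY_EPS
from .structure_io import FilterConfig


@dataclass
class RunConfig:
    tcr_only_eps: float = TCR_ONLY_EPS
    joint_eps: dict[str, float] = field(default_factory=lambda: dict(JOINT_EPS))
    min_structures: int = MIN_STRUCTURES
    joint_min_unique: int = JOINT_MIN_UNIQUE_SEQUENCES
    resolution_cutoff: float = 2.8
    bfactor_cutoff: float = 80.0
    bond_cutoff: float = 1.37
    pc_threshold: float = 1.0
    fit_on: str = "loop"
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [self.tcr_only_eps, self.min_structures, self.joint_min_unique,
                   self.resolution_cutoff, self.bfactor_cutoff, self.bond_cutoff,
                   *self.joint_eps.values()]
        if any(v <= 0 for v in numeric):
            raise ValueError("all numeric thresholds must be positive")
        if self.fit_on not in ("loop", "anchors"):
            raise ValueError("fit_on must be 'loop' or 'anchors'")

    def filters(self) -> FilterConfig:
        return FilterConfig(self.resolution_cutoff, self.bfactor_cutoff, self.bond_cutoff)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**values)
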