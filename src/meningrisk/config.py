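"""Run configuration: calling thresholds, gates and I/O conventions."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .cnv import DEFAULT_CDKN2AB_LOG2, DEFAULT_LOSS_LOG2, DEFAULT_MIN_ARM_FRACTION
from .scoring import DEFAULT_CS_GATE, DEFAULT_SMARCE1_POINTS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    loss_log2: float = DEFAULT_LOSS_LOG2
    min_arm_fraction: float = DEFAULT_MIN_ARM_FRACTION
    cdkn2ab_log2: float = DEFAULT_CDKN2AB_LOG2
    cs_gate: float = DEFAULT_CS_GATE
    cs_unclassified_below: float = 0.3
    smarce1_points: int = DEFAULT_SMARCE1_POINTS
    arms_one_based: bool = False
    seg_one_based: bool = True
    proportion_ndigits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_log2 >= 0:
            raise ValueError("loss_log2 must be negative")
        if not 0.0 < self.min_arm_fraction < 1.0:
            raise ValueError("min_arm_fraction must be in (0, 1)")
        if self.cdkn2ab_log2 >= 0:
            raise ValueError("cdkn2ab_log2 must be negative")
        if not 0.0 <= self.cs_unclassified_below <= self.cs_gate <= 1.0:
            raise ValueError("calibrated-score gates must satisfy 0 <= low < gate <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
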