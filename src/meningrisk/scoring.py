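"""Additive integrated model score and risk-group binning.

Components: WHO grade (Grade 1 -> 0, Grade 2 -> 1, Grade 3 -> 2),
methylation family (benign -> 0, intermediate -> 2, malignant -> 4) and
1p/6q/14q loss count (none -> 0, one or two -> 2, all three -> 3).  The
total (0-9) bins into low (0-2), intermediate (3-5) and high (6-9) risk
of early recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product

from .grading import Grade

__all__ = [
    "MC_CLASSES",
    "RiskGroup",
    "MethylationCall",
    "ModelScore",
    "NoScoreError",
    "grade_component",
    "mf_component",
    "chrom_component",
    "risk_group",
    "reachable_scores",
    "compute_model_score",
    "DEFAULT_SMARCE1_POINTS",
    "DEFAULT_CS_GATE",
]

MC_CLASSES = ("benign", "intermediate", "malignant", "SMARCE1_altered", "other")

#: calibrated-score inclusion gate
DEFAULT_CS_GATE = 0.9
#: methylation-family points assigned to the SMARCE1-altered class; the
#: published family points cover benign/intermediate/malignant only, and
#: treating SMARCE1-altered as benign (0) reconciles the printed Grade-2
#: class and risk-group totals.
DEFAULT_SMARCE1_POINTS = 0

_GRADE_POINTS = {Grade.G1: 0, Grade.G2: 1, Grade.G3: 2}
_MF_POINTS = {"benign": 0, "intermediate": 2, "malignant": 4}
MF_COMPONENTS = (0, 2, 4)
CHROM_COMPONENTS = (0, 2, 3)


class RiskGroup(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class NoScoreError(ValueError):
    """The model score is undefined for this input (ungraded / class other)."""


@dataclass(frozen=True)
class MethylationCall:
    mc_class: str
    calibrated_score: float

    def __post_init__(self) -> None:
        if self.mc_class not in MC_CLASSES:
            raise ValueError(f"unknown methylation class: {self.mc_class!r}")
        if not 0.0 <= self.calibrated_score <= 1.0:
            raise ValueError(
                f"calibrated score must be in [0, 1], got {self.calibrated_score}"
            )


@dataclass(frozen=True)
class ModelScore:
    grade_component: int
    mf_component: int
    chrom_component: int
    n_arms_lost: int
    total: int
    risk_group: RiskGroup

    def __post_init__(self) -> None:
        if self.total != self.grade_component + self.mf_component + self.chrom_component:
            raise ValueError("total must equal the sum of its components")


def grade_component(grade: Grade | int) -> int:
    """Grade 1 -> 0, Grade 2 -> 1, Grade 3 -> 2; ungraded has no score."""
    if isinstance(grade, int):
        grade = Grade(grade)
    if grade is Grade.UNGRADED:
        raise NoScoreError("ungraded samples carry no model score")
    return _GRADE_POINTS[grade]


def mf_component(mc_class: str, smarce1_points: int = DEFAULT_SMARCE1_POINTS) -> int:
    """Methylation-family points; SMARCE1-altered mapping is configurable."""
    if mc_class in _MF_POINTS:
        return _MF_POINTS[mc_class]
    if mc_class == "SMARCE1_altered":
        return smarce1_points
    raise NoScoreError(f"methylation class {mc_class!r} has no family points")


def chrom_component(lost_1p: bool, lost_6q: bool, lost_14q: bool) -> int:
    """0 losses -> 0 points; 1 or 2 -> 2; all three -> 3."""
    n_lost = sum((bool(lost_1p), bool(lost_6q), bool(lost_14q)))
    return {0: 0, 1: 2, 2: 2, 3: 3}[n_lost]


def risk_group(total: int) -> RiskGroup:
    """Bin a total score: 0-2 low, 3-5 intermediate, 6-9 high."""
    if not 0 <= total <= 9:
        raise ValueError(f"model score must be in 0..9, got {total}")
    if total <= 2:
        return RiskGroup.LOW
    if total <= 5:
        return RiskGroup.INTERMEDIATE
    return RiskGroup.HIGH


def reachable_scores(grade: Grade | int) -> set[int]:
    """All totals attainable for a grade, enumerating the component grid."""
    g = grade_component(grade)
    return {g + mf + ch for mf, ch in product(MF_COMPONENTS, CHROM_COMPONENTS)}


def compute_model_score(
    grade: Grade | int,
    mc_class: str,
    lost_1p: bool,
    lost_6q: bool,
    lost_14q: bool,
    smarce1_points: int = DEFAULT_SMARCE1_POINTS,
) -> ModelScore:
    """Assemble the full model score; raises :class:`NoScoreError` when
    the grade or methylation class does not admit one."""
    g = grade_component(grade)
    mf = mf_component(mc_class, smarce1_points=smarce1_points)
    ch = chrom_component(lost_1p, lost_6q, lost_14q)
    total = g + mf + ch
    return ModelScore(
        grade_component=g,
        mf_component=mf,
        chrom_component=ch,
        n_arms_lost=sum((bool(lost_1p), bool(lost_6q), bool(lost_14q))),
        total=total,
        risk_group=risk_group(total),
    )
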