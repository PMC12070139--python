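"""CNS WHO grading of meningiomas from histological and molecular features.

Grade 2 criteria: mitotic count 4-19 per 10 HPF, brain invasion, chordoid
or clear-cell subtype, or at least 3 of 5 cytoarchitectural atypia
features.  Grade 3: 20+ mitoses per 10 HPF, CDKN2A/B homozygous deletion
or TERT promoter mutation.  Rhabdoid and papillary subtypes are graded by
the same criteria but floor at Grade 2.

Samples unsuitable for morphological assessment (``gradeable=False``) are
returned as ``UNGRADED`` and carry no model score downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "ATYPIA_FEATURES",
    "WHO_SUBTYPES",
    "Grade",
    "Criterion",
    "CriterionCategory",
    "HistologyFeatures",
    "MolecularFlags",
    "GradeResult",
    "effective_mitotic_count",
    "mitoses_per_mm2",
    "assign_grade",
    "DEFAULT_HPF_AREA_MM2",
]

#: area of one standardized high-power field
DEFAULT_HPF_AREA_MM2 = 0.16

ATYPIA_FEATURES = frozenset(
    {
        "hypercellularity",
        "sheet_like_growth",
        "prominent_nucleoli",
        "spotty_necrosis",
        "small_cell_change",
    }
)

#: the 15 recognized histological subtypes plus "unspecified"
WHO_SUBTYPES = frozenset(
    {
        "meningothelial",
        "fibrous",
        "transitional",
        "psammomatous",
        "angiomatous",
        "microcystic",
        "secretory",
        "lymphoplasmacyte_rich",
        "metaplastic",
        "chordoid",
        "clear_cell",
        "atypical",
        "papillary",
        "rhabdoid",
        "anaplastic",
        "unspecified",
    }
)

GRADE2_SUBTYPES = frozenset({"chordoid", "clear_cell"})
FLOOR2_SUBTYPES = frozenset({"rhabdoid", "papillary"})

TRISTATE = ("yes", "no", "unknown")


class Grade(Enum):
    G1 = 1
    G2 = 2
    G3 = 3
    UNGRADED = "ungraded"


class Criterion(str, Enum):
    MITOTIC_COUNT = "mitotic_count"
    BRAIN_INVASION = "brain_invasion"
    HISTOLOGY_SUBTYPE = "histology_subtype"
    ATYPIA_FEATURES = "atypia_features"
    MOLECULAR_GRADE3 = "molecular_grade3"


class CriterionCategory(str, Enum):
    """Mutually exclusive Grade-2 criterion rows used by the cohort tables."""

    BRAIN_INVASION = "brain_invasion"
    MITOTIC_COUNT = "mitotic_count"
    HISTOLOGY_TYPE = "histology_type"
    BRAIN_INVASION_PLUS_MITOSES = "brain_invasion_plus_mitoses"
    NONE = "none"


class UndefinedCountError(ValueError):
    """Neither a local nor a referred mitotic count is available."""


@dataclass(frozen=True)
class HistologyFeatures:
    mitotic_count_local: int | None = None
    mitotic_count_referred: int | None = None
    hpf_area_mm2: float = DEFAULT_HPF_AREA_MM2
    brain_invasion: str = "unassessable"  # yes / no / unassessable
    subtype: str = "unspecified"
    atypia_features: frozenset[str] = frozenset()
    gradeable: bool = True

    def __post_init__(self) -> None:
        for count in (self.mitotic_count_local, self.mitotic_count_referred):
            if count is not None and count < 0:
                raise ValueError("mitotic counts must be non-negative")
        extra = set(self.atypia_features) - ATYPIA_FEATURES
        if extra:
            raise ValueError(f"unknown atypia feature(s): {sorted(extra)}")
        if self.subtype not in WHO_SUBTYPES:
            raise ValueError(f"unknown subtype: {self.subtype!r}")
        if self.brain_invasion not in ("yes", "no", "unassessable"):
            raise ValueError(f"invalid brain_invasion: {self.brain_invasion!r}")


@dataclass(frozen=True)
class MolecularFlags:
    cdkn2ab_deleted: str = "unknown"
    tert_promoter_mutant: str = "unknown"

    def __post_init__(self) -> None:
        for value in (self.cdkn2ab_deleted, self.tert_promoter_mutant):
            if value not in TRISTATE:
                raise ValueError(f"molecular flags must be yes/no/unknown, got {value!r}")


@dataclass(frozen=True)
class GradeResult:
    grade: Grade
    criteria_fired: frozenset[Criterion] = frozenset()
    criterion_category: CriterionCategory = CriterionCategory.NONE
    caveats: tuple[str, ...] = ()


def effective_mitotic_count(
    local: int | None, referred: int | None
) -> int:
    """The count used for grading: the higher of the available values."""
    counts = [c for c in (local, referred) if c is not None]
    if not counts:
        raise UndefinedCountError("no mitotic count available")
    return max(counts)


def mitoses_per_mm2(
    count_per_10hpf: float, hpf_area_mm2: float = DEFAULT_HPF_AREA_MM2
) -> float:
    """Convert a per-10-HPF mitotic count into a density per mm²."""
    if hpf_area_mm2 <= 0:
        raise ValueError("HPF area must be positive")
    return count_per_10hpf / (10.0 * hpf_area_mm2)


def assign_grade(
    features: HistologyFeatures, flags: MolecularFlags | None = None
) -> GradeResult:
    """Apply the grading rules and record which criteria fired.

    Unknown molecular flags never upgrade; they are surfaced as caveats.
    ``criterion_category`` labels Grade-2 results with the mutually
    exclusive row used in the cohort cross-tabulations: invasion plus
    elevated mitoses, invasion alone, mitoses alone, otherwise histology
    type (subtype or atypia).
    """
    flags = flags or MolecularFlags()
    if not features.gradeable:
        return GradeResult(grade=Grade.UNGRADED)

    try:
        count: int | None = effective_mitotic_count(
            features.mitotic_count_local, features.mitotic_count_referred
        )
    except UndefinedCountError:
        count = None

    caveats: list[str] = []
    if flags.cdkn2ab_deleted == "unknown":
        caveats.append("CDKN2A/B status unknown; not used for grading")
    if flags.tert_promoter_mutant == "unknown":
        caveats.append("TERT promoter status unknown; not used for grading")
    if count is None:
        caveats.append("no mitotic count available")

    fired: set[Criterion] = set()
    if count is not None and count >= 20:
        fired.add(Criterion.MITOTIC_COUNT)
    if flags.cdkn2ab_deleted == "yes" or flags.tert_promoter_mutant == "yes":
        fired.add(Criterion.MOLECULAR_GRADE3)
    if fired:
        return GradeResult(
            grade=Grade.G3, criteria_fired=frozenset(fired), caveats=tuple(caveats)
        )

    mitoses_2 = count is not None and 4 <= count <= 19
    invasion = features.brain_invasion == "yes"
    subtype_2 = features.subtype in GRADE2_SUBTYPES
    atypia_2 = len(features.atypia_features) >= 3
    floor_2 = features.subtype in FLOOR2_SUBTYPES

    if mitoses_2:
        fired.add(Criterion.MITOTIC_COUNT)
    if invasion:
        fired.add(Criterion.BRAIN_INVASION)
    if subtype_2 or floor_2:
        fired.add(Criterion.HISTOLOGY_SUBTYPE)
    if atypia_2:
        fired.add(Criterion.ATYPIA_FEATURES)

    if not fired:
        return GradeResult(grade=Grade.G1, caveats=tuple(caveats))

    if invasion and mitoses_2:
        category = CriterionCategory.BRAIN_INVASION_PLUS_MITOSES
    elif invasion:
        category = CriterionCategory.BRAIN_INVASION
    elif mitoses_2:
        category = CriterionCategory.MITOTIC_COUNT
    else:
        category = CriterionCategory.HISTOLOGY_TYPE
    return GradeResult(
        grade=Grade.G2,
        criteria_fired=frozenset(fired),
        criterion_category=category,
        caveats=tuple(caveats),
    )
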