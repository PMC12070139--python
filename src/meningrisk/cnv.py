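"""Arm-level copy-number loss calling from log2-ratio segments.

Segments (as exported by methylation-array CNV pipelines in SEG form) are
intersected with chromosome-arm definitions; an arm is called "lost" when
the union of its segments at or below the loss threshold covers strictly
more than ``min_fraction`` of the arm.  A focal deep-deletion call at a
named locus (CDKN2A/B) is made from the minimum log2 ratio of overlapping
segments.

All coordinates are 0-based, half-open.  Converters for 1-based inclusive
input live in :mod:`meningrisk.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Segment",
    "ArmDefinition",
    "LocusDefinition",
    "ArmStatus",
    "CnvProfile",
    "SCORED_ARMS",
    "DEFAULT_LOSS_LOG2",
    "DEFAULT_MIN_ARM_FRACTION",
    "DEFAULT_CDKN2AB_LOG2",
    "arm_loss_fraction",
    "call_arm_status",
    "call_cdkn2ab",
    "build_cnv_profile",
]

#: log2 ratio at or below which a segment counts as a single-copy loss.
DEFAULT_LOSS_LOG2 = -0.1
#: an arm is "lost" when strictly more than this fraction of it is lost.
DEFAULT_MIN_ARM_FRACTION = 0.05
#: minimum locus log2 strictly below this calls a homozygous deletion.
DEFAULT_CDKN2AB_LOG2 = -0.4

#: arms entering the chromosome component of the model score, plus 22q
#: which is analysed separately.
SCORED_ARMS = ("1p", "6q", "14q", "22q")


class CnvConfigError(ValueError):
    """A required arm or locus definition is missing or malformed."""


@dataclass(frozen=True)
class Segment:
    """One genomic interval with a log2 copy-number ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("segment chromosome must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"segment end ({self.end}) must exceed start ({self.start})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValueError("segment log2 ratio must be finite")


@dataclass(frozen=True)
class ArmDefinition:
    """A named chromosome arm with genomic bounds."""

    chrom: str
    arm_label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm_label not in ("p", "q"):
            raise ValueError(f"arm label must be 'p' or 'q', got {self.arm_label!r}")
        if self.end <= self.start:
            raise ValueError(
                f"arm end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def key(self) -> str:
        """Compact arm key such as ``1p`` or ``22q``."""
        return self.chrom.removeprefix("chr") + self.arm_label

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LocusDefinition:
    """A focal locus checked for deep deletion (e.g. CDKN2A/B)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus end ({self.end}) must exceed start ({self.start})"
            )


@dataclass(frozen=True)
class ArmStatus:
    """Loss-fraction and boolean loss call for one arm."""

    arm_key: str
    fraction_lost: float
    lost: bool


@dataclass
class CnvProfile:
    """Per-sample arm-loss calls plus the CDKN2A/B deletion call.

    ``cdkn2ab_log2`` / ``cdkn2ab_deleted`` are ``None`` when no segment
    overlapped the locus (a "no-call", reported as unknown downstream,
    never silently as intact).
    """

    sample_id: str
    statuses: dict[str, ArmStatus] = field(default_factory=dict)
    cdkn2ab_log2: float | None = None
    cdkn2ab_deleted: bool | None = None

    def lost(self, arm_key: str) -> bool:
        return self.statuses[arm_key].lost

    def fraction(self, arm_key: str) -> float:
        return self.statuses[arm_key].fraction_lost


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open integer intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    total += cur_end - cur_start
    return total


def arm_loss_fraction(
    segments: list[Segment],
    arm: ArmDefinition,
    loss_log2: float = DEFAULT_LOSS_LOG2,
) -> float:
    """Fraction of ``arm`` covered by the union of lost segments.

    A segment is lost when ``log2_ratio <= loss_log2``.  Segments are
    clipped to the arm, so one spanning the p/q boundary contributes only
    its overlap.  Overlapping segments are unioned, never double-counted.
    """
    if arm.length <= 0:
        raise ValueError(f"arm {arm.key} has non-positive length")
    lost: list[tuple[int, int]] = []
    for seg in segments:
        if seg.chrom != arm.chrom or seg.log2_ratio > loss_log2:
            continue
        start = max(seg.start, arm.start)
        end = min(seg.end, arm.end)
        if end > start:
            lost.append((start, end))
    return _union_length(lost) / arm.length


def call_arm_status(
    arm_key: str,
    fraction_lost: float,
    min_fraction: float = DEFAULT_MIN_ARM_FRACTION,
) -> ArmStatus:
    """Call an arm lost iff strictly more than ``min_fraction`` is lost."""
    if not 0.0 <= fraction_lost <= 1.0:
        raise ValueError(f"fraction_lost must be in [0, 1], got {fraction_lost}")
    return ArmStatus(
        arm_key=arm_key,
        fraction_lost=fraction_lost,
        lost=fraction_lost > min_fraction,
    )


def call_cdkn2ab(
    segments: list[Segment],
    locus: LocusDefinition,
    deletion_log2: float = DEFAULT_CDKN2AB_LOG2,
) -> tuple[float | None, bool | None]:
    """Minimum log2 over segments overlapping ``locus`` and the deletion call.

    Returns ``(None, None)`` — a no-call — when nothing overlaps the locus.
    The deletion is called when the minimum log2 is strictly below
    ``deletion_log2``.
    """
    overlapping = [
        seg.log2_ratio
        for seg in segments
        if seg.chrom == locus.chrom and seg.start < locus.end and seg.end > locus.start
    ]
    if not overlapping:
        return None, None
    lowest = min(overlapping)
    return lowest, lowest < deletion_log2


def build_cnv_profile(
    sample_id: str,
    segments: list[Segment],
    arms: list[ArmDefinition],
    loci: list[LocusDefinition],
    loss_log2: float = DEFAULT_LOSS_LOG2,
    min_fraction: float = DEFAULT_MIN_ARM_FRACTION,
    cdkn2ab_log2: float = DEFAULT_CDKN2AB_LOG2,
    arm_keys: tuple[str, ...] = SCORED_ARMS,
) -> CnvProfile:
    """Compose per-arm loss calls and the CDKN2A/B call for one sample."""
    by_key = {arm.key: arm for arm in arms}
    missing = [key for key in arm_keys if key not in by_key]
    if missing:
        raise CnvConfigError(f"missing arm definition(s): {', '.join(missing)}")
    cdkn2ab = next((loc for loc in loci if loc.name == "CDKN2A/B"), None)
    if cdkn2ab is None:
        raise CnvConfigError("missing locus definition: CDKN2A/B")

    statuses = {}
    for key in arm_keys:
        frac = arm_loss_fraction(segments, by_key[key], loss_log2=loss_log2)
        statuses[key] = call_arm_status(key, frac, min_fraction=min_fraction)
    log2_min, deleted = call_cdkn2ab(segments, cdkn2ab, deletion_log2=cdkn2ab_log2)
    return CnvProfile(
        sample_id=sample_id,
        statuses=statuses,
        cdkn2ab_log2=log2_min,
        cdkn2ab_deleted=deleted,
    )
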