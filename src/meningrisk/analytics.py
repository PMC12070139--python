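"""Cohort-level analytics: calibrated-score gating, cross-tabulations,
mitotic strata, sex ratios, 1p/22q co-deletion groups and the
mitoses-vs-CDKN2A/B correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import CnvProfile
from .grading import (
    Grade,
    GradeResult,
    HistologyFeatures,
    UndefinedCountError,
    effective_mitotic_count,
)
from .rounding import pct, round_half_up
from .scoring import DEFAULT_CS_GATE, MethylationCall, ModelScore

__all__ = [
    "SampleRecord",
    "CohortTable",
    "GatedCohort",
    "records_to_frame",
    "gate_by_calibrated_score",
    "crosstab",
    "mitotic_stratum",
    "MITOTIC_STRATA",
    "sex_ratio_by",
    "cochromosome_groups",
    "COCHROMOSOME_GROUPS",
    "correlate_mitoses_cdkn2ab",
]

MITOTIC_STRATA = ("0-3", "4-7", "8-11", "12-15", "16-19", "20-30")

COCHROMOSOME_GROUPS = (
    "1p intact / 22q intact",
    "1p intact / 22q deleted",
    "1p deleted / 22q intact",
    "1p deleted / 22q deleted",
)


@dataclass
class SampleRecord:
    """One tumour: demographics, histology, methylation call, CNV profile
    and the derived grade / model score."""

    sample_id: str
    sex: str
    age: float
    features: HistologyFeatures
    methylation: MethylationCall
    pathway: str = "local"
    cnv: CnvProfile | None = None
    grade_result: GradeResult | None = None
    model_score: ModelScore | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.pathway not in ("local", "external"):
            raise ValueError(f"pathway must be local or external, got {self.pathway!r}")


class GatedCohort(NamedTuple):
    """Disjoint, exhaustive partition by calibrated score."""

    included: list[SampleRecord]
    low_band: list[SampleRecord]
    unclassified: list[SampleRecord]


def gate_by_calibrated_score(
    records: Iterable[SampleRecord],
    lo: float = DEFAULT_CS_GATE,
    unclassified_below: float = 0.3,
) -> GatedCohort:
    """Partition records into included (cs >= lo), a low-confidence band
    (unclassified_below <= cs < lo) and unclassified (cs < unclassified_below)."""
    included: list[SampleRecord] = []
    low_band: list[SampleRecord] = []
    unclassified: list[SampleRecord] = []
    for rec in records:
        cs = rec.methylation.calibrated_score
        if cs >= lo:
            included.append(rec)
        elif cs >= unclassified_below:
            low_band.append(rec)
        else:
            unclassified.append(rec)
    return GatedCohort(included, low_band, unclassified)


def _grade_label(grade: Grade) -> str:
    return "ungraded" if grade is Grade.UNGRADED else str(grade.value)


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Flatten records into the analytics frame (one row per sample)."""
    rows = []
    for rec in records:
        try:
            mitoses = effective_mitotic_count(
                rec.features.mitotic_count_local, rec.features.mitotic_count_referred
            )
        except UndefinedCountError:
            mitoses = None
        row: dict = {
            "sample_id": rec.sample_id,
            "sex": rec.sex,
            "age": rec.age,
            "pathway": rec.pathway,
            "mitoses": mitoses,
            "mc_class": rec.methylation.mc_class,
            "calibrated_score": rec.methylation.calibrated_score,
            "grade": _grade_label(rec.grade_result.grade) if rec.grade_result else None,
            "criterion_category": (
                rec.grade_result.criterion_category.value if rec.grade_result else None
            ),
        }
        if rec.cnv is not None:
            for key, status in rec.cnv.statuses.items():
                row[f"frac_{key}"] = status.fraction_lost
                row[f"lost_{key}"] = status.lost
            row["cdkn2ab_log2"] = rec.cnv.cdkn2ab_log2
            if rec.cnv.cdkn2ab_deleted is None:
                row["cdkn2ab_call"] = "no-call"
            else:
                row["cdkn2ab_call"] = "deleted" if rec.cnv.cdkn2ab_deleted else "intact"
        if rec.model_score is not None:
            row["score"] = rec.model_score.total
            row["risk_group"] = rec.model_score.risk_group.value
            row["grade_component"] = rec.model_score.grade_component
            row["mf_component"] = rec.model_score.mf_component
            row["chrom_component"] = rec.model_score.chrom_component
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortTable:
    """A labelled cross-tabulation: integer counts plus row proportions
    rounded for report parity with the printed tables."""

    counts: pd.DataFrame
    row_proportions: pd.DataFrame
    row_totals: pd.Series
    col_totals: pd.Series
    grand_total: int
    ndigits: int = 2

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        row_totals: pd.Series | None = None,
        ndigits: int = 2,
    ) -> "CohortTable":
        """Build a table from a counts matrix.

        ``row_totals`` defaults to the row sums; an explicit value lets a
        printed (possibly inconsistent) row total act as the proportion
        denominator.
        """
        counts = counts.astype(int)
        if (counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        if row_totals is None:
            row_totals = counts.sum(axis=1)
        props = counts.divide(row_totals.replace(0, np.nan), axis=0).fillna(0.0)
        props = props.map(lambda v: round_half_up(v, ndigits))
        return cls(
            counts=counts,
            row_proportions=props,
            row_totals=row_totals,
            col_totals=counts.sum(axis=0),
            grand_total=int(counts.to_numpy().sum()),
            ndigits=ndigits,
        )


def crosstab(
    frame: pd.DataFrame,
    row_key: str,
    col_key: str,
    row_order: list | None = None,
    col_order: list | None = None,
    ndigits: int = 2,
) -> CohortTable:
    """Cross-tabulate two computed attributes of the cohort frame."""
    if frame.empty:
        empty = pd.DataFrame(dtype=int)
        return CohortTable(
            counts=empty,
            row_proportions=pd.DataFrame(dtype=float),
            row_totals=pd.Series(dtype=int),
            col_totals=pd.Series(dtype=int),
            grand_total=0,
            ndigits=ndigits,
        )
    sub = frame.dropna(subset=[row_key, col_key])
    counts = pd.crosstab(sub[row_key], sub[col_key])
    if row_order is not None:
        counts = counts.reindex([r for r in row_order if r in counts.index])
    if col_order is not None:
        counts = counts.reindex(
            columns=[c for c in col_order if c in counts.columns]
        )
    counts = counts.fillna(0)
    return CohortTable.from_counts(counts, ndigits=ndigits)


def mitotic_stratum(count_per_10hpf: int) -> str:
    """Bin a per-10-HPF count into the report strata (closed integer bins)."""
    if count_per_10hpf < 0:
        raise ValueError("mitotic count must be non-negative")
    if count_per_10hpf > 30:
        warnings.warn(
            f"mitotic count {count_per_10hpf} exceeds the top stratum; "
            "assigned to 20-30",
            stacklevel=2,
        )
        return "20-30"
    for stratum in MITOTIC_STRATA:
        lo, hi = (int(x) for x in stratum.split("-"))
        if lo <= count_per_10hpf <= hi:
            return stratum
    raise AssertionError("unreachable")


def sex_ratio_by(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    """F:M ratios (M normalized to 1) per level of ``key``, with counts.

    The ratio is NaN (flagged undefined) where there are no male samples.
    """
    if frame["sex"].isna().any():
        raise ValueError("sex missing for some records")
    counts = pd.crosstab(frame[key], frame["sex"])
    for col in ("F", "M"):
        if col not in counts.columns:
            counts[col] = 0
    out = counts[["F", "M"]].copy()
    out["ratio"] = np.where(out["M"] > 0, out["F"] / out["M"], np.nan)
    out["ratio_str"] = [
        "undefined" if m == 0 else f"{round_half_up(f / m, 1):g}:1"
        for f, m in zip(out["F"], out["M"])
    ]
    return out


def cochromosome_groups(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Partition samples by joint 1p/22q status into four disjoint groups.

    Returns the subset of the frame with a ``cochrom_group`` column added,
    plus the count of samples excluded for lack of a CNV profile.
    """
    if "lost_1p" not in frame.columns or "lost_22q" not in frame.columns:
        return frame.iloc[0:0].assign(cochrom_group=pd.Series(dtype=object)), len(frame)
    has_cnv = frame["lost_1p"].notna() & frame["lost_22q"].notna()
    sub = frame.loc[has_cnv].copy()
    idx = (
        sub["lost_1p"].astype(bool).astype(int) * 2
        + sub["lost_22q"].astype(bool).astype(int)
    )
    sub["cochrom_group"] = idx.map(dict(enumerate(COCHROMOSOME_GROUPS)))
    return sub, int((~has_cnv).sum())


@dataclass
class CorrelationResult:
    coefficient: float
    n_pairs: int
    pairs: pd.DataFrame = field(repr=False)
    flag: str | None = None


def correlate_mitoses_cdkn2ab(frame: pd.DataFrame) -> CorrelationResult | None:
    """Pearson correlation of (mitotic count, CDKN2A/B log2) pairs.

    Returns None with fewer than 3 complete pairs; a zero-variance input
    yields a NaN coefficient with an explanatory flag.
    """
    if "cdkn2ab_log2" not in frame.columns or "mitoses" not in frame.columns:
        return None
    pairs = frame[["mitoses", "cdkn2ab_log2"]].dropna()
    if len(pairs) < 3:
        return None
    x = pairs["mitoses"].to_numpy(dtype=float)
    y = pairs["cdkn2ab_log2"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            coefficient=float("nan"),
            n_pairs=len(pairs),
            pairs=pairs,
            flag="zero variance in one variable; correlation undefined",
        )
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult(coefficient=float(r), n_pairs=len(pairs), pairs=pairs)


def grade_percentage(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Report-style percentage (half-up rounding)."""
    return pct(numerator, denominator, ndigits)
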