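"""Glue: derive CNV profiles, grades and scores for a cohort, and write
the report tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .analytics import (
    SampleRecord,
    cochromosome_groups,
    crosstab,
    gate_by_calibrated_score,
    mitotic_stratum,
    records_to_frame,
    sex_ratio_by,
)
from .cnv import ArmDefinition, LocusDefinition, Segment, build_cnv_profile
from .config import RunConfig
from .grading import Grade, MolecularFlags, assign_grade
from .io import write_manifest
from .scoring import NoScoreError, compute_model_score

__all__ = ["derive_record", "run_pipeline", "aggregate_reports"]

log = logging.getLogger("meningrisk")

MC_ORDER = ["benign", "intermediate", "SMARCE1_altered", "malignant"]
CRITERION_ORDER = [
    "brain_invasion",
    "mitotic_count",
    "histology_type",
    "brain_invasion_plus_mitoses",
]
RISK_ORDER = ["low", "intermediate", "high"]
GRADE_ORDER = ["1", "2", "3", "ungraded"]


def derive_record(
    record: SampleRecord,
    segments: list[Segment] | None,
    arms: list[ArmDefinition],
    loci: list[LocusDefinition],
    config: RunConfig,
) -> SampleRecord:
    """Fill the derived fields of one record in place and return it."""
    if segments is not None:
        record.cnv = build_cnv_profile(
            record.sample_id,
            segments,
            arms,
            loci,
            loss_log2=config.loss_log2,
            min_fraction=config.min_arm_fraction,
            cdkn2ab_log2=config.cdkn2ab_log2,
        )
    if record.cnv is not None and record.cnv.cdkn2ab_deleted is not None:
        cdkn2ab = "yes" if record.cnv.cdkn2ab_deleted else "no"
    else:
        cdkn2ab = "unknown"
    flags = MolecularFlags(cdkn2ab_deleted=cdkn2ab)
    record.grade_result = assign_grade(record.features, flags)

    record.model_score = None
    gated = record.methylation.calibrated_score >= config.cs_gate
    if (
        gated
        and record.grade_result.grade is not Grade.UNGRADED
        and record.cnv is not None
    ):
        try:
            record.model_score = compute_model_score(
                record.grade_result.grade,
                record.methylation.mc_class,
                record.cnv.lost("1p"),
                record.cnv.lost("6q"),
                record.cnv.lost("14q"),
                smarce1_points=config.smarce1_points,
            )
        except NoScoreError:
            record.model_score = None
    log.info(
        "sample=%s grade=%s category=%s mc=%s cs=%.3f gated=%s score=%s",
        record.sample_id,
        record.grade_result.grade.value,
        record.grade_result.criterion_category.value,
        record.methylation.mc_class,
        record.methylation.calibrated_score,
        gated,
        record.model_score.total if record.model_score else None,
    )
    return record


def run_pipeline(
    records: list[SampleRecord],
    segments_by_sample: dict[str, list[Segment]],
    arms: list[ArmDefinition],
    loci: list[LocusDefinition],
    config: RunConfig,
) -> list[SampleRecord]:
    """Derive CNV, grade and score for every record."""
    return [
        derive_record(rec, segments_by_sample.get(rec.sample_id), arms, loci, config)
        for rec in records
    ]


def _write_table(table, stem: str, outdir: Path) -> None:
    table.counts.to_csv(outdir / f"{stem}_counts.csv")
    table.row_proportions.to_csv(outdir / f"{stem}_proportions.csv")


def aggregate_reports(
    records: list[SampleRecord], config: RunConfig, outdir: str | Path
) -> dict[str, object]:
    """Write the cohort report tables for gated records; returns the tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gated = gate_by_calibrated_score(
        records, lo=config.cs_gate, unclassified_below=config.cs_unclassified_below
    )
    frame = records_to_frame(gated.included)
    tables: dict[str, object] = {}

    if not frame.empty:
        tables["grade_by_mc"] = crosstab(
            frame, "grade", "mc_class", row_order=GRADE_ORDER, col_order=MC_ORDER
        )
        grade2 = frame[frame["grade"] == "2"]
        tables["criteria_by_mc"] = crosstab(
            grade2,
            "criterion_category",
            "mc_class",
            row_order=CRITERION_ORDER,
            col_order=MC_ORDER,
        )
        if "risk_group" in frame.columns:
            tables["criteria_by_risk"] = crosstab(
                grade2,
                "criterion_category",
                "risk_group",
                row_order=CRITERION_ORDER,
                col_order=RISK_ORDER,
            )
            scored2 = grade2.dropna(subset=["score"]) if "score" in grade2 else grade2
            tables["criteria_by_score"] = crosstab(
                scored2, "criterion_category", "score", row_order=CRITERION_ORDER
            )
            with_mit = frame.dropna(subset=["mitoses"]).copy()
            if not with_mit.empty:
                with_mit["stratum"] = [
                    mitotic_stratum(int(m)) for m in with_mit["mitoses"]
                ]
                tables["strata_by_risk"] = crosstab(
                    with_mit, "stratum", "risk_group", col_order=RISK_ORDER
                )
            scored = frame.dropna(subset=["score"])
            if not scored.empty:
                tables["sex_by_score"] = sex_ratio_by(scored, "score")
        grouped, n_missing = cochromosome_groups(frame)
        if not grouped.empty:
            tables["cochromosome_by_grade"] = crosstab(
                grouped, "grade", "cochrom_group", row_order=GRADE_ORDER
            )
            tables["cochromosome_missing_cnv"] = n_missing

    for name, table in tables.items():
        if hasattr(table, "counts"):
            _write_table(table, name, outdir)
        elif isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"{name}.csv")
    write_manifest(
        outdir / "manifest.json",
        {
            "config": config.to_dict(),
            "n_records": len(records),
            "n_included": len(gated.included),
            "n_low_band": len(gated.low_band),
            "n_unclassified": len(gated.unclassified),
        },
    )
    return tables
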