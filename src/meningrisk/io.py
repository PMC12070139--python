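"""Readers and writers for the formats the pipeline exchanges.

SEG input follows the IGV dialect: tab-delimited, a header line, columns
sample ID, chromosome, start, end, optional marker count and the segment
mean (log2 ratio).  SEG coordinates are 1-based inclusive on disk and
converted to 0-based half-open on read.  Arm and locus tables are
tab-delimited ``chrom / label / start / end`` (0-based half-open by
default, with a flag for 1-based input).  The cohort sheet is CSV/TSV
with a required header.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .analytics import SampleRecord
from .cnv import ArmDefinition, CnvProfile, LocusDefinition, Segment
from .grading import ATYPIA_FEATURES, HistologyFeatures
from .scoring import MethylationCall

__all__ = [
    "FormatError",
    "SchemaError",
    "read_seg",
    "write_seg",
    "load_arm_definitions",
    "load_locus_definitions",
    "default_arms",
    "default_loci",
    "read_cohort_sheet",
    "write_cohort_sheet",
    "write_profile_table",
    "read_profile_table",
    "write_manifest",
    "COHORT_COLUMNS",
]


class FormatError(ValueError):
    """Malformed input file; message names the file and line."""


class SchemaError(ValueError):
    """Input violates the documented schema (missing column, bad value)."""


ATYPIA_COLUMNS = [f"atypia_{name}" for name in sorted(ATYPIA_FEATURES)]

COHORT_COLUMNS = [
    "sample_id",
    "sex",
    "age",
    "pathway",
    "mitoses_local",
    "mitoses_referred",
    "brain_invasion",
    "subtype",
    *ATYPIA_COLUMNS,
    "gradeable",
    "mc_class",
    "calibrated_score",
]

_SEG_COLUMN_ALIASES = {
    "sample": {"id", "sample", "sample_id", "track"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"loc.start", "start", "loc_start", "chromstart"},
    "end": {"loc.end", "end", "loc_end", "chromend"},
    "seg_mean": {"seg.mean", "seg_mean", "segmean", "log2", "log2_ratio", "mean"},
}


def _match_seg_columns(header: list[str], path: str) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for field, aliases in _SEG_COLUMN_ALIASES.items():
        for i, name in enumerate(lowered):
            if name in aliases and field not in mapping:
                mapping[field] = i
    missing = [f for f in _SEG_COLUMN_ALIASES if f not in mapping]
    if missing:
        raise FormatError(
            f"{path}: SEG header missing column(s) {missing}; got {header}"
        )
    return mapping


def read_seg(
    path: str | Path,
    one_based: bool = True,
    headerless: bool = False,
) -> dict[str, list[Segment]]:
    """Read an IGV-style SEG file into per-sample segment lists.

    ``headerless`` accepts the alternate dialect with fixed column order
    (sample, chrom, start, end, seg.mean) and no header line.
    """
    path = Path(path)
    segments: dict[str, list[Segment]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        if headerless:
            mapping = {"sample": 0, "chrom": 1, "start": 2, "end": 3, "seg_mean": 4}
            start_line = 1
        else:
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError(f"{path}: empty SEG file") from None
            mapping = _match_seg_columns(header, str(path))
            start_line = 2
        for lineno, row in enumerate(reader, start=start_line):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                sample = row[mapping["sample"]].strip()
                chrom = row[mapping["chrom"]].strip()
                start = int(row[mapping["start"]])
                end = int(row[mapping["end"]])
                mean = float(row[mapping["seg_mean"]])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed SEG row: {exc}") from exc
            if not chrom.startswith("chr"):
                chrom = f"chr{chrom}"
            if one_based:
                start -= 1
            try:
                seg = Segment(chrom, start, end, mean)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            segments.setdefault(sample, []).append(seg)
    return segments


def write_seg(
    segments_by_sample: dict[str, list[Segment]],
    path: str | Path,
    one_based: bool = True,
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ID", "chrom", "loc.start", "loc.end", "seg.mean"])
        for sample, segments in segments_by_sample.items():
            for seg in segments:
                start = seg.start + 1 if one_based else seg.start
                writer.writerow(
                    [sample, seg.chrom, start, seg.end, f"{seg.log2_ratio:.4f}"]
                )


def _read_region_table(path: str | Path, n_fields: int) -> list[list[str]]:
    rows = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty table")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(row)}"
                )
            rows.append([field.strip() for field in row])
    return rows


def load_arm_definitions(
    path: str | Path, one_based: bool = False
) -> list[ArmDefinition]:
    """Read a chrom/arm/start/end table; rejects overlapping p/q arms."""
    arms: list[ArmDefinition] = []
    for row in _read_region_table(path, 4):
        chrom, label, start_s, end_s = row[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinate in {row}") from exc
        if one_based:
            start -= 1
        try:
            arms.append(ArmDefinition(chrom, label, start, end))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    by_chrom: dict[str, dict[str, ArmDefinition]] = {}
    for arm in arms:
        seen = by_chrom.setdefault(arm.chrom, {})
        if arm.arm_label in seen:
            raise FormatError(f"{path}: duplicate {arm.key} definition")
        seen[arm.arm_label] = arm
    for chrom, seen in by_chrom.items():
        if "p" in seen and "q" in seen:
            p, q = seen["p"], seen["q"]
            if p.start < q.end and q.start < p.end:
                raise FormatError(f"{path}: {chrom} p and q arms overlap")
    return arms


def load_locus_definitions(
    path: str | Path, one_based: bool = False
) -> list[LocusDefinition]:
    loci = []
    for row in _read_region_table(path, 4):
        name, chrom, start_s, end_s = row[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinate in {row}") from exc
        if one_based:
            start -= 1
        try:
            loci.append(LocusDefinition(name, chrom, start, end))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return loci


def _data_path(name: str) -> Path:
    return Path(str(resources.files("meningrisk").joinpath("data", name)))


def default_arms() -> list[ArmDefinition]:
    """The packaged hg19-style chromosome-arm table (autosomes)."""
    return load_arm_definitions(_data_path("arms_hg19.tsv"))


def default_loci() -> list[LocusDefinition]:
    """The packaged locus table (CDKN2A/B)."""
    return load_locus_definitions(_data_path("loci_hg19.tsv"))


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_bool(value: object, column: str, path: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"{path}: cannot parse boolean {column}={value!r}")


def _parse_optional_int(value: object) -> int | None:
    text = str(value).strip()
    if text == "" or text.lower() in ("nan", "na", "none"):
        return None
    return int(float(text))


def _sheet_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_cohort_sheet(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample cohort sheet into records (no derived fields)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sheet_sep(path), dtype=str, keep_default_na=False)
    missing = [col for col in COHORT_COLUMNS if col not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    records = []
    for i, row in frame.iterrows():
        where = f"{path} row {i + 2}"
        try:
            atypia = frozenset(
                name
                for name, col in zip(sorted(ATYPIA_FEATURES), ATYPIA_COLUMNS)
                if _parse_bool(row[col], col, where)
            )
            features = HistologyFeatures(
                mitotic_count_local=_parse_optional_int(row["mitoses_local"]),
                mitotic_count_referred=_parse_optional_int(row["mitoses_referred"]),
                brain_invasion=row["brain_invasion"].strip() or "unassessable",
                subtype=row["subtype"].strip() or "unspecified",
                atypia_features=atypia,
                gradeable=_parse_bool(row["gradeable"], "gradeable", where),
            )
            methylation = MethylationCall(
                mc_class=row["mc_class"].strip(),
                calibrated_score=float(row["calibrated_score"]),
            )
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    sex=row["sex"].strip(),
                    age=float(row["age"]),
                    pathway=row["pathway"].strip() or "local",
                    features=features,
                    methylation=methylation,
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return records


def write_cohort_sheet(records: Iterable[SampleRecord], path: str | Path) -> None:
    path = Path(path)
    sep = _sheet_sep(path)
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "sex": rec.sex,
            "age": rec.age,
            "pathway": rec.pathway,
            "mitoses_local": rec.features.mitotic_count_local,
            "mitoses_referred": rec.features.mitotic_count_referred,
            "brain_invasion": rec.features.brain_invasion,
            "subtype": rec.features.subtype,
            **{
                col: name in rec.features.atypia_features
                for name, col in zip(sorted(ATYPIA_FEATURES), ATYPIA_COLUMNS)
            },
            "gradeable": rec.features.gradeable,
            "mc_class": rec.methylation.mc_class,
            "calibrated_score": rec.methylation.calibrated_score,
        }
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep=sep, index=False)


def write_profile_table(profiles: Iterable[CnvProfile], path: str | Path) -> None:
    """Per-sample CNV profile CSV (fractions, calls, CDKN2A/B)."""
    rows = []
    for prof in profiles:
        row: dict = {"sample_id": prof.sample_id}
        for key, status in prof.statuses.items():
            row[f"frac_{key}"] = round(status.fraction_lost, 6)
            row[f"lost_{key}"] = status.lost
        row["cdkn2ab_log2"] = (
            "" if prof.cdkn2ab_log2 is None else round(prof.cdkn2ab_log2, 4)
        )
        if prof.cdkn2ab_deleted is None:
            row["cdkn2ab_call"] = "no-call"
        else:
            row["cdkn2ab_call"] = "deleted" if prof.cdkn2ab_deleted else "intact"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns:
        raise SchemaError(f"{path}: missing sample_id column")
    return frame


def write_manifest(path: str | Path, payload: dict) -> None:
    """Run manifest: config, seed, thresholds and software version."""
    from . import __version__

    payload = {"meningrisk_version": __version__, **payload}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
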