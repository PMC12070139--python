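"""Seeded synthetic cohorts with known ground truth.

The generator plants, per sample: a WHO grade (or ungraded), the Grade-2
criterion category, a methylation class with calibrated score, arm-loss
flags for 1p/6q/14q/22q, a CDKN2A/B deletion state, demographics and
histology features consistent with the planted grade — then derives the
expected model score and risk group with the scoring module itself, so
the whole pipeline can be validated round-trip.  Segment emission is the
inverse of the arm caller: lost arms receive segments safely across the
loss threshold, intact arms safely above it.

Default parameters follow the published cohort's marginal and conditional
proportions; everything is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .analytics import SampleRecord, crosstab
from .cnv import ArmDefinition, LocusDefinition, Segment
from .grading import HistologyFeatures
from .scoring import MethylationCall, NoScoreError, compute_model_score

__all__ = [
    "SegmentNoise",
    "CohortParams",
    "generate_cohort",
    "emit_segments",
    "recovery_report",
    "TRUTH_COLUMNS",
]

GRADE_LABELS = ("1", "2", "3", "ungraded")
CRITERIA = (
    "brain_invasion",
    "mitotic_count",
    "histology_type",
    "brain_invasion_plus_mitoses",
)
MC_LABELS = ("benign", "intermediate", "SMARCE1_altered", "malignant")
ARMS = ("1p", "6q", "14q", "22q")

BENIGN_SUBTYPES = ("meningothelial", "fibrous", "transitional", "psammomatous")

TRUTH_COLUMNS = [
    "sample_id",
    "grade",
    "criterion_category",
    "mc_class",
    "calibrated_score",
    "lost_1p",
    "lost_6q",
    "lost_14q",
    "lost_22q",
    "cdkn2ab_deleted",
    "expected_score",
    "expected_risk_group",
]


def _normalized(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class SegmentNoise:
    """Log2 noise for emitted segments; clipping keeps every segment on
    the correct side of the calling thresholds."""

    neutral_mean: float = 0.0
    neutral_sd: float = 0.05
    neutral_floor: float = -0.09  # never dips to the loss threshold
    loss_mean: float = -0.35
    loss_sd: float = 0.05
    loss_ceiling: float = -0.15  # always at or below the loss threshold
    deep_mean: float = -1.2
    deep_sd: float = 0.1
    deep_ceiling: float = -0.8
    lost_frac_min: float = 0.2
    lost_frac_max: float = 0.95

    def __post_init__(self) -> None:
        for sd in (self.neutral_sd, self.loss_sd, self.deep_sd):
            if sd < 0:
                raise ValueError("noise sd must be non-negative")
        if not 0 < self.lost_frac_min <= self.lost_frac_max <= 1:
            raise ValueError("lost fraction range must satisfy 0 < min <= max <= 1")


@dataclass
class CohortParams:
    """Generative parameters; defaults reflect the published cohort."""

    n_samples: int = 1000
    rng_seed: int = 0
    grade_probs: dict[str, float] = field(
        default_factory=lambda: _normalized({"1": 455, "2": 441, "3": 27, "ungraded": 66})
    )
    criterion_probs: dict[str, float] = field(
        default_factory=lambda: _normalized(
            {
                "brain_invasion": 95,
                "mitotic_count": 247,
                "histology_type": 70,
                "brain_invasion_plus_mitoses": 28,
            }
        )
    )
    # methylation-class conditionals keyed by grade label, with per-criterion
    # overrides for Grade 2 keyed by (grade, criterion)
    mc_probs: dict = field(
        default_factory=lambda: {
            "1": _normalized({"benign": 408, "intermediate": 46, "SMARCE1_altered": 1}),
            "3": _normalized({"benign": 7, "intermediate": 10, "malignant": 10}),
            "ungraded": _normalized({"benign": 49, "intermediate": 16, "malignant": 1}),
            ("2", "brain_invasion"): _normalized(
                {"benign": 69, "intermediate": 24, "malignant": 2}
            ),
            ("2", "mitotic_count"): _normalized(
                {"benign": 154, "intermediate": 80, "SMARCE1_altered": 1, "malignant": 12}
            ),
            ("2", "histology_type"): _normalized(
                {"benign": 55, "intermediate": 9, "SMARCE1_altered": 6}
            ),
            ("2", "brain_invasion_plus_mitoses"): _normalized(
                {"benign": 6, "intermediate": 20, "malignant": 2}
            ),
        }
    )
    # arm-loss conditionals keyed per arm by grade label, with optional
    # (grade, mc_class) overrides; 22q and 1p follow printed per-grade
    # frequencies, 6q/14q are unpublished and set to plausible values
    arm_loss_probs: dict = field(
        default_factory=lambda: {
            "1p": {"1": 142 / 455, "2": 0.56, "3": 1.0, "ungraded": 0.40},
            "6q": {"1": 0.08, "2": 0.30, "3": 0.70, "ungraded": 0.15},
            "14q": {"1": 0.10, "2": 0.35, "3": 0.80, "ungraded": 0.20},
            "22q": {"1": 235 / 455, "2": 303 / 442, "3": 1.0, "ungraded": 35 / 66},
        }
    )
    cdkn2ab_del_probs: dict[str, float] = field(
        default_factory=lambda: {"1": 0.0, "2": 0.0, "3": 0.4, "ungraded": 0.0}
    )
    # calibrated-score bands: >=0.9, 0.3-0.9, <0.3
    cs_band_probs: tuple[float, float, float] = (0.81, 0.18, 0.01)
    female_probs: dict[str, float] = field(
        default_factory=lambda: {
            "1": 2.4 / 3.4,
            "2": 1.6 / 2.6,
            "3": 0.7 / 1.7,
            "ungraded": 0.70,
        }
    )
    age_mean: float = 58.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (16.0, 91.0)
    # strata weights for elevated (Grade-2) mitotic counts
    mitoses_strata_weights: dict[str, float] = field(
        default_factory=lambda: _normalized(
            {"4-7": 234, "8-11": 38, "12-15": 14, "16-19": 13}
        )
    )
    noise: SegmentNoise = field(default_factory=SegmentNoise)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        self._check_vector("grade_probs", self.grade_probs)
        self._check_vector("criterion_probs", self.criterion_probs)
        for key, vec in self.mc_probs.items():
            self._check_vector(f"mc_probs[{key!r}]", vec)
        self._check_vector("cs_band_probs", dict(enumerate(self.cs_band_probs)))
        for arm, by_key in self.arm_loss_probs.items():
            for key, p in by_key.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"arm_loss_probs[{arm}][{key!r}] out of [0,1]")
        for key, p in {**self.cdkn2ab_del_probs, **self.female_probs}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {key!r} out of [0,1]")

    @staticmethod
    def _check_vector(name: str, vec: Mapping) -> None:
        values = list(vec.values())
        if any(v < 0 for v in values):
            raise ValueError(f"{name} has negative entries")
        if abs(sum(values) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1, got {sum(values)}")


def _draw(rng: np.random.Generator, probs: Mapping) -> object:
    keys = list(probs.keys())
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p)]


def _arm_loss_p(params: CohortParams, arm: str, grade: str, mc: str) -> float:
    by_key = params.arm_loss_probs.get(arm, {})
    if (grade, mc) in by_key:
        return by_key[(grade, mc)]
    return by_key.get(grade, 0.0)


def _draw_mitoses(
    rng: np.random.Generator, params: CohortParams, grade: str, criterion: str | None
) -> int | None:
    if grade == "ungraded":
        return None
    if grade == "3":
        return int(rng.integers(20, 31))
    if grade == "2" and criterion in ("mitotic_count", "brain_invasion_plus_mitoses"):
        stratum = _draw(rng, params.mitoses_strata_weights)
        lo, hi = (int(x) for x in stratum.split("-"))
        return int(rng.integers(lo, min(hi, 19) + 1))
    return int(rng.integers(0, 4))


def _draw_features(
    rng: np.random.Generator,
    params: CohortParams,
    grade: str,
    criterion: str | None,
    mc: str,
) -> HistologyFeatures:
    """Histology consistent with the planted grade and criterion."""
    mitoses = _draw_mitoses(rng, params, grade, criterion)
    subtype = str(rng.choice(BENIGN_SUBTYPES))
    invasion = "no"
    atypia: frozenset[str] = frozenset()

    if grade == "ungraded":
        return HistologyFeatures(gradeable=False, subtype="unspecified")
    if grade == "3":
        subtype = "anaplastic"
    elif grade == "2":
        if criterion in ("brain_invasion", "brain_invasion_plus_mitoses"):
            invasion = "yes"
        if criterion == "histology_type":
            if mc == "SMARCE1_altered" or rng.random() < 0.5:
                subtype = "clear_cell" if mc == "SMARCE1_altered" else str(
                    rng.choice(("chordoid", "clear_cell"))
                )
            else:
                n_feat = int(rng.integers(3, 6))
                atypia = frozenset(
                    rng.choice(
                        sorted(
                            {
                                "hypercellularity",
                                "sheet_like_growth",
                                "prominent_nucleoli",
                                "spotty_necrosis",
                                "small_cell_change",
                            }
                        ),
                        size=n_feat,
                        replace=False,
                    )
                )
        elif mc == "SMARCE1_altered":
            subtype = "clear_cell"
    return HistologyFeatures(
        mitotic_count_local=mitoses,
        brain_invasion=invasion,
        subtype=subtype,
        atypia_features=atypia,
        gradeable=True,
    )


def _draw_cs(rng: np.random.Generator, params: CohortParams) -> float:
    band = _draw(rng, dict(enumerate(params.cs_band_probs)))
    if band == 0:
        return float(rng.uniform(0.9, 1.0))
    if band == 1:
        return float(rng.uniform(0.3, 0.9))
    return float(rng.uniform(0.0, 0.3))


def generate_cohort(
    params: CohortParams,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Generate records plus a per-sample ground-truth table.

    Deterministic for a fixed ``params.rng_seed``.  Expected scores and
    risk groups in the truth table are derived from the planted values
    with the scoring module itself.
    """
    rng = np.random.default_rng(params.rng_seed)
    records: list[SampleRecord] = []
    truth_rows: list[dict] = []
    for i in range(params.n_samples):
        sample_id = f"SYN{i:05d}"
        grade = _draw(rng, params.grade_probs)
        criterion = _draw(rng, params.criterion_probs) if grade == "2" else None
        mc_key = (grade, criterion) if grade == "2" else grade
        mc = _draw(rng, params.mc_probs[mc_key])
        cs = _draw_cs(rng, params)
        sex = "F" if rng.random() < params.female_probs[grade] else "M"
        age = float(
            np.clip(rng.normal(params.age_mean, params.age_sd), *params.age_range)
        )
        losses = {
            arm: bool(rng.random() < _arm_loss_p(params, arm, grade, mc))
            for arm in ARMS
        }
        cdkn2ab = bool(rng.random() < params.cdkn2ab_del_probs.get(grade, 0.0))
        features = _draw_features(rng, params, grade, criterion, mc)

        expected_score: int | None = None
        expected_risk: str | None = None
        if grade != "ungraded":
            try:
                score = compute_model_score(
                    int(grade), mc, losses["1p"], losses["6q"], losses["14q"]
                )
            except NoScoreError:
                score = None
            if score is not None:
                expected_score = score.total
                expected_risk = score.risk_group.value

        records.append(
            SampleRecord(
                sample_id=sample_id,
                sex=sex,
                age=round(age, 1),
                features=features,
                methylation=MethylationCall(mc_class=mc, calibrated_score=cs),
            )
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "grade": grade,
                "criterion_category": criterion if criterion else "none",
                "mc_class": mc,
                "calibrated_score": cs,
                "lost_1p": losses["1p"],
                "lost_6q": losses["6q"],
                "lost_14q": losses["14q"],
                "lost_22q": losses["22q"],
                "cdkn2ab_deleted": cdkn2ab,
                "expected_score": expected_score,
                "expected_risk_group": expected_risk,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def _clip_normal(
    rng: np.random.Generator, mean: float, sd: float, ceiling: float | None = None,
    floor: float | None = None,
) -> float:
    value = float(rng.normal(mean, sd))
    if ceiling is not None:
        value = min(value, ceiling)
    if floor is not None:
        value = max(value, floor)
    return value


def emit_segments(
    truth_row: Mapping,
    arms: list[ArmDefinition],
    loci: list[LocusDefinition],
    noise: SegmentNoise,
    rng: np.random.Generator,
    lost_fraction: float | None = None,
) -> list[Segment]:
    """Emit SEG-style segments realizing one sample's planted CNV truth.

    Lost arms receive one segment covering a fraction drawn from
    ``[lost_frac_min, lost_frac_max]`` of the arm (always > the 5% rule)
    at a log2 safely below the loss threshold, flanked by neutral
    segments; intact arms receive a single neutral segment.  A planted
    CDKN2A/B deletion adds a deep-deletion segment over the locus.
    ``lost_fraction`` overrides the drawn coverage (useful for boundary
    tests).
    """
    segments: list[Segment] = []
    for arm in arms:
        lost = bool(truth_row.get(f"lost_{arm.key}", False))
        if lost:
            frac = (
                lost_fraction
                if lost_fraction is not None
                else float(rng.uniform(noise.lost_frac_min, noise.lost_frac_max))
            )
            length = max(1, round(frac * arm.length))
            offset = int(rng.integers(0, arm.length - length + 1))
            start = arm.start + offset
            end = start + length
            log2 = _clip_normal(
                rng, noise.loss_mean, noise.loss_sd, ceiling=noise.loss_ceiling
            )
            if start > arm.start:
                segments.append(
                    Segment(
                        arm.chrom,
                        arm.start,
                        start,
                        _clip_normal(
                            rng,
                            noise.neutral_mean,
                            noise.neutral_sd,
                            floor=noise.neutral_floor,
                        ),
                    )
                )
            segments.append(Segment(arm.chrom, start, end, log2))
            if end < arm.end:
                segments.append(
                    Segment(
                        arm.chrom,
                        end,
                        arm.end,
                        _clip_normal(
                            rng,
                            noise.neutral_mean,
                            noise.neutral_sd,
                            floor=noise.neutral_floor,
                        ),
                    )
                )
        else:
            segments.append(
                Segment(
                    arm.chrom,
                    arm.start,
                    arm.end,
                    _clip_normal(
                        rng,
                        noise.neutral_mean,
                        noise.neutral_sd,
                        floor=noise.neutral_floor,
                    ),
                )
            )
    if truth_row.get("cdkn2ab_deleted"):
        for locus in loci:
            if locus.name == "CDKN2A/B":
                segments.append(
                    Segment(
                        locus.chrom,
                        locus.start,
                        locus.end,
                        _clip_normal(
                            rng, noise.deep_mean, noise.deep_sd, ceiling=noise.deep_ceiling
                        ),
                    )
                )
    return segments


def emit_cohort_segments(
    truth: pd.DataFrame,
    arms: list[ArmDefinition],
    loci: list[LocusDefinition],
    noise: SegmentNoise,
    seed: int,
) -> dict[str, list[Segment]]:
    """Emit segments for every sample of a truth table (seeded)."""
    rng = np.random.default_rng(seed)
    return {
        row["sample_id"]: emit_segments(row, arms, loci, noise, rng)
        for row in truth.to_dict("records")
    }


def recovery_report(
    params: CohortParams,
    n: int | None = None,
    seed: int | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Planted vs re-estimated Grade-2 (criterion x methylation-class)
    conditional proportions, with binomial confidence intervals.

    One row per Table-1-style cell: planted probability, estimate, Wilson
    CI at ``confidence``, and whether the planted value falls inside.
    """
    if n is not None or seed is not None:
        params = replace(
            params,
            n_samples=n if n is not None else params.n_samples,
            rng_seed=seed if seed is not None else params.rng_seed,
        )
    records, truth = generate_cohort(params)
    grade2 = truth[truth["grade"] == "2"]
    table = crosstab(grade2, "criterion_category", "mc_class")
    rows = []
    for criterion in CRITERIA:
        planted_vec = params.mc_probs.get(("2", criterion), {})
        n_row = int(grade2["criterion_category"].eq(criterion).sum())
        for mc in MC_LABELS:
            planted = planted_vec.get(mc, 0.0)
            k = (
                int(table.counts.loc[criterion, mc])
                if criterion in table.counts.index and mc in table.counts.columns
                else 0
            )
            if n_row > 0:
                ci = binomtest(k, n_row).proportion_ci(
                    confidence_level=confidence, method="wilson"
                )
                lo, hi = float(ci.low), float(ci.high)
                estimate = k / n_row
            else:
                lo, hi, estimate = 0.0, 1.0, float("nan")
            rows.append(
                {
                    "criterion": criterion,
                    "mc_class": mc,
                    "planted_p": planted,
                    "estimate": estimate,
                    "n": n_row,
                    "ci_low": lo,
                    "ci_high": hi,
                    "inside_ci": lo <= planted <= hi,
                }
            )
    return pd.DataFrame(rows)
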