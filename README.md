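# meningrisk

Integrated risk stratification of meningiomas, as a reusable pipeline:

- **CNV arm caller** (`meningrisk.cnv`) — turns per-sample log2-ratio segments
  (IGV-style SEG input) into chromosome-arm loss calls. A segment at log2 ≤ −0.1
  counts as lost; an arm is called "lost" when the union of lost segments covers
  strictly more than 5% of the arm. A focal CDKN2A/B homozygous deletion is
  called when the minimum log2 over the locus is below −0.4 (no overlapping
  segment → explicit no-call). All thresholds are configuration, not constants.
- **WHO grading** (`meningrisk.grading`) — CNS WHO grade 1/2/3 (or ungraded)
  from mitotic count per 10 HPF (higher of local/referred), brain invasion,
  subtype (chordoid/clear-cell; rhabdoid/papillary floor at grade 2),
  cytoarchitectural atypia (≥3 of 5 features) and molecular grade-3 flags
  (CDKN2A/B deletion, TERT promoter mutation). Grade-2 results carry the
  mutually exclusive criterion category used by the report tables.
- **Integrated score** (`meningrisk.scoring`) — additive model score:
  grade (0/1/2) + methylation family (0/2/4) + 1p/6q/14q loss count (0/2/3),
  binned into low (0–2) / intermediate (3–5) / high (6–9) risk.
- **Cohort analytics** (`meningrisk.analytics`) — calibrated-score gating
  (≥0.9 included; 0.3–0.9 low-confidence; <0.3 unclassified), labelled
  cross-tabulations with report-style rounded row proportions, mitotic strata,
  F:M ratios by score, the four-way 1p/22q co-deletion partition and the
  mitoses-vs-CDKN2A/B Pearson correlation.
- **Synthetic cohorts** (`meningrisk.simulate`) — seeded generator of sample
  sheets + SEG files with known ground truth (planted grades, criteria,
  methylation classes, arm losses, expected scores), plus a parameter-recovery
  report with binomial CIs. The real patient data behind the published cohort
  are not deposited; the simulator emulates its marginal and conditional
  structure so every stage is testable offline.
- **CLI + I/O** (`meningrisk.cli`, `meningrisk.io`) — readers/writers for SEG,
  arm/locus tables (an hg19-style arm table is packaged) and the cohort sheet.

## CLI

```sh
# generate a seeded synthetic cohort (sheet, SEG, ground truth)
meningrisk simulate --n 500 --seed 7 --out sim/

# arm-loss + CDKN2A/B profiles from a SEG file
meningrisk call-cnv --seg sim/segments.seg --out profiles.csv

# the whole chain: CNV calls, grading, scoring, report tables
meningrisk run-all --cohort sim/cohort.csv --seg sim/segments.seg --out run/
```

Thresholds are flags on every subcommand (`--loss-log2`, `--min-arm-fraction`,
`--cdkn2ab-log2`, `--cs-gate`) or a YAML file via `--config`. `--arms/--loci`
override the packaged hg19 region tables. `-v` logs one decision line per
sample.

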