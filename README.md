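# dews

Dynamic early warning scores for ward vital-sign time series.

`dews` implements an end-to-end pipeline for building and evaluating
deterioration risk scores from routinely collected clinical observations:

- **NEWS-2 scoring** — table-driven implementation of the published band
  chart, including oxygen-saturation scale 2 for chronic respiratory
  disease (episode-level rule).
- **Feature engineering** — a 38-dimensional vector per scoring-eligible
  observation set: hinge splits above/below normal bands for U-shaped
  vitals, an ordinal inspired-oxygen level (0–5), the ACVPU ordinal, plus
  difference-from-previous, rolling mean/SD (window 5, minimum 3) and a
  five-level slope category per channel.
- **Labeling** — two outcomes: death or ICU admission within 24 h
  (`d_icu`) and clinically significant deterioration within 4 h (`csd`),
  with episode-level temporal or random train/validation splits.
- **Modeling** — L2-regularized logistic regression with episode-grouped,
  outcome-stratified 10-fold cross-validation for strength selection;
  features normalized to zero mean/unit variance with training constants.
- **Evaluation** — AUROC (rank identity) and AUPRC (average precision),
  percentile bootstrap CIs (500 resamples), threshold tables with
  sensitivity/specificity and false-positive/false-negative rates as a
  percentage of all observation sets, matched cut-points between two
  scores, and event-level detection within a 4-hour look-back window.
- **Synthetic cohorts** — a seeded generator of AR(1) vitals with
  trend-bearing deterioration archetypes, plus a generator that labels
  rows from a known logistic truth for parameter-recovery checks.
- **Sample-size planning** — Hanley–McNeil ROC-comparison power
  calculation with explicit sidedness/correlation/allocation assumptions.

## Command line

All functionality is exposed through the `dews` entry point
(equivalently `python -m dews.cli`):

```sh
dews simulate --out cohort/ --seed 7          # synthetic cohort
dews validate cohort/observations.csv cohort/events.csv
dews news2     cohort/observations.csv cohort/events.csv --out news2.csv
dews featurize cohort/observations.csv cohort/events.csv --out features.csv
dews label     cohort/observations.csv cohort/events.csv --outcome d_icu --out labels.csv
dews train     cohort/observations.csv cohort/events.csv --outcome d_icu --seed 0 --out model.json
dews score     model.json cohort/observations.csv cohort/events.csv --out scored.csv
dews evaluate  cohort/observations.csv cohort/events.csv model.json \
               --outcome d_icu --bootstrap 500 --seed 0 --report report.json
dews power --auc0 0.8 --auc1 0.85 --power 0.8
```

Exit codes: 0 ok, 2 schema error, 3 training error, 4 config error.
Commands that write artifacts also write a provenance record (config,
seeds, resource-file versions) beside their outputs; identical
configuration and seed reproduce byte-identical outputs.

Input files are plain CSV. Observations: `episode_id, timestamp,
heart_rate, resp_rate, sbp, temperature, spo2, o2_mode, o2_value, acvpu,
scale2_label`; events: `episode_id, timestamp, kind, csd_code`.
Timestamps are ISO-8601 (naive values are taken as UTC).

The NEWS-2 band chart, the inspired-oxygen ordinal mapping and the
normal-band/tolerance table ship as editable CSV resources under
`src/dews/resources/`.

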