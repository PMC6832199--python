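# mirscore

Composite dichotomized-biomarker prognostic scoring for critically ill
cohorts, built as a reusable, fully tested pipeline:

* **synthetic cohort generator** — right-censored 204-patient ICU cohorts
  with log-normal serum marker levels (7-miRNA panel), configurable
  log-scale group effects, exponential ICU stay / follow-up / censoring
  and a survivor/non-survivor age gap; bit-reproducible per seed, with a
  prefix-sharing random stream across cohort sizes.
* **stats core** — from-scratch midrank Wilcoxon rank-sum (exact
  enumeration for small tie-free samples, tie/continuity-corrected normal
  approximation otherwise), Spearman correlation, ROC construction over
  midpoint thresholds, and Youden-index optimal cut-point selection with
  deterministic tie-breaking.
* **survival** — Kaplan-Meier product-limit estimation with Greenwood
  variance, k-group log-rank test (hypergeometric variance), univariate
  Cox regression with Breslow ties and separation detection.
* **scoring** — marker selection by rank-sum significance, additive
  0/1-point score construction via per-item Youden cut-offs (optional age
  item), strict-inequality score application, and stratified mortality
  tables with half-up one-decimal percentages.
* **pipeline + CLI** — simulate → compare → select → cut-offs → score →
  stratify → survival-test orchestration with a deterministic JSON run
  manifest, CSV artifacts and a score-by-sepsis contingency report.

## CLI

```bash
# simulate a default 204-patient cohort
mirscore simulate --seed 7 --out cohort.csv

# full pipeline (4 score definitions: ICU and overall survival, each with
# and without the age item) into an output directory
mirscore run --cohort cohort.csv --seed 7 --out-dir out/

# individual stages
mirscore compare --cohort cohort.csv --out tests.csv
mirscore cutoffs --cohort cohort.csv --outcome icu --out icu_score.json
mirscore score   --cohort cohort.csv --definition icu_score.json --out scores.csv
mirscore survive --cohort cohort.csv --scores scores.csv --outcome icu \
                 --grouping '0|1,2|3' --out survival.json
```

Exit codes: `0` success, `2` schema error, `3` degenerate input,
`4` configuration error. Logs go to stderr; numeric results only to files.

The cohort CSV schema is
`patient_id,age,sepsis,icu_death,icu_los,overall_event,followup_time`
followed by one column per panel marker (`miR-122` … `miR-223`); booleans
are 0/1, times are days, marker levels are positive arbitrary units.

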