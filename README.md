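# sarcnet

Bootstrapped-lasso stability selection and signed association networks for
acute-sarcopenia cohort studies.

## The problem

Acute sarcopenia is the loss of muscle strength plus muscle quantity or
quality developing within months of a stressor event such as surgery or an
acute infection in older adults. Observational studies of it yield small,
heterogeneous longitudinal tables: three recruitment groups (elective
surgery, emergency surgery, medical admissions), up to four assessment
timepoints (preoperative — elective patients only, 48 hours, 7 days,
13 weeks), dozens of mixed-type candidate predictors (demographics,
comorbidity and medication flags, ultrasound muscle thickness, bioimpedance,
handgrip strength, systemic biomarkers), and heavy missingness at remote
follow-up. `sarcnet` packages the analysis such a study needs, for clinical
researchers and biostatisticians: which clinical features and biomarkers are
reproducibly associated with incident sarcopenia and with changes in muscle
quantity and quality?

## The method

**Sarcopenia classification.** Sarcopenia at a timepoint is low handgrip
strength (< 16 kg female / < 27 kg male) together with low muscle quantity:
bilateral anterior thigh thickness BATT = RF_right + VI_right + RF_left +
VI_left < 3.85 / 5.44 cm, and/or skeletal muscle mass below 15 / 20 kg,
estimated from bioimpedance by the Sergi equation

    SMM = −3.964 + 0.227·Ht²/R + 0.095·Wt + 1.384·male + 0.064·Xc

(the Janssen equation is also provided). Comparisons are strict; values at a
cutoff are not low.

**Stability selection.** For each cell of a model grid — analysis variant
(all participants vs the biomarker subset) × outcome (sarcopenia status,
echogenicity change, BATT change, SMM change) × horizon (7 days, 13 weeks) ×
predictor timepoint, 2·4·2·4 = 64 models by default — the pipeline deletes
features with ≥ 30% missing values, imputes the rest (median / mode),
standardizes, and fits B bootstrap replicates of an L1-penalized regression
(logistic for status, linear for changes), with B scaled linearly from 20 to
70 by sample size and the penalty weight chosen by seeded 5-fold
cross-validation. Baseline sarcopenia status is a forced, unpenalized
covariate. Features whose selection count exceeds the threshold

    t = (max(counts) + Q3(counts)) / 2

have their nonzero coefficients averaged with 95% percentile confidence
intervals. Per-stratum results combine into signed, weighted feature→outcome
networks (green positive, red negative).

Because studies of this design rarely deposit raw data, the package includes
a seeded synthetic-cohort generator reproducing the study structure (group
sizes 24/14/41, visit schedule, missingness pattern) with planted
ground-truth effects, so the whole pipeline is testable end to end.

## Worked example

```sh
sarcnet simulate --seed 7 --out cohort.csv
sarcnet run --cohort cohort.csv --seed 7 --outdir results_run
```

which prints, for the bundled study-like defaults:

```
wrote 233 rows for 79 participants to cohort.csv
fitted 64 models (0 skipped); artifacts in results_run
```

`results_run/table2.csv` then lists one row per retained association, e.g.

```
variant,outcome,horizon,predictor_timepoint,feature,coefficient,ci_low,ci_high,selected,tested,n_rows,retrodictive
all_data,BATT,d7,h48,cond_delirium,-0.601979,-0.813863,-0.407401,62,62,68,False
all_data,Echo,d7,h48,cond_COPD,0.402747,0.163267,0.666882,59,59,64,False
```

read: delirium carried a mean standardized coefficient of −0.60 (95% CI
−0.81 to −0.41) for the 7-day change in thigh thickness and was selected in
62 of 62 bootstrap replicates of that model; COPD was positively associated
with the 7-day change in echogenicity (worsening muscle quality). Both are
effects the generator plants, recovered from the synthetic cohort. `results_run/networks/` holds the per-stratum GraphML/TSV
networks, `missingness.csv` the missing-data matrix, and `manifest.json` the
config hash, seed and versions needed to re-run bit-identically.

Library use mirrors the CLI:

```python
from sarcnet import PipelineConfig, run_pipeline
run = run_pipeline(PipelineConfig(seed=7))      # simulates by default
best = run.results[0].summaries
```

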