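# Methods

## Scope and model

`sarcnet` implements an association-screening pipeline for small
longitudinal cohorts of older adults around a stressor event, built from
four layers:

1. **Clinical derivations** (`sarcnet.cohort`). Bilateral anterior thigh
   thickness (BATT, cm) is the sum of the rectus femoris and vastus
   intermedius thicknesses on both sides. Skeletal muscle mass (kg) is
   estimated from bioimpedance by the Sergi equation
   (SMM = −3.964 + 0.227·Ht²/R + 0.095·Wt + 1.384·male + 0.064·Xc, with
   height in cm, resistance and reactance in ohm, weight in kg) and the
   Janssen equation (SM = 0.401·Ht²/R + 3.825·male − 0.071·age + 5.102).
   The coefficients live in one named-constant block so they can be
   corrected without code changes; sex is encoded male = 1, the convention
   of the source equations. Sarcopenia at a timepoint is low handgrip
   strength AND (low BATT and/or low SMM), with per-sex cutoffs
   16/27 kg, 3.85/5.44 cm and 15/20 kg and *strict* comparisons: a value
   exactly at a cutoff is not low.

2. **Preprocessing** (`sarcnet.preprocessing`). One model's table holds
   constant predictors (age, sex, ethnicity and smoking one-hot encoded with
   the first observed level as reference, comorbidity and medication flags)
   plus the measurements of the predictor timepoint, suffixed `@timepoint`.
   Systemic biomarkers enter only for preoperative and 48-hour predictor
   timepoints, when they are drawn. Continuous outcomes are signed changes,
   horizon minus baseline, where a participant's baseline is the
   preoperative visit when attended and the 48-hour visit otherwise. The
   published order is kept: delete features with a missing fraction **at or
   above 0.30**, impute the remainder (median for numeric, mode for
   binary/categorical), standardize. The `biomarker_subset` variant instead
   restricts rows to participants with biomarker data and imputes everything
   (threshold 1.0, removing only entirely-missing columns — imputation
   requires that much). Baseline sarcopenia status is a *forced* covariate:
   exempt from deletion, constant-dropping and penalization.

3. **Stability selection** (`sarcnet.selection`). Per model: B bootstrap
   resamples of participants (B = round(20 + 50·(n−10)/69) clamped to
   [20, 70], anchors configurable — a linear reconstruction of
   "20 to 70 depending on sample size" with the full cohort of 79 at 70),
   an L1- or elastic-net-penalized fit per resample, selection counting at
   |β| > 1e−8, the relative threshold t = (max + Q3)/2 over the counts (Q3
   by linear interpolation at position 0.75·(m−1)), and for features
   strictly above t the mean of their *nonzero* draws with a 95% percentile
   interval (2.5th/97.5th; [min, max] below four draws).

4. **Networks** (`sarcnet.network`). Each selected (feature, outcome) pair
   is an edge weighted by the averaged standardized coefficient; when
   several models of a stratum select the same pair, the unweighted mean of
   the per-model means is used and the encounter count accumulates. Feature
   node identity includes the timing tag, so the same comorbidity tested
   against 48-hour data and preoperative data forms two nodes.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `missing_thresholds` | 0.30 / 1.0 | per-variant deletion threshold (fraction missing) |
| `replicate_count` anchors | 20–70 over n = 10–79 | bootstrap replicates per model |
| `cv_folds` | 5 | internal cross-validation folds (reduced to n−1, min 2, for tiny tables) |
| `lambda_rule` | `"min"` | penalty at CV-loss minimum; `"1se"` picks the sparsest λ within one SE |
| `penalty`, `mixing` | `lasso`, 1.0 | elastic-net mixing; 0.5 is a sensible elastic-net default |
| `stratify_bootstrap` | on | class-stratified resampling for status outcomes, avoiding single-class replicates |
| `SarcopeniaCutoffs` | printed values | per-sex diagnostic cutoffs |

## Numerical conventions

- "Selected" means |coefficient| > 1e−8; lasso solvers return exact zeros,
  the tolerance only guards float dust.
- Regression fits profile the intercept and forced covariates out exactly by
  least-squares residualization; the profiled problem is exactly the lasso
  with unpenalized covariates. Logistic fits approximate zero penalty by
  rescaling forced columns ×100 (effective penalty 1%), as exact penalty
  factors are not exposed by the solver.
- The regression penalty weight is scikit-learn's per-sample `alpha`; the
  logistic penalty λ corresponds to C = 1/(nλ) and is searched on a fixed
  log grid (10 points, 1e−3 to 10^0.5), appropriate for standardized
  predictors at these sample sizes. CV ties break toward the larger penalty.
- Medians of even counts are midpoints of the central order statistics; mode
  ties break to the first-observed value in column order. Both keep runs
  reproducible.
- Zero-variance predictors are dropped (logged) after imputation; a constant
  forced column is kept unscaled.
- Every random draw descends from one integer seed via `SeedSequence`;
  a repeated run writes byte-identical CSV/JSON/GraphML artifacts.
- Rank-sum tests in the descriptive biomarker summary use the normal
  approximation without continuity correction, so identical groups give
  p = 1 exactly; groups with fewer than two observations are flagged not
  computable.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *statistical shape* of such a study: group
sizes 24/14/41 (configurable), the visit schedule (preoperative visits only
for elective patients; SPPB/gait/patient-reported function collected on the
study's per-group schedule; biomarkers preoperatively and, for a configurable
64.6% of participants, at 48 hours), truncated-normal ages (mean 79.1,
SD 6.6, floor 70), 39.2% female, per-sex muscle baselines with
group-specific time deltas and Gaussian visit noise, log-normal biomarkers,
Bernoulli comorbidity/medication flags, MCAR cell missingness with a heavier
13-week rate (0.45 vs 0.02–0.08) plus visit dropout, and *assessment blocks*:
the four ultrasound thicknesses share one missingness draw, as do the three
bioimpedance values, because an instrument reading is lost as a unit.

Ground truth is planted explicitly. Continuous effects shift the latent
outcome trajectory at the chosen horizon (BATT effects are split over the
four thickness components; SMM effects adjust the latent SMM and the
resistance is back-solved through the Sergi equation, so the pipeline's
derived SMM reproduces the latent value). Sarcopenia status at 7 days and
13 weeks is drawn from a logistic model whose linear predictor holds an
intercept, the baseline status (itself classified from the generated
baseline measurements through the real cutoffs) and the planted log-odds
effects — the same linear/logistic forms the selection engine assumes, so
parameter recovery is a fair test.

Not emulated: informative (MNAR) missingness, realistic biomarker
correlation structure, and physiological coupling between the planted
7-day/13-week status and the muscle measurements at those visits (status is
model-generated there, not derived from the measurements). Passing tests
therefore demonstrate that the engine recovers effects *of the assumed
form* under realistic sparsity and missingness — not that the model family
is correct for real cohorts.

## Problem sizes used in tests and the reproduction script

Deterministic checks run on hand-sized fixtures (5×3 orthonormal designs,
count vectors, 12-participant cohorts). Monte-Carlo checks use cohorts of
150 (planted-effect recovery and null behaviour, 20 repeats) and the full
default 79-participant, 64-model grid run twice for byte-level determinism;
marginal-distribution checks use single draws of 2,500–4,000 participants.
These sizes give comfortable Monte-Carlo margins for the assertions made
while keeping a full test run in minutes on one core.

## Design choices where the design was open

- **Replicate-count rule**: only the range 20–70 and its dependence on
  sample size are specified by the analysis being reimplemented; the linear
  interpolation with anchors n = 10 and n = 79 is this package's
  reconstruction, monotone and clamped.
- **Missing quantity measures in the sarcopenia call**: a third category
  `indeterminate` is returned whenever the observed values cannot settle the
  definition (e.g. strength low, one quantity arm missing, the other
  non-low). Indeterminate statuses become missing outcomes and the
  participant drops from that model.
- **Confidence intervals** are bootstrap percentiles over the nonzero draws;
  averaging over nonzero draws (not all B) matches reporting averaged
  coefficients next to selected counts.
- **The 30% rule is applied per model table**, since each model has its own
  row set and therefore its own column census.
- **Imputation is computed once per model table**, not re-estimated inside
  each bootstrap replicate — mirroring the stated order (impute, then
  model). This leaks a little information into the resamples and is a known
  optimism source.
- **Stratified bootstrap** for status outcomes is a deliberate deviation
  from plain i.i.d. resampling, taken for stability (it eliminates
  single-class replicates); it can be switched off
  (`stratify_bootstrap=False`).
- **Grid factorization**: 64 = 2 variants × 4 outcomes × 2 horizons × 4
  predictor timepoints. The grid is config-driven, so other factorizations
  are expressible; cells whose predictors are measured at or after the
  outcome horizon are fitted when configured but flagged `retrodictive`.

## Known limitations

- With `lambda_rule="min"` the per-replicate penalty is permissive: in
  pure-noise cohorts (n = 150, ~45 candidates) a null feature whose chance
  in-sample correlation with the outcome reaches ≈0.25 can be selected in
  most — occasionally all — bootstrap replicates of that cohort. The
  relative threshold usually, but not always, cuts such features from the
  summary. The `"1se"` rule is markedly sparser and available per config;
  no formal per-family error control (stability-selection bounds) is
  implemented.
- Classification models at very small n (preoperative predictor, 13-week
  horizon) can run with few informative rows; they are reported with their
  `n_rows` and flagged `unstable` when more than 20% of replicates are
  discarded as degenerate.
- Coefficients are reported on the standardized scale; `unscale_coefficient`
  maps them back per model, but cross-model averages in the networks remain
  standardized quantities.
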