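# Methods

## Model and assumptions

`labmort` predicts death within 7 days of a day of laboratory testing, using
only what the laboratory information system holds: numeric results, patient
demographics (sex, age, dialysis status) and per-day testing context
(requesting department, patient location). The unit of analysis is the
*patient-day* — one (patient, test date) pair — and the model is a binary
classifier over patient-days. The key assumptions are:

* the informative signal is *how far* results deviate from their item-specific
  norms, not their raw values, so every item can contribute on a common scale
  after robust standardization;
* a day's results can be collapsed to exchangeable summary statistics (counts,
  rates and the mean of the standardized deviations) without per-item
  features, which makes the predictor vector fixed-length regardless of which
  of the >1,000 possible items were ordered;
* labels are determined solely by the recorded death date: positive for test
  days 0–7 days before death, negative otherwise (including all days of
  patients with no recorded death). Days exactly 8 days before death are
  negative — the window is the closed interval [0, 7].

## Robust standardization (the value summary list)

For each item: Q1 and Q3 over **all** of the item's values (no prior
exclusion), fences Q1 − 1.5·IQR and Q3 + 1.5·IQR, then μ_k and σ_k over the
values inside the **closed** fence interval, in a single pass (the fence is
not iterated). Conventions fixed for determinism and recorded in the
serialized JSON:

* quantiles: linear interpolation between order statistics (numpy default,
  the common "type 7" rule);
* σ_k: sample denominator (n − 1);
* boundary values are not outliers (closed interval).

Items whose fenced subset has fewer than two values, or zero spread, are
retained with σ = 0 and flagged *degenerate*; featurization skips them with a
counted warning, never emitting a missing value. SDL uses the absolute
deviation |X − μ_k|/σ_k: the Over2SD/Over3SD semantics ("two or more standard
deviations away from the mean") and the use of mean SDL as a severity feature
both require unsigned distance. Thresholds at 2 and 3 are inclusive.

## Feature layout (44 predictors)

13 scalar/indicator fields — sex, age (floor of whole years at the test
date), dialysis, 4 location indicators (outpatient, general ward, intensive
care, palliative care), item count, Over2SD/Over3SD counts and rates, mean
SDL — plus 31 requesting-department indicators (30 named departments and
"Others"). Exactly one location and one department indicator are set per row.
The vocabulary is configurable, but the default reproduces the 44-predictor
layout. The day's item count counts *scorable* items (those covered by a
non-degenerate summary entry); a day with zero scorable items yields no row.

## Critical value list

The CVL ships as data (`labmort/data/cvl_rules.json`): 22 single-item numeric
rules (12 chemistry, 7 hematology, 3 coagulation), each a low and/or high
bound, both inclusive, matching the conventional "≦ low or ≧ high" reading.
Composite quantities such as the lymphocyte rate are treated as independent
single-item thresholds. As a day-level classifier the CVL predicts positive
iff **any** of the day's results breaches its rule — the only reading
consistent with day-level confusion counts — and site-specific LIS codes map
onto the fixture through an alias table. We recompute threshold breaches from
values rather than replaying an operational callback log.

## Training pipeline

Stratified 70/30 split (per-class counts within one row of exact
stratification), then stratified random undersampling of the training
majority class: all positives kept, negatives sampled without replacement to
an exact 50:50 balance. The classifier is XGBoost (`binary:logistic`,
histogram tree method, single thread) with defaults of 200 trees, depth 4,
learning rate 0.1, subsample and column subsample 0.9. The random-search
space covers tree count, depth, learning rate, subsampling rates and minimum
child weight; draws are scored by mean stratified k-fold cross-validation
ROC-AUC (default k = 10) with ties broken by the earliest draw.
Cross-validation folds are drawn from the *balanced* training set by default
(fold threshold metrics at 0.5 are then interpretable); validating against
the full unbalanced 70% partition is available by running `cross_validate`
on that partition directly. Fold threshold metrics use 0.5, consistent with
training on balanced data.

## Evaluation protocol

* Hard classifiers (the CVL) get the single-operating-point ROC-AUC
  (sensitivity + specificity)/2 — the area under the two-segment ROC through
  their one (FPR, TPR) point. This identity is property-tested against the
  rank AUC of the equivalent 0/1 scores.
* Score classifiers get the rank ROC-AUC (ties counted half), computed via
  the trapezoid under the empirical ROC and tested against an exhaustive
  pairwise oracle.
* The head-to-head comparison counts, per classifier, correct ("true
  result") and incorrect ("false result") day-level predictions over all
  patient-days, and applies a two-sided Fisher's exact test (summing
  hypergeometric probabilities ≤ the observed table's, the scipy
  convention). The two classifiers' counts are in fact *paired*, which
  Fisher's test ignores; the protocol is reproduced as specified, and an
  exact McNemar test on discordant pairs is available separately for the
  statistically strict comparison.
* Model interpretability uses exact TreeSHAP contributions computed natively
  by XGBoost (`pred_contribs`), reported as mean |contribution| per feature
  in log-odds units, alongside normalized total-gain importances.

## Synthetic cohort generator

No public LIS extract exists at this scale, so the generator emulates the
statistical structure of a 12-month adult cohort of an urban teaching
hospital. Defaults (all in `SyntheticParams`):

* 5,000 patients, ≈20,000 patient-days over 365 days; positive patient-day
  fraction 0.006; ages N(59, 18.5²) clipped to ≥18; 59% female; 3% dialysis.
* Department and location sampling weights proportional to observed test
  volumes (outpatient-dominated; 31-department vocabulary).
* 60 item types: the first 22 are the critical-value panel items with
  realistic healthy means/SDs placed so each CVL bound sits ≈2.5–3.5 SD from
  the mean (giving the CVL genuine signal and a realistic ≈5–10% day-level
  flag rate); the rest are generic items with random scales. Items per day:
  1 + Poisson(20) — scaled down from the ≈34 items/test of a full
  biochemistry panel for runtime.
* Deceased patients (count solved so the expected positive fraction hits the
  target; their ordinary test days are placed ≥8 days before death) receive
  1 + Poisson(1.5) final-week test days (≈2.5, matching the observed ≈2.6
  positive days per deceased patient). Final-week days carry the terminal
  signature: item counts ×1.4, a per-day severity multiplier on all z-scores
  drawn U(1, 3) so some terminal days are only mildly abnormal, and location
  reweighted toward intensive/palliative care. A 2% heavy-tail fraction
  (z ×4) on all days provides baseline Over3SD events and CVL false
  positives.

The per-day severity draw is what produces the published qualitative regime
— a CVL that catches only the grossly deranged terminal days (recall ≈0.6–0.7
at FPR ≈0.05–0.09) while the boosted model integrates milder but broad
deviations (rank AUC ≈0.98). What the generator does **not** emulate:
between-item correlation (real panels are strongly correlated), within-
patient temporal autocorrelation across days, item-specific skewed
distributions, department–item dependence, and informative test-ordering
beyond the terminal item-count inflation. Passing tests therefore show the
pipeline recovers a terminal-deviation signal of realistic size and shape,
not that the quantitative performance transfers to any real hospital.

## Numerical choices and degenerate inputs

* All randomness flows through explicit integer seeds (numpy `default_rng`,
  sklearn `random_state`, xgboost `random_state`); CLI runs write a manifest
  with seeds, config hash and library versions.
* Fisher tables with a zero margin return p = 1 with a `degenerate` flag;
  confusion matrices with no predicted positives report precision = F1 = 0
  with a flag; single-class inputs to splitting, fitting or AUC raise.
* The generator validates the realized positive fraction against the
  requested one (default relative tolerance 0.5, tight enough to catch
  construction errors while allowing small-sample noise at a 0.6% rate).
* XGBoost's default minimum child weight (1) means toy datasets with fewer
  than ~8 rows per class train no splits (logistic hessians are 0.25/row);
  tests on such toys relax it explicitly.

## Problem sizes used in the shipped checks

Reference metrics and Fisher comparisons are exact arithmetic on published
day-level counts (instant). The undersampling contract runs at study scale
(155,461 rows). The end-to-end model-vs-CVL property uses the default
generator size (≈20,000 patient-days) over 10 seeds — about 1 s per seed —
and the null-effect check (all terminal effects off ⇒ AUC ≈ 0.5) uses 2,000
patients × 5 seeds with a 2% positive rate to stabilize the held-out AUC
estimate at small n.
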