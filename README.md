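# labmort

Short-term (7-day) all-cause in-hospital mortality prediction from numeric
laboratory results, with the conventional critical-value-list callback as the
baseline it is measured against.

## The problem

Hospital laboratories flag "critical" (panic) values — results so far outside
the normal range that they signal an immediately life-threatening state — by
comparing each result against a per-item threshold table, the critical value
list (CVL). The CVL covers only a couple of dozen items, treats each in
isolation, and either fires or doesn't. Yet the laboratory information system
(LIS) holds the *entire* day's numeric results for every patient, and how far
those results sit from their item-specific norms carries far more signal about
imminent death than any single threshold breach. `labmort` turns one day of a
patient's numeric results into a fixed-length feature vector and trains a
gradient-boosted-tree classifier of death within 7 days, then evaluates it
head-to-head against the CVL.

## The method

**Robust standardization (SDL).** For each laboratory item *k*, quartiles Q1
and Q3 are computed over all observed values, Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] exclude gross outliers, and the reference mean
μ_k and SD σ_k are estimated from the values inside the closed fence interval
(this is the *value summary list*). A raw result X is standardized to its
standard-deviation level

    SDL = |X − μ_k| / σ_k ,

with Over2SD ⇔ SDL ≥ 2 and Over3SD ⇔ SDL ≥ 3 (both inclusive).

**Patient-day features.** Each (patient, test date) pair becomes one row with
44 predictors: sex, age, dialysis status, 4 patient-location indicators, 31
requesting-department indicators, and six aggregates of the day's SDL values —
item count, Over2SD and Over3SD counts and rates, and mean SDL. No missing
values can arise by construction. The label is positive iff the day falls 0–7
days before the patient's recorded death.

**Training.** Positives are ~0.6% of patient-days, so after a stratified
70/30 split the training majority class is randomly undersampled to an exact
50:50 balance; an XGBoost classifier is then fitted, optionally tuned by
random hyperparameter search with stratified 10-fold cross-validation scored
by ROC-AUC.

**Evaluation.** The CVL is a hard classifier (a day is positive iff any
result breaches its item's thresholds), so its ROC-AUC is the single-operating
-point area (sensitivity + specificity)/2; the boosted model uses the usual
rank AUC. Classifiers are compared by their total correct ("true result") and
incorrect ("false result") day-level predictions with a two-sided Fisher's
exact test.

## Worked example

```python
from labmort import MortalityModel, generate_synthetic_cohort

cohort = generate_synthetic_cohort(seed=42)        # ~5,000 patients, ~20,000 patient-days
results = MortalityModel.from_cohort(cohort).fit(seed=42, cv=10)
print(results.summary())
report = results.compare_with_cvl(cohort)
print("CVL ROC-AUC:", round(report["cvl"]["metrics"]["roc_auc"], 4))
print("Fisher p:", report["comparison"]["fisher_p"])
```

prints

```
        Seven-day mortality model (gradient boosted trees)
====================================================================
Training rows (balanced):        174    positives: 87
Held-out rows:                  6008    positives: 37
Predictors: 44    seed: 42
--------------------------------------------------------------------
Held-out performance (threshold 0.5):
  ROC-AUC (scores)    0.9857
  accuracy            0.9632
  recall              0.9730
  specificity         0.9632
  precision           0.1406
  F1                  0.2457
--------------------------------------------------------------------
Cross-validation (10 folds, balanced training data):
  ROC-AUC  0.9880 ± 0.0171    recall  0.9431 ± 0.0798
  accuracy 0.9366 ± 0.0565    F1      0.9365 ± 0.0589
--------------------------------------------------------------------
Top features (gain importance):
  count_over2sd                0.5330
  mean_sdl                     0.1591
  count_item                   0.0982
  loc_outpatient               0.0616
  rate_over2sd                 0.0513
====================================================================

CVL ROC-AUC: 0.8399
Fisher p: 0.00012719190419972654
```

The model ranks held-out patient-days far better than the CVL baseline
(rank AUC 0.986 vs 0.840), with high recall but — as expected at a 0.6%
positive rate trained on balanced data — low precision: the intended use is
as decision support for the laboratory callback, not automated alerting.
The dominant features are the deviation aggregates (Over2SD count, mean SDL)
and whether the patient is an outpatient.

The same pipeline is available from the shell:

```
labmort simulate --seed 42 --out cohort/
labmort fit      --cohort cohort/ --seed 42 --out fit/
labmort evaluate --model fit/ --cohort cohort/ --seed 42 --held-out --out eval/
```

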