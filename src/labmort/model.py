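"""Model/Results interface over the full pipeline.

`MortalityModel` holds a patient-day feature table (built from a cohort or
supplied directly); `fit()` runs stratified splitting, majority
undersampling, optional random hyperparameter search, k-fold
cross-validation and the final boosted-tree fit, and returns a
:class:`MortalityResults` carrying the fitted model, the cross-validation
report, held-out evaluation helpers and a text ``summary()``.

    >>> cohort = generate_synthetic_cohort(seed=7)
    >>> model = MortalityModel.from_cohort(cohort)
    >>> res = model.fit(seed=7, cv=10)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as _evaluate
from . import train as _train
from .cvl_engine import CVLRuleSet, load_cvl
from .featurize import FEATURE_COLUMNS, LABEL_COLUMN, build_feature_table
from .lis_data import Cohort
from .value_summary import ValueSummaryList, build_value_summary


class MortalityModel:
    """Seven-day mortality model over one-day laboratory feature rows.

    Parameters
    ----------
    features : patient-day feature table with the 44 predictor columns and a
        binary ``label`` column (see :mod:`labmort.featurize`).
    summary : the value summary list used to standardize results, kept for
        provenance and for scoring new cohorts.
    """

    def __init__(self, features: pd.DataFrame,
                 summary: ValueSummaryList | None = None):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:4]}")
        if LABEL_COLUMN not in features.columns:
            raise ValueError("feature table has no label column")
        self.features = features.reset_index(drop=True)
        self.summary = summary

    @classmethod
    def from_cohort(cls, cohort: Cohort,
                    summary: ValueSummaryList | None = None) -> "MortalityModel":
        """Build the value summary from the cohort (unless given) and featurize."""
        summary = summary or build_value_summary(cohort.results)
        return cls(build_feature_table(cohort, summary), summary)

    def fit(self, hyperparameters: dict | None = None, *,
            train_fraction: float = 0.70, undersample: bool = True,
            cv: int = 0, n_search: int = 0, seed: int = 0) -> "MortalityResults":
        """Split, rebalance, optionally search and cross-validate, then fit.

        ``cv=k`` runs stratified k-fold cross-validation on the (balanced)
        training data; ``n_search=m`` first picks hyperparameters by random
        search with m draws.  All randomness derives from ``seed``.
        """
        train_rows, test_rows = _train.stratified_split(
            self.features, _train.SplitSpec(train_fraction, seed=seed))
        fit_rows = (_train.undersample_majority(train_rows, seed=seed)
                    if undersample else train_rows)

        search_log = None
        if n_search:
            hyperparameters, search_log = _train.random_search(
                fit_rows, n_draws=n_search, k=max(cv, 3), seed=seed)
        cv_report = (_train.cross_validate(fit_rows, hyperparameters, k=cv, seed=seed)
                     if cv else None)
        fitted = _train.fit_gbt(fit_rows, hyperparameters, seed=seed)
        return MortalityResults(model=fitted, parent=self,
                                train_rows=fit_rows, test_rows=test_rows,
                                cv_report=cv_report, search_log=search_log,
                                seed=seed)


@dataclass
class MortalityResults:
    """Fitted pipeline: booster, partitions, CV report and evaluation helpers."""

    model: _train.TrainedModel
    parent: MortalityModel
    train_rows: pd.DataFrame
    test_rows: pd.DataFrame
    cv_report: _train.CVReport | None = None
    search_log: pd.DataFrame | None = None
    seed: int = 0

    def predict(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Mortality scores for ``rows`` (default: the held-out partition)."""
        return self.model.predict_scores(self.test_rows if rows is None else rows)

    def evaluate(self, rows: pd.DataFrame | None = None,
                 threshold: float = 0.5) -> _evaluate.MetricSet:
        """Threshold metrics plus hard AUC on ``rows`` (default held-out)."""
        rows = self.test_rows if rows is None else rows
        cm = _evaluate.confusion(self.model.predict_labels(rows, threshold),
                                 rows[LABEL_COLUMN])
        return _evaluate.metrics_from_confusion(cm)

    def roc_auc(self, rows: pd.DataFrame | None = None) -> float:
        """Rank ROC-AUC of the scores on ``rows`` (default held-out)."""
        rows = self.test_rows if rows is None else rows
        auc, _ = _evaluate.roc_auc_from_scores(self.predict(rows), rows[LABEL_COLUMN])
        return auc

    def compare_with_cvl(self, cohort: Cohort,
                         rows: pd.DataFrame | None = None,
                         rules: CVLRuleSet | None = None,
                         threshold: float = 0.5,
                         attribution: bool = False) -> dict:
        """Head-to-head report (confusions, metrics, ROC, Fisher) vs the CVL.

        ``rows`` defaults to the held-out partition; CVL day predictions are
        computed from ``cohort.results`` restricted to those patient-days.
        """
        rows = self.test_rows if rows is None else rows
        rules = rules or load_cvl()
        days = rules.predict_days(cohort.results)
        keyed = rows.merge(days, on=["patient_id", "test_date"],
                           how="left", validate="one_to_one")
        if keyed["prediction"].isna().any():
            raise ValueError("cohort results do not cover all evaluation days")
        return _evaluate.build_report(
            labels=keyed[LABEL_COLUMN],
            model_scores=self.model.predict_scores(keyed),
            cvl_predictions=keyed["prediction"].astype(int),
            threshold=threshold,
            model=self.model if attribution else None,
            feature_rows=keyed if attribution else None)

    def feature_importances(self) -> pd.Series:
        return self.model.feature_importances()

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        m = self.evaluate()
        auc = self.roc_auc()
        lines = [
            "        Seven-day mortality model (gradient boosted trees)",
            "=" * 68,
            f"Training rows (balanced):   {self.model.n_train:>8d}"
            f"    positives: {self.model.n_positive}",
            f"Held-out rows:              {len(self.test_rows):>8d}"
            f"    positives: {int(self.test_rows[LABEL_COLUMN].sum())}",
            f"Predictors: {len(self.model.feature_columns)}    seed: {self.seed}",
            "-" * 68,
            "Held-out performance (threshold 0.5):",
            f"  ROC-AUC (scores)  {auc:8.4f}",
            f"  accuracy          {m.accuracy:8.4f}",
            f"  recall            {m.recall:8.4f}",
            f"  specificity       {m.specificity:8.4f}",
            f"  precision         {m.precision:8.4f}",
            f"  F1                {m.f1:8.4f}",
        ]
        if self.cv_report is not None:
            mean, sd = self.cv_report.mean, self.cv_report.sd
            lines += [
                "-" * 68,
                f"Cross-validation ({len(self.cv_report.folds)} folds, balanced training data):",
                f"  ROC-AUC  {mean['roc_auc']:.4f} ± {sd['roc_auc']:.4f}"
                f"    recall  {mean['recall']:.4f} ± {sd['recall']:.4f}",
                f"  accuracy {mean['accuracy']:.4f} ± {sd['accuracy']:.4f}"
                f"    F1      {mean['f1']:.4f} ± {sd['f1']:.4f}",
            ]
        top = self.feature_importances().head(5)
        lines += ["-" * 68, "Top features (gain importance):"]
        lines += [f"  {name:<28s} {val:.4f}" for name, val in top.items()]
        lines.append("=" * 68)
        return "\n".join(lines)
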