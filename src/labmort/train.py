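"""Model training: stratified split, majority undersampling, gradient boosting.

The outcome (death within 7 days of a test day) occurs on roughly 0.6% of
patient-days, so the pipeline is: stratified 70/30 split of the feature
table, stratified random undersampling of the training majority class down
to a 50:50 balance, then an XGBoost classifier tuned by random search over a
documented hyperparameter space with stratified 10-fold cross-validation
scored by ROC-AUC.  Every stochastic stage takes an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .featurize import FEATURE_COLUMNS, LABEL_COLUMN

DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_weight": 1,
}

#: Default random-search space: lists are sampled uniformly; pairs are
#: uniform (int) ranges.
DEFAULT_SEARCH_SPACE: dict = {
    "n_estimators": [100, 200, 400],
    "max_depth": [2, 3, 4, 6, 8],
    "learning_rate": [0.03, 0.1, 0.3],
    "subsample": [0.7, 0.9, 1.0],
    "colsample_bytree": [0.7, 0.9, 1.0],
    "min_child_weight": [1, 3, 5],
}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout specification."""

    train_fraction: float = 0.70
    seed: int = 0
    stratify_on: str = LABEL_COLUMN

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainedModel:
    """Fitted booster plus everything needed to reproduce and apply it."""

    booster: xgb.Booster
    hyperparameters: dict
    feature_columns: tuple[str, ...]
    seed: int
    n_train: int
    n_positive: int

    def _dmatrix(self, rows: pd.DataFrame) -> xgb.DMatrix:
        X = rows[list(self.feature_columns)].to_numpy(dtype=float)
        return xgb.DMatrix(X, feature_names=list(self.feature_columns))

    def predict_scores(self, rows: pd.DataFrame) -> np.ndarray:
        """Mortality scores in [0, 1]; enforces the training feature order."""
        return self.booster.predict(self._dmatrix(rows))

    def predict_labels(self, rows: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(rows) >= threshold).astype(int)

    def feature_importances(self) -> pd.Series:
        """Total-gain importance per feature, normalized to sum 1, descending."""
        gains = self.booster.get_score(importance_type="total_gain")
        imp = pd.Series({c: gains.get(c, 0.0) for c in self.feature_columns})
        total = imp.sum()
        if total > 0:
            imp /= total
        return imp.sort_values(ascending=False)

    def shap_values(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Exact TreeSHAP contributions per row and feature (log-odds units)."""
        contrib = self.booster.predict(self._dmatrix(rows), pred_contribs=True)
        return pd.DataFrame(contrib[:, :-1], columns=list(self.feature_columns))

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(out / "model.ubj")
        sidecar = {
            "hyperparameters": self.hyperparameters,
            "feature_columns": list(self.feature_columns),
            "seed": self.seed,
            "n_train": self.n_train,
            "n_positive": self.n_positive,
        }
        (out / "model.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, out_dir) -> "TrainedModel":
        out = Path(out_dir)
        sidecar = json.loads((out / "model.json").read_text())
        booster = xgb.Booster()
        booster.load_model(out / "model.ubj")
        return cls(booster=booster,
                   hyperparameters=sidecar["hyperparameters"],
                   feature_columns=tuple(sidecar["feature_columns"]),
                   seed=sidecar["seed"],
                   n_train=sidecar["n_train"],
                   n_positive=sidecar["n_positive"])


def stratified_split(rows: pd.DataFrame,
                     spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random partition into (train, test) at ``train_fraction``.

    Per-class counts land within one row of exact stratification; the split
    is a partition (train ∪ test = input, disjoint) and reproducible by seed.
    """
    y = rows[spec.stratify_on]
    if (y.value_counts() < 2).any():
        raise ValueError("each class needs at least 2 rows to stratify")
    train, test = train_test_split(rows, train_size=spec.train_fraction,
                                   stratify=y, random_state=spec.seed)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def undersample_majority(rows: pd.DataFrame, seed: int = 0,
                         label_col: str = LABEL_COLUMN) -> pd.DataFrame:
    """Random undersampling of the majority class to an exact 50:50 balance.

    Every minority row is retained; majority rows are sampled without
    replacement down to the minority count.  Already-balanced input is
    returned unchanged up to row order.
    """
    counts = rows[label_col].value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("both classes must be present")
    minority = counts.idxmin() if counts.iloc[0] != counts.iloc[1] else counts.index[1]
    minority_rows = rows[rows[label_col] == minority]
    majority_rows = rows[rows[label_col] != minority]
    sampled = majority_rows.sample(n=len(minority_rows), replace=False,
                                   random_state=seed)
    out = pd.concat([minority_rows, sampled])
    return out.sample(frac=1.0, random_state=seed).reset_index(drop=True)


def _make_classifier(hyperparameters: dict, seed: int) -> xgb.XGBClassifier:
    params = dict(DEFAULT_HYPERPARAMETERS)
    params.update(hyperparameters or {})
    return xgb.XGBClassifier(
        objective="binary:logistic",
        eval_metric="auc",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )


def fit_gbt(rows: pd.DataFrame, hyperparameters: dict | None = None,
            seed: int = 0) -> TrainedModel:
    """Fit the gradient-boosted-tree classifier on a feature table.

    The feature column order is recorded on the returned model and enforced
    at prediction time.  Identical data, seed and hyperparameters reproduce
    identical scores.
    """
    y = rows[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = _make_classifier(hyperparameters or {}, seed)
    X = rows[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    clf.fit(X, y)
    booster = clf.get_booster()
    booster.feature_names = list(FEATURE_COLUMNS)
    return TrainedModel(booster=booster,
                        hyperparameters={**DEFAULT_HYPERPARAMETERS,
                                         **(hyperparameters or {})},
                        feature_columns=FEATURE_COLUMNS,
                        seed=seed,
                        n_train=len(rows),
                        n_positive=int(y.sum()))


@dataclass
class CVReport:
    """Per-fold metrics with a recomputable mean +/- SD summary."""

    folds: pd.DataFrame          # k rows: accuracy, roc_auc, recall, precision, f1
    threshold: float = 0.5

    @property
    def mean(self) -> pd.Series:
        return self.folds.mean()

    @property
    def sd(self) -> pd.Series:
        return self.folds.std(ddof=1)

    def table(self) -> pd.DataFrame:
        """Fold rows plus a trailing mean row (k + 1 rows)."""
        mean_row = self.mean.to_frame().T
        mean_row.index = ["mean"]
        return pd.concat([self.folds, mean_row])

    def to_csv(self, path) -> None:
        table = self.folds.copy()
        table.index.name = "validation"
        summary = pd.DataFrame(
            {c: [f"{self.mean[c]:.4f} ± {self.sd[c]:.4f}"] for c in table.columns},
            index=["mean ± SD"])
        pd.concat([table.round(4).astype(object), summary]).to_csv(path)


def cross_validate(rows: pd.DataFrame, hyperparameters: dict | None = None,
                   k: int = 10, seed: int = 0,
                   threshold: float = 0.5) -> CVReport:
    """Stratified k-fold cross-validation of the booster on ``rows``.

    Per fold: accuracy, recall, precision and F1 at ``threshold`` on the
    held-out fold, plus rank-based ROC-AUC of the scores.
    """
    from .evaluate import confusion, metrics_from_confusion, roc_auc_from_scores

    if k < 2:
        raise ValueError("k must be >= 2")
    y = rows[LABEL_COLUMN].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(rows, y), start=1):
        test_y = y[test_idx]
        if len(np.unique(test_y)) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        model = fit_gbt(rows.iloc[train_idx], hyperparameters, seed=seed)
        scores = model.predict_scores(rows.iloc[test_idx])
        cm = confusion((scores >= threshold).astype(int), test_y)
        m = metrics_from_confusion(cm)
        auc, _ = roc_auc_from_scores(scores, test_y)
        records.append({"accuracy": m.accuracy, "roc_auc": auc,
                        "recall": m.recall, "precision": m.precision, "f1": m.f1})
    folds = pd.DataFrame(records, index=pd.RangeIndex(1, k + 1))
    return CVReport(folds=folds, threshold=threshold)


def random_search(rows: pd.DataFrame, search_space: dict | None = None,
                  n_draws: int = 10, k: int = 10,
                  seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Random hyperparameter search scored by mean CV ROC-AUC.

    Returns (best hyperparameters, search log).  Each draw samples one value
    per parameter from its candidate list; ties on the score are broken by
    the earliest draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    space = search_space or DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    log = []
    best_params, best_score = None, -np.inf
    for draw in range(n_draws):
        params = {name: candidates[rng.integers(len(candidates))]
                  for name, candidates in space.items()}
        report = cross_validate(rows, params, k=k, seed=seed)
        score = float(report.mean["roc_auc"])
        log.append({"draw": draw, "mean_roc_auc": score, **params})
        if score > best_score:
            best_params, best_score = params, score
    return best_params, pd.DataFrame(log)
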