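"""Classifier evaluation: confusion matrices, ROC-AUC, Fisher comparison.

Two classifier types meet here.  The gradient-boosted model emits continuous
scores, so its ROC-AUC is the usual rank statistic.  The critical value list
is a hard (single-threshold) classifier: its ROC "curve" is the two-segment
polyline through its one operating point, whose area is exactly
(sensitivity + specificity) / 2 -- that identity is what
``metrics_from_confusion`` reports as ``roc_auc`` and it reproduces the
printed CVL areas from confusion counts alone.

Classifier comparison follows the head-to-head protocol: per classifier, the
"true result" is its total count of correct day-level predictions and the
"false result" its incorrect count; the 2x2 {classifier} x {true, false}
table is tested with Fisher's exact test (two-sided, summing hypergeometric
probabilities no larger than the observed table's).  The counts are paired
across classifiers, which the protocol ignores; McNemar's paired test is
available separately for the statistically strict comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts for a binary classifier (positive = death within 7 days)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def n_correct(self) -> int:
        """The "true result": correct predictions over all laboratory tests."""
        return self.tp + self.tn

    @property
    def n_incorrect(self) -> int:
        """The "false result": incorrect predictions over all laboratory tests."""
        return self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Derived metrics, all in [0, 1].

    ``roc_auc`` here is the hard-classifier area (recall + specificity) / 2;
    use :func:`roc_auc_from_scores` for score-based classifiers.
    ``precision_undefined`` flags the tp + fp = 0 case, where precision and
    F1 are reported as 0.
    """

    accuracy: float
    roc_auc: float
    recall: float
    specificity: float
    precision: float
    f1: float
    precision_undefined: bool = False


def _coerce_binary(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        mapped = np.where(arr == "positive", 1, np.where(arr == "negative", 0, -1))
        if (mapped < 0).any():
            raise ValueError("labels must be 0/1 or 'positive'/'negative'")
        return mapped
    return arr.astype(int)


def confusion(predictions, labels) -> ConfusionMatrix:
    """Cross-tabulate binary predictions against labels."""
    pred = _coerce_binary(predictions)
    y = _coerce_binary(labels)
    if len(pred) != len(y):
        raise ValueError("predictions and labels differ in length")
    if len(y) == 0:
        raise ValueError("empty inputs")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, single-threshold ROC-AUC, recall, specificity, precision, F1."""
    if cm.n_positive == 0:
        raise ValueError("recall undefined: no positive rows")
    recall = cm.tp / cm.n_positive
    specificity = cm.tn / cm.n_negative if cm.n_negative else 1.0
    accuracy = cm.n_correct / cm.total
    undefined = (cm.tp + cm.fp) == 0
    precision = 0.0 if undefined else cm.tp / (cm.tp + cm.fp)
    denom = precision + recall
    f1 = 0.0 if (undefined or denom == 0) else 2 * precision * recall / denom
    return MetricSet(accuracy=accuracy,
                     roc_auc=(recall + specificity) / 2.0,
                     recall=recall,
                     specificity=specificity,
                     precision=precision,
                     f1=f1,
                     precision_undefined=undefined)


def roc_auc_from_scores(scores, labels) -> tuple[float, pd.DataFrame]:
    """Rank-based ROC-AUC with the curve points.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2.  Returns (auc, points) where points has
    columns fpr, tpr, threshold.
    """
    y = _coerce_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for ROC-AUC")
    fpr, tpr, thresholds = _roc_curve(y, np.asarray(scores, dtype=float))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(_trapezoid_auc(fpr, tpr)), points


@dataclass(frozen=True)
class ComparisonResult:
    """Head-to-head true/false-result counts for two classifiers and the p-value."""

    a_name: str
    a_true: int
    a_false: int
    b_name: str
    b_true: int
    b_false: int
    p_value: float
    degenerate: bool = False

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"True result": [self.a_true, self.b_true],
             "False result": [self.a_false, self.b_false]},
            index=[self.a_name, self.b_name])


def fisher_compare(a_true: int, a_false: int, b_true: int, b_false: int,
                   a_name: str = "A", b_name: str = "B") -> ComparisonResult:
    """Two-sided Fisher's exact test on the 2x2 true/false-result table.

    A table with a zero margin carries no information; p is reported as 1
    with the ``degenerate`` flag set.
    """
    for c in (a_true, a_false, b_true, b_false):
        if c < 0:
            raise ValueError("counts must be non-negative")
    table = np.array([[a_true, a_false], [b_true, b_false]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ComparisonResult(a_name, a_true, a_false, b_name, b_true, b_false,
                                p_value=1.0, degenerate=True)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ComparisonResult(a_name, a_true, a_false, b_name, b_true, b_false,
                            p_value=float(p))


def mcnemar_compare(both_correct: int, a_only: int, b_only: int,
                    both_wrong: int) -> float:
    """Exact McNemar p-value on paired discordant predictions (optional)."""
    n = a_only + b_only
    if n == 0:
        return 1.0
    k = min(a_only, b_only)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def build_report(labels, model_scores, cvl_predictions,
                 threshold: float = 0.5,
                 model=None, feature_rows: pd.DataFrame | None = None,
                 top_attribution: int = 10) -> dict:
    """Assemble the model-vs-CVL evaluation report for one dataset.

    Parameters
    ----------
    labels : binary outcome per patient-day.
    model_scores : model scores aligned with ``labels``.
    cvl_predictions : CVL day-level 0/1 predictions aligned with ``labels``.
    model, feature_rows : optionally, a :class:`~labmort.train.TrainedModel`
        and its feature rows, to append a feature-attribution section (mean
        |SHAP| per feature, descending).

    Returns a JSON-serializable dict with per-classifier confusion counts,
    metrics, ROC points for the model, the single operating point for the
    CVL, and the Fisher true/false-result comparison.
    """
    y = _coerce_binary(labels)
    scores = np.asarray(model_scores, dtype=float)
    cvl_pred = _coerce_binary(cvl_predictions)
    if not (len(y) == len(scores) == len(cvl_pred)):
        raise ValueError("labels, scores and CVL predictions must align")

    model_cm = confusion((scores >= threshold).astype(int), y)
    model_metrics = metrics_from_confusion(model_cm)
    model_auc, roc_points = roc_auc_from_scores(scores, y)
    cvl_cm = confusion(cvl_pred, y)
    cvl_metrics = metrics_from_confusion(cvl_cm)
    comparison = fisher_compare(cvl_cm.n_correct, cvl_cm.n_incorrect,
                                model_cm.n_correct, model_cm.n_incorrect,
                                a_name="CVL", b_name="model")

    report = {
        "n_tests": int(len(y)),
        "n_positive": int(y.sum()),
        "threshold": threshold,
        "model": {
            "confusion": asdict(model_cm),
            "metrics": {**asdict(model_metrics), "roc_auc_scores": model_auc},
            "true_result": model_cm.n_correct,
            "false_result": model_cm.n_incorrect,
        },
        "cvl": {
            "confusion": asdict(cvl_cm),
            "metrics": asdict(cvl_metrics),
            "operating_point": {
                "fpr": 1.0 - cvl_metrics.specificity,
                "tpr": cvl_metrics.recall,
            },
            "true_result": cvl_cm.n_correct,
            "false_result": cvl_cm.n_incorrect,
        },
        "comparison": {
            "fisher_p": comparison.p_value,
            "table": {
                "CVL": [comparison.a_true, comparison.a_false],
                "model": [comparison.b_true, comparison.b_false],
            },
        },
        "roc_points": roc_points.to_dict(orient="list"),
    }
    if model is not None and feature_rows is not None:
        shap = model.shap_values(feature_rows)
        mean_abs = shap.abs().mean().sort_values(ascending=False)
        report["attribution"] = {
            "method": "TreeSHAP (mean |contribution|, log-odds units)",
            "top_features": mean_abs.head(top_attribution).round(6).to_dict(),
        }
    return report


def write_report(report: dict, out_dir) -> dict[str, Path]:
    """Write report.json plus CSV tables (confusion, metrics, comparison, ROC)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json"}
    paths["report"].write_text(json.dumps(report, indent=1))

    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    conf = pd.DataFrame({name: report[name]["confusion"] for name in ("cvl", "model")}).T
    conf.to_csv(tables / "confusion.csv")
    paths["confusion"] = tables / "confusion.csv"
    mets = pd.DataFrame({name: {k: v for k, v in report[name]["metrics"].items()
                                if isinstance(v, (int, float))}
                         for name in ("cvl", "model")}).T
    mets.to_csv(tables / "metrics.csv")
    paths["metrics"] = tables / "metrics.csv"
    comp = pd.DataFrame(report["comparison"]["table"],
                        index=["true_result", "false_result"]).T
    comp["fisher_p"] = report["comparison"]["fisher_p"]
    comp.to_csv(tables / "comparison.csv")
    paths["comparison"] = tables / "comparison.csv"
    pd.DataFrame(report["roc_points"]).to_csv(tables / "roc_points.csv", index=False)
    paths["roc_points"] = tables / "roc_points.csv"
    return paths


def plot_roc(report: dict, path) -> None:
    """ROC figure: model curve plus the CVL operating point polyline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    pts = report["roc_points"]
    ax.plot(pts["fpr"], pts["tpr"],
            label=f"model (AUC {report['model']['metrics']['roc_auc_scores']:.4f})")
    op = report["cvl"]["operating_point"]
    ax.plot([0, op["fpr"], 1], [0, op["tpr"], 1], "--",
            label=f"CVL (AUC {report['cvl']['metrics']['roc_auc']:.4f})")
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
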