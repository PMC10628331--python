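import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from labmort import (ConfusionMatrix, confusion, fisher_compare,
                     metrics_from_confusion, roc_auc_from_scores)
from labmort.evaluate import build_report, mcnemar_compare, write_report


def pairwise_auc(scores, labels):
    """Brute-force rank AUC: P(random positive outscores random negative)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_fisher(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum tables with probability <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_complement_predictions(self):
        cm = confusion([0, 1, 0], [1, 0, 1])
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 1 and cm.fn == 2

    def test_string_labels_accepted(self):
        cm = confusion(["positive", "negative"], [1, 0])
        assert cm.tp == 1 and cm.tn == 1

    def test_counts_partition_rows(self):
        rng = np.random.default_rng(0)
        pred, y = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert confusion(pred, y).total == 50

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])


class TestMetrics:
    def test_30pct_cvl_counts_reproduce_printed_metrics(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=239, fp=5842, tn=60785, fn=161))
        assert round(m.roc_auc, 4) == 0.7549
        assert round(m.recall, 4) == 0.5975
        assert round(m.precision, 4) == 0.0393
        assert round(m.f1, 4) == 0.0738

    def test_validation_cvl_counts_reproduce_printed_auc(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=307, fp=9665, tn=101754, fn=282))
        assert round(m.roc_auc, 4) == 0.7172
        assert round(100 * m.specificity, 1) == 91.3
        assert round(100 * m.recall, 1) == 52.1

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert m.accuracy == m.roc_auc == m.recall == m.precision == m.f1 == 1.0

    def test_no_positive_predictions_flagged(self):
        m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=9, fn=1))
        assert m.precision == 0.0 and m.f1 == 0.0 and m.precision_undefined

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(1, 40))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_hard_auc_equals_rank_auc_on_binary_scores(self, fp, tn, fn, tp):
        if tn + fp == 0:
            tn = 1
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        m = metrics_from_confusion(cm)
        scores = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        labels = [1] * (tp + fn) + [0] * (fp + tn)
        assert m.roc_auc == pytest.approx(pairwise_auc(scores, labels))
        for value in (m.accuracy, m.roc_auc, m.recall, m.specificity,
                      m.precision, m.f1):
            assert 0.0 <= value <= 1.0


class TestRocAuc:
    def test_constant_scores_give_half(self):
        auc, _ = roc_auc_from_scores([0.3] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_perfect_separation_gives_one(self):
        auc, pts = roc_auc_from_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert {"fpr", "tpr", "threshold"} <= set(pts.columns)

    def test_tied_scores_match_pairwise_oracle(self):
        scores = [0.9, 0.5, 0.5, 0.5, 0.2, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        auc, _ = roc_auc_from_scores(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels))

    @given(st.lists(st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                              st.integers(0, 1)), min_size=4, max_size=30))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_matches_pairwise_oracle(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, _ = roc_auc_from_scores(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_from_scores([0.1, 0.2], [1, 1])


class TestFisher:
    def test_headline_comparison_tables_significant(self):
        assert fisher_compare(61024, 6003, 61535, 5492).p_value < 0.001
        assert fisher_compare(102061, 9947, 105956, 6052).p_value < 0.001

    def test_symmetric_table_p_one(self):
        assert fisher_compare(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        res = fisher_compare(0, 0, 3, 4)
        assert res.p_value == 1.0 and res.degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(-1, 2, 3, 4)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_exhaustive_enumeration(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        res = fisher_compare(a, b, c, d)
        assert res.p_value == pytest.approx(enumerate_fisher(a, b, c, d),
                                            rel=1e-8)

    def test_mcnemar_no_discordance_is_one(self):
        assert mcnemar_compare(10, 0, 0, 5) == 1.0
        assert mcnemar_compare(10, 8, 1, 5) < 0.05


@pytest.fixture(scope="module")
def report():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 300)
    scores = np.clip(y * 0.55 + rng.normal(0.25, 0.22, 300), 0, 1)
    cvl = (rng.random(300) < (0.1 + 0.5 * y)).astype(int)
    return build_report(y, scores, cvl)


class TestBuildReport:
    def test_schema(self, report):
        assert {"n_tests", "model", "cvl", "comparison", "roc_points"} <= set(report)
        for name in ("model", "cvl"):
            assert {"confusion", "metrics", "true_result", "false_result"} \
                <= set(report[name])

    def test_true_plus_false_is_total(self, report):
        for name in ("model", "cvl"):
            assert (report[name]["true_result"] + report[name]["false_result"]
                    == report["n_tests"])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_report([1, 0], [0.5], [1, 0])

    def test_write_report_emits_tables(self, report, tmp_path):
        paths = write_report(report, tmp_path)
        assert paths["report"].exists()
        conf = pd.read_csv(paths["confusion"], index_col=0)
        assert set(conf.columns) == {"tp", "fp", "tn", "fn"}
        comp = pd.read_csv(paths["comparison"], index_col=0)
        assert (comp["true_result"] + comp["false_result"]
                == report["n_tests"]).all()
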