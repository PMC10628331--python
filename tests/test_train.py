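import numpy as np
import pandas as pd
import pytest

from labmort import (SplitSpec, cross_validate, fit_gbt, random_search,
                     stratified_split, undersample_majority)
from labmort.featurize import FEATURE_COLUMNS, LABEL_COLUMN


def toy_table(n_pos, n_neg, separation=3.0, seed=0):
    """Feature table where mean_sdl separates the classes by `separation`."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    df = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_COLUMNS))
    df["age_years"] = rng.normal(60, 10, n)
    df["loc_outpatient"] = 1
    df["dept_others"] = 1
    df["count_item"] = 10
    y = np.array([1] * n_pos + [0] * n_neg)
    df["mean_sdl"] = rng.normal(1.0 + separation * y, 0.5)
    df[LABEL_COLUMN] = y
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


class TestStratifiedSplit:
    def test_exact_stratification_on_balanced_input(self):
        rows = toy_table(50, 50)
        train, test = stratified_split(rows, SplitSpec(0.7, seed=0))
        assert len(train) == 70 and len(test) == 30
        assert train[LABEL_COLUMN].sum() == 35
        assert test[LABEL_COLUMN].sum() == 15

    def test_rare_class_proportions_within_one_row(self):
        rows = toy_table(20, 2000)
        train, test = stratified_split(rows, SplitSpec(0.7, seed=1))
        assert abs(train[LABEL_COLUMN].sum() - 14) <= 1
        assert train[LABEL_COLUMN].sum() + test[LABEL_COLUMN].sum() == 20

    def test_seed_determinism(self):
        rows = toy_table(30, 300)
        a = stratified_split(rows, SplitSpec(seed=7))
        b = stratified_split(rows, SplitSpec(seed=7))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_partition_conservation(self):
        rows = toy_table(30, 300).reset_index().rename(columns={"index": "rid"})
        train, test = stratified_split(rows, SplitSpec(seed=2))
        assert sorted(train["rid"]) + sorted(test["rid"]) != []
        assert set(train["rid"]) | set(test["rid"]) == set(rows["rid"])
        assert set(train["rid"]) & set(test["rid"]) == set()

    def test_tiny_class_rejected(self):
        rows = toy_table(1, 50)
        with pytest.raises(ValueError):
            stratified_split(rows, SplitSpec())


class TestUndersample:
    def test_small_case_keeps_all_minority(self):
        rows = toy_table(3, 10)
        out = undersample_majority(rows, seed=0)
        assert len(out) == 6
        assert out[LABEL_COLUMN].sum() == 3

    def test_balanced_input_unchanged_up_to_order(self):
        rows = toy_table(5, 5)
        out = undersample_majority(rows, seed=0)
        pd.testing.assert_frame_equal(
            out.sort_values("mean_sdl", ignore_index=True),
            rows.sort_values("mean_sdl", ignore_index=True))

    def test_minority_rows_appear_exactly_once(self):
        rows = toy_table(40, 400)
        out = undersample_majority(rows, seed=3)
        pos_in = rows[rows[LABEL_COLUMN] == 1]["mean_sdl"].sort_values()
        pos_out = out[out[LABEL_COLUMN] == 1]["mean_sdl"].sort_values()
        assert np.allclose(pos_in.to_numpy(), pos_out.to_numpy())
        # majority sampled without replacement
        assert not out[out[LABEL_COLUMN] == 0]["mean_sdl"].duplicated().any()

    def test_single_class_rejected(self):
        rows = toy_table(5, 5)
        with pytest.raises(ValueError):
            undersample_majority(rows[rows[LABEL_COLUMN] == 1])


class TestFitGBT:
    def test_separable_toy_reaches_training_auc_one(self):
        from labmort.evaluate import roc_auc_from_scores
        rows = toy_table(10, 10, separation=6.0)
        model = fit_gbt(rows, seed=0)
        auc, _ = roc_auc_from_scores(model.predict_scores(rows), rows[LABEL_COLUMN])
        assert auc == 1.0

    def test_refit_reproduces_identical_scores(self):
        rows = toy_table(20, 20)
        a = fit_gbt(rows, seed=5).predict_scores(rows)
        b = fit_gbt(rows, seed=5).predict_scores(rows)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        rows = toy_table(10, 10)
        with pytest.raises(ValueError):
            fit_gbt(rows[rows[LABEL_COLUMN] == 0])

    def test_save_load_round_trip(self, tmp_path):
        rows = toy_table(15, 15)
        model = fit_gbt(rows, seed=1)
        model.save(tmp_path)
        from labmort import TrainedModel
        back = TrainedModel.load(tmp_path)
        assert np.allclose(back.predict_scores(rows), model.predict_scores(rows))
        assert back.feature_columns == model.feature_columns

    def test_deviation_features_dominate_importance(self):
        # mirrors the expectation that SDL aggregates carry the signal
        rows = toy_table(60, 600, separation=3.0)
        model = fit_gbt(rows, seed=0)
        top = set(model.feature_importances().head(3).index)
        assert top & {"mean_sdl", "rate_over2sd", "rate_over3sd", "count_over2sd"}


class TestCrossValidate:
    def test_two_fold_toy_matches_hand_computation(self):
        # recompute every fold metric by hand from refitted fold predictions
        # (min_child_weight relaxed: 3+3 logistic hessians never reach 1)
        from sklearn.model_selection import StratifiedKFold
        from test_evaluate import pairwise_auc

        params = {"min_child_weight": 0}
        rows = toy_table(6, 6, separation=8.0)
        report = cross_validate(rows, params, k=2, seed=0)
        assert len(report.folds) == 2
        assert np.allclose(report.folds["roc_auc"], 1.0)  # separable by rank

        y = rows[LABEL_COLUMN].to_numpy()
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        for row, (tr, te) in zip(report.folds.itertuples(index=False),
                                 skf.split(rows, y)):
            scores = fit_gbt(rows.iloc[tr], params, seed=0).predict_scores(rows.iloc[te])
            pred, truth = (scores >= 0.5).astype(int), y[te]
            tp = int(((pred == 1) & (truth == 1)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            assert row.accuracy == pytest.approx((pred == truth).mean())
            assert row.roc_auc == pytest.approx(pairwise_auc(scores, truth))
            assert row.recall == pytest.approx(tp / (tp + fn))
            assert row.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)

    def test_summary_recomputed_from_folds(self):
        rows = toy_table(15, 15)
        report = cross_validate(rows, k=3, seed=0)
        assert np.allclose(report.mean, report.folds.mean(), atol=1e-12)
        assert np.allclose(report.sd, report.folds.std(ddof=1), atol=1e-12)
        assert len(report.table()) == 4  # k folds + mean row

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        rows = toy_table(40, 40, separation=4.0, seed=0)
        rows[LABEL_COLUMN] = rng.permutation(rows[LABEL_COLUMN].to_numpy())
        report = cross_validate(rows, k=4, seed=0)
        assert abs(report.mean["roc_auc"] - 0.5) < 0.2

    def test_underpopulated_class_rejected(self):
        rows = toy_table(2, 30)
        with pytest.raises(ValueError):
            cross_validate(rows, k=3, seed=0)


class TestRandomSearch:
    def test_single_draw_returns_that_configuration(self):
        rows = toy_table(10, 10)
        space = {"max_depth": [3], "n_estimators": [50]}
        best, log = random_search(rows, space, n_draws=1, k=2, seed=0)
        assert best == {"max_depth": 3, "n_estimators": 50}
        assert len(log) == 1

    def test_same_seed_same_trajectory(self):
        rows = toy_table(10, 10)
        _, log_a = random_search(rows, n_draws=3, k=2, seed=9)
        _, log_b = random_search(rows, n_draws=3, k=2, seed=9)
        pd.testing.assert_frame_equal(log_a, log_b)

    def test_dominant_configuration_wins(self):
        # XOR of two features: a depth-1 single-tree model cannot rank it at
        # all, so any draw with depth >= 2 and enough trees provably wins
        rng = np.random.default_rng(0)
        rows = toy_table(20, 20)
        a = rng.integers(0, 2, len(rows))
        b = rng.integers(0, 2, len(rows))
        rows["mean_sdl"] = a * 3.0 + rng.normal(0, 0.1, len(rows))
        rows["age_years"] = 40.0 + b * 30.0
        rows[LABEL_COLUMN] = (a ^ b).astype(int)
        # boosted stumps are additive in the features and cannot rank XOR
        space = {"max_depth": [1, 4]}
        best, log = random_search(rows, space, n_draws=6, k=2, seed=1)
        assert set(log["max_depth"]) == {1, 4}
        assert best == {"max_depth": 4}

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            random_search(toy_table(5, 5), n_draws=0)
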