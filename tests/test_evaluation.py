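import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from simpep.evaluation import (
    ConfusionCounts,
    EvaluationError,
    auc_roc,
    ci_halfwidth,
    fold_summary,
    metrics,
    run_cv,
)
from simpep.model import NetConfig
from simpep.synthetic import SynthSpec, gen_embedding_clusters


def bruteforce_auc(scores, labels):
    """O(n^2) Mann-Whitney pair count; ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_formula_evaluation(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, TN=8, FP=2))
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPC"] == pytest.approx(0.80)
        assert m["ACC"] == pytest.approx(11 / 14)

    def test_all_correct(self):
        m = metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert m == {"ACC": 1.0, "SPC": 1.0, "SEN": 1.0}

    def test_undefined_sensitivity_is_nan_not_zero(self):
        m = metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        assert np.isnan(m["SEN"])
        assert m["SPC"] == pytest.approx(0.75)

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    def test_from_predictions(self):
        counts = ConfusionCounts.from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (counts.TP, counts.FN, counts.TN, counts.FP) == (1, 1, 1, 1)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_roc([0.1, 0.2], [1, 1])

    @given(seed=st.integers(0, 2_000))
    def test_matches_bruteforce_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        assert auc_roc(scores, labels) == pytest.approx(
            bruteforce_auc(scores, labels), abs=1e-12
        )


class TestFoldSummary:
    # reference fold columns; expected AVG/STD verified by hand
    # (mean and sample standard deviation at 2-decimal rounding)
    @pytest.mark.parametrize(
        "column,expected_avg,expected_std",
        [
            ([89.11, 90.76, 85.42, 83.64, 85.42], 86.87, 2.95),
            ([76.76, 85.54, 71.31, 74.09, 72.62], 76.06, 5.67),
        ],
    )
    def test_reference_columns_reproduced(self, column, expected_avg, expected_std):
        frame = pd.DataFrame({"ACC": column})
        out = fold_summary(frame)
        assert round(float(out.loc["AVG", "ACC"]), 2) == expected_avg
        assert round(float(out.loc["STD", "ACC"]), 2) == expected_std

    def test_constant_column_zero_std(self):
        out = fold_summary(pd.DataFrame({"ACC": [0.8, 0.8, 0.8]}))
        assert float(out.loc["STD", "ACC"]) == pytest.approx(0.0)

    def test_single_fold_rejected(self):
        with pytest.raises(EvaluationError):
            fold_summary(pd.DataFrame({"ACC": [0.9]}))


class TestCIHalfwidth:
    # frozen from z * STD / sqrt(k) at the 95% level over 5 folds
    @pytest.mark.parametrize(
        "std,k,expected", [(5.67, 5, 4.97), (2.94, 5, 2.58), (0.0, 5, 0.0)]
    )
    def test_reference_values(self, std, k, expected):
        assert round(ci_halfwidth(std, k, z=1.96), 2) == expected

    def test_negative_std_rejected(self):
        with pytest.raises(EvaluationError):
            ci_halfwidth(-1.0, 5)


@pytest.fixture(scope="module")
def separable_cv():
    # reference separable conditions: 40 positives, 160 negatives, 6-sigma gap
    data = gen_embedding_clusters(SynthSpec(dim=32, n_pos=40, n_neg=160, delta=6.0, seed=0))
    pos, neg = data.pools()
    config = NetConfig(input_dim=32, max_rounds=3, seed=0)
    return run_cv(pos, neg, data.backend, config, k=5, seed=0)


class TestRunCV:
    def test_separable_pools_score_high_on_every_fold(self, separable_cv):
        fold_rows = separable_cv.opd_table.iloc[:5]
        assert (fold_rows["ACC"] >= 0.9).all()

    def test_tables_have_avg_and_std_rows(self, separable_cv):
        for table in (separable_cv.ops_table, separable_cv.opd_table):
            assert list(table.index[-2:]) == ["AVG", "STD"]
            assert list(table.columns) == ["fold", "ACC", "AUC", "SPC", "SEN"]

    def test_avg_row_is_mean_of_folds(self, separable_cv):
        table = separable_cv.opd_table
        assert float(table.loc["AVG", "ACC"]) == pytest.approx(
            table.iloc[:5]["ACC"].mean()
        )

    def test_ci_row_derives_from_std(self, separable_cv):
        ci = separable_cv.ci_row("opd")
        table = separable_cv.opd_table
        assert ci["ACC"] == pytest.approx(1.96 * float(table.loc["STD", "ACC"]) / np.sqrt(5))

    def test_no_leakage_fold_pools_disjoint(self, separable_cv):
        split = separable_cv.fold_split
        for i in range(split.k):
            test_pos, test_neg = split.test_ids(i)
            train_pos, train_neg = split.train_ids(i)
            assert not (set(test_pos) & set(train_pos))
            assert not (set(test_neg) & set(train_neg))
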