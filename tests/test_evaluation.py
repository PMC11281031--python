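import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mixtox import evaluation as ev


class TestSplits:
    def test_holdout_fraction_and_determinism(self):
        tr1, te1 = ev.holdout_indices(101, seed=3, iteration=4)
        tr2, te2 = ev.holdout_indices(101, seed=3, iteration=4)
        assert np.array_equal(te1, te2) and np.array_equal(tr1, tr2)
        assert te1.size == 20  # floor(0.2 * 101)
        assert np.array_equal(np.sort(np.concatenate([tr1, te1])), np.arange(101))

    def test_holdout_iterations_differ(self):
        _, te0 = ev.holdout_indices(100, seed=3, iteration=0)
        _, te1 = ev.holdout_indices(100, seed=3, iteration=1)
        assert not np.array_equal(te0, te1)

    def test_stratified_folds_within_one_of_proportional(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = ev.stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            members = y[folds == f]
            assert members.size == 10
            assert np.sum(members == 0) == 5 and np.sum(members == 1) == 5

    def test_stratified_folds_uneven_classes(self):
        y = np.array([0] * 47 + [1] * 23)
        folds = ev.stratified_kfold(y, k=5, seed=1)
        for f in range(5):
            for cls, total in ((0, 47), (1, 23)):
                got = np.sum((folds == f) & (y == cls))
                assert abs(got - total / 5) <= 1

    def test_single_class_warns(self):
        with pytest.warns(UserWarning, match="single-class"):
            folds = ev.stratified_kfold(np.zeros(20, dtype=int), k=4, seed=0)
        assert np.bincount(folds).tolist() == [5, 5, 5, 5]

    def test_kfold_determinism(self):
        y = np.array([0, 1] * 25)
        assert np.array_equal(
            ev.stratified_kfold(y, k=5, seed=9), ev.stratified_kfold(y, k=5, seed=9)
        )


class TestCompoundOut:
    mixtures = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("c", "d")]

    def test_test_set_touches_held_out_only(self):
        train, test = ev.compound_out_split(self.mixtures, {"a"})
        assert sorted(test) == [0, 1]
        train_chems = {x for i in train for x in self.mixtures[i]}
        assert "a" not in train_chems

    def test_absent_chemical_gives_empty_test(self):
        with pytest.raises(ValueError, match="empty test"):
            ev.compound_out_split(self.mixtures, {"zz"})

    def test_holding_out_everything_gives_empty_train(self):
        with pytest.raises(ValueError, match="empty train"):
            ev.compound_out_split(self.mixtures, set("abcde"))


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        rep = ev.classification_metrics(y, y, scores=y.astype(float))
        assert (rep.accuracy, rep.sensitivity, rep.specificity,
                rep.precision, rep.auc) == (1, 1, 1, 1, 1)

    def test_hand_confusion_counts(self):
        # TP=3, FP=1, TN=4, FN=2
        y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        yhat = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        rep = ev.classification_metrics(y, yhat)
        assert rep.confusion == (3, 1, 4, 2)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.75)

    def test_constant_scores_auc_half(self):
        y = [0, 1, 0, 1]
        rep = ev.classification_metrics(y, y, scores=[0.5] * 4)
        assert rep.auc == pytest.approx(0.5)

    def test_one_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            rep = ev.classification_metrics([1, 1], [1, 1], scores=[0.2, 0.9])
        assert rep.auc is None

    def test_fuzz_against_confusion_and_mannwhitney_oracles(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = 50
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            yhat = rng.integers(0, 2, n)
            s = rng.random(n)
            rep = ev.classification_metrics(y, yhat, s)
            tp = np.sum((y == 1) & (yhat == 1)); fp = np.sum((y == 0) & (yhat == 1))
            tn = np.sum((y == 0) & (yhat == 0)); fn = np.sum((y == 1) & (yhat == 0))
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert rep.specificity == pytest.approx(tn / (tn + fp))
            u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert rep.auc == pytest.approx(u / (np.sum(y == 1) * np.sum(y == 0)))


class TestMicroAverage:
    def test_perfect_multiclass(self):
        y = [0, 1, 2, 1, 0]
        rep = ev.micro_average(y, y)
        assert rep.accuracy == 1.0 and rep.sensitivity == 1.0

    def test_micro_sensitivity_equals_overall_accuracy(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 4, 40)
        yhat = rng.integers(0, 4, 40)
        rep = ev.micro_average(y, yhat)
        assert rep.sensitivity == pytest.approx(np.mean(y == yhat))

    def test_three_class_one_error_in_five(self):
        y = [0, 1, 2, 0, 1]
        yhat = [0, 1, 2, 0, 2]
        rep = ev.micro_average(y, yhat)
        assert rep.sensitivity == pytest.approx(0.8)


class TestRegressionMetrics:
    def test_perfect_fit(self):
        rep = ev.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rep.mse, rep.mae, rep.r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = ev.regression_metrics(y, np.full(3, y.mean()))
        assert rep.r2 == pytest.approx(0.0)

    def test_hand_example(self):
        rep = ev.regression_metrics([0, 1, 2], [0, 1, 5])
        assert rep.mse == pytest.approx(3.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(-3.5)

    def test_zero_variance_target_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = ev.regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert rep.r2 is None


class TestAgreement:
    def test_identical_and_complement(self):
        assert ev.agreement_with_experiment([1, 0, 1], [1, 0, 1])["percent"] == 100.0
        assert ev.agreement_with_experiment([1, 0], [0, 1])["percent"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.agreement_with_experiment([1, 0], [1])

    def test_headline_rounding(self):
        res = ev.agreement_with_experiment([1] * 30 + [0] * 7, [1] * 37)
        assert res["percent_1dp"] == 81.1 and res["percent_int"] == 81


def test_aggregate_reports_mean_is_arithmetic():
    reps = [ev.regression_metrics([0, 1, 2.0], [0, 1, 2 + d]) for d in (0.3, 0.6)]
    summary = ev.aggregate_reports(reps)
    assert summary.mean("mse") == pytest.approx((0.03 + 0.12) / 2)
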