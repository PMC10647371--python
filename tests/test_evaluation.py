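"""Confusion metrics, zero-one loss, cross-validation, Wilcoxon comparison."""

import itertools

import numpy as np
import pytest

import pelagiscan as p
from pelagiscan.evaluation import (
    confusion_matrix,
    kfold_cv,
    learning_curve,
    metrics,
    wilcoxon_compare,
    zero_one_loss,
)

from conftest import make_toy_dataset


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["a", "b", "c"], ["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_hand_counted_example(self):
        cm = confusion_matrix([1, 1, 2, 2], [1, 2, 2, 2], [1, 2])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_matrix([], [], ["a"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside class set"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestMetrics:
    def test_diagonal_matrix_gives_100_percent(self):
        cm = p.ConfusionMatrix(np.diag([5, 3, 2]), ["a", "b", "c"])
        rep = metrics(cm)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 100.0

    def test_binary_case_matches_direct_arithmetic(self):
        # positive class: TP=50, FN=10, FP=10, TN=30
        cm = p.ConfusionMatrix(np.array([[50, 10], [10, 30]]), ["pos", "neg"])
        rep = metrics(cm)
        pos = rep.per_class["pos"]
        assert pos["ACC"] == pytest.approx(80.0)
        assert pos["PRE"] == pytest.approx(83.3333, abs=1e-3)
        assert pos["REC"] == pytest.approx(83.3333, abs=1e-3)
        assert pos["F1"] == pytest.approx(83.3333, abs=1e-3)

    def test_one_vs_rest_bookkeeping_sums_to_total(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, (4, 4))
        cm = p.ConfusionMatrix(counts, list("abcd"))
        total = counts.sum()
        for i in range(4):
            tp = counts[i, i]
            fp = counts[:, i].sum() - tp
            fn = counts[i, :].sum() - tp
            tn = total - tp - fp - fn
            assert tp + fp + fn + tn == total

    def test_global_accuracy_equals_weighted_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y_true = rng.integers(0, 4, 60)
            y_pred = rng.integers(0, 4, 60)
            rep = metrics(confusion_matrix(y_true, y_pred, [0, 1, 2, 3]))
            assert rep.accuracy == pytest.approx(rep.recall, abs=1e-12)
            _, mean_loss = zero_one_loss(y_true, y_pred)
            assert rep.accuracy == pytest.approx(100 * (1 - mean_loss), abs=1e-12)

    def test_agrees_with_sklearn_weighted_averages(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 80)
        y_pred = rng.integers(0, 3, 80)
        rep = metrics(confusion_matrix(y_true, y_pred, [0, 1, 2]))
        pre, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(100 * pre, abs=1e-9)
        assert rep.recall == pytest.approx(100 * rec, abs=1e-9)
        assert rep.f1 == pytest.approx(100 * f1, abs=1e-9)

    def test_zero_support_class_warns_and_reports_zero(self):
        cm = p.ConfusionMatrix(np.array([[4, 0], [0, 0]]), ["a", "ghost"])
        with pytest.warns(UserWarning, match="zero support"):
            rep = metrics(cm)
        assert rep.per_class["ghost"]["PRE"] == 0.0


class TestZeroOneLoss:
    def test_identical_vectors(self):
        losses, mean = zero_one_loss([1, 2, 3], [1, 2, 3])
        assert mean == 0.0 and (losses == 0).all()

    def test_fully_mismatched(self):
        _, mean = zero_one_loss([1, 1], [2, 2])
        assert mean == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            zero_one_loss([1], [1, 2])


class _MajorityModel:
    """Deterministic dummy: always predicts the first class."""

    def __init__(self, label):
        self.label = label

    def predict(self, ds):
        return np.array([self.label] * len(ds))


def majority_spec(train_ds, seed):
    return _MajorityModel(train_ds.classes[0])


class TestKFoldCV:
    def test_folds_partition_the_dataset(self):
        ds = make_toy_dataset(15, classes=("a", "b", "c"), image_size=8)
        report = kfold_cv(ds, majority_spec, k=5, seed=0)
        assert sorted(report.fold_ids.tolist()).count(-1) == 0
        assert set(report.fold_ids) == set(range(5))
        assert sum(report.fold_test_sizes) == len(ds)

    def test_stratification_within_one_sample(self):
        ds = make_toy_dataset(10, classes=("a", "b"), image_size=8)
        report = kfold_cv(ds, majority_spec, k=5, seed=1)
        labels = ds.labels()
        for fold in range(5):
            members = labels[report.fold_ids == fold]
            assert abs((members == "a").sum() - 2) <= 1

    def test_majority_model_metrics_are_analytic(self):
        ds = make_toy_dataset(10, classes=("a", "b"), image_size=8)
        report = kfold_cv(ds, majority_spec, k=5, seed=0)
        for rep in report.fold_metrics:
            assert rep.accuracy == pytest.approx(50.0)
            assert rep.recall == pytest.approx(50.0)
        assert report.losses.mean() == pytest.approx(0.5)

    def test_class_smaller_than_k_rejected(self):
        ds = make_toy_dataset(3, classes=("a", "b"), image_size=8)
        with pytest.raises(ValueError, match="at least k"):
            kfold_cv(ds, majority_spec, k=5, seed=0)

    def test_grouped_mode_keeps_sources_together(self):
        ds = make_toy_dataset(12, classes=("a", "b"), image_size=8)
        for i, s in enumerate(ds.samples):
            s.provenance["source"] = f"{s.label}-src{i % 4}"
        report = kfold_cv(ds, majority_spec, k=2, seed=0, group_by_source=True)
        sources = ds.source_ids()
        for src in np.unique(sources):
            assert len(set(report.fold_ids[sources == src])) == 1


class TestLearningCurve:
    def spec(self):
        def fit(train_ds, seed):
            return p.SVMBaseline("spectral").fit(train_ds, seed)
        return fit

    def easy_dataset(self):
        return make_toy_dataset(30, classes=("lo", "hi"), image_size=8,
                                sig_len=8, sig_offsets={"lo": 0.2, "hi": 0.8})

    def test_output_lengths_match_sizes(self):
        curves = learning_curve(self.spec(), self.easy_dataset(), [8, 16, 32],
                                seed=0)
        assert len(curves["train_error"]) == len(curves["test_error"]) == 3

    def test_full_pool_point_equals_plain_split_evaluation(self):
        ds = self.easy_dataset()
        curves = learning_curve(self.spec(), ds, [48], seed=0)
        assert curves["sizes"][-1] == 48  # = pool size at test_fraction 0.2
        assert curves["test_error"][-1] == pytest.approx(0.0)

    def test_error_shrinks_with_more_data_majority_vote(self):
        wins = 0
        for seed in (0, 1, 2):
            curves = learning_curve(self.spec(), self.easy_dataset(), [4, 40],
                                    seed=seed)
            if curves["test_error"][-1] <= curves["test_error"][0]:
                wins += 1
        assert wins >= 2

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds pool"):
            learning_curve(self.spec(), self.easy_dataset(), [1000], seed=0)


class TestWilcoxon:
    def test_identical_losses_no_effect(self):
        res = wilcoxon_compare([0, 1, 0, 1], [0, 1, 0, 1])
        assert res.pvalue == 1.0 and res.no_effect

    def test_six_one_sided_differences_exact_p(self):
        res = wilcoxon_compare([1] * 6, [0] * 6)
        assert res.pvalue == pytest.approx(0.03125)
        assert not res.no_effect

    def test_exact_p_matches_sign_enumeration(self):
        """DP tail equals explicit enumeration of all 2^n sign assignments."""
        rng = np.random.default_rng(0)
        a = rng.random(10)
        b = rng.random(10)
        res = wilcoxon_compare(a, b)
        diffs = (a - b)[(a - b) != 0]
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        sums = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=len(diffs))
        ]
        sums = np.array(sums)
        p_le = (sums <= w_obs + 1e-9).mean()
        p_ge = (sums >= w_obs - 1e-9).mean()
        expected = min(1.0, 2 * min(p_le, p_ge))
        assert res.pvalue == pytest.approx(expected, abs=1e-12)

    def test_statistic_matches_explicit_ranking(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(10), rng.random(10)
        res = wilcoxon_compare(a, b)
        from scipy.stats import rankdata

        d = a - b
        ranks = rankdata(np.abs(d))
        assert res.statistic == pytest.approx(
            min(ranks[d > 0].sum(), ranks[d < 0].sum())
        )

    def test_exact_agrees_with_scipy_small_n(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(7)
        a, b = rng.random(15), rng.random(15)
        res = wilcoxon_compare(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_agrees_with_scipy_large_n(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(9)
        # discrete paired losses: plenty of ties among nonzero differences
        a = rng.integers(0, 2, 200).astype(float)
        b = rng.integers(0, 2, 200).astype(float)
        res = wilcoxon_compare(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="approx",
                             correction=False, zero_method="wilcox")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)
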