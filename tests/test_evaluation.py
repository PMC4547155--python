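"""Confusion algebra, per-class metrics, repeated CV, online protocol."""

import itertools
import math

import numpy as np
import pytest

import harkit as hk
from harkit.evaluation import cv_fold_indices, online_evaluate
from helpers import make_matrix


class TestConfusionMatrix:
    def test_small_example(self):
        cm = hk.confusion_matrix([1, 1, 2], [1, 2, 2], (1, 2))
        assert cm.counts.tolist() == [[1, 1], [0, 1]]
        assert cm.total == 3

    def test_perfect_predictions_are_diagonal(self):
        y = [3, 1, 2, 1, 3]
        cm = hk.confusion_matrix(y, y, (1, 2, 3))
        assert cm.diagonal_sum == cm.total == 5
        assert np.count_nonzero(cm.counts - np.diag(np.diag(cm.counts))) == 0

    def test_counts_match_brute_force_and_sklearn(self):
        rng = np.random.default_rng(8)
        actual = rng.integers(1, 6, 500)
        predicted = rng.integers(1, 6, 500)
        classes = (1, 2, 3, 4, 5)
        cm = hk.confusion_matrix(actual, predicted, classes)
        # brute-force tally, independent of the implementation
        for i, a in enumerate(classes):
            for j, p in enumerate(classes):
                expected = sum(
                    1 for x, y in zip(actual, predicted) if x == a and y == p
                )
                assert cm.counts[i, j] == expected
        # cross-check against sklearn's tally
        from sklearn.metrics import confusion_matrix as sk_cm

        assert np.array_equal(cm.counts, sk_cm(actual, predicted, labels=classes))

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            hk.confusion_matrix([1, 2], [1], (1, 2))
        with pytest.raises(ValueError):
            hk.confusion_matrix([1, 3], [1, 1], (1, 2))

    def test_tsv_roundtrip(self, tmp_path):
        cm = hk.confusion_matrix([1, 1, 2, 3], [1, 2, 2, 3], (1, 2, 3))
        path = tmp_path / "cm.tsv"
        cm.to_tsv(path)
        back = hk.ConfusionMatrix.from_tsv(path)
        assert back.classes == cm.classes
        assert np.array_equal(back.counts, cm.counts)


class TestClassMetrics:
    def test_hand_one_vs_rest_arithmetic(self):
        cm = hk.ConfusionMatrix((1, 2), np.array([[1, 1], [0, 1]]))
        m = hk.class_metrics(cm, 1)
        assert (m.se, m.sp, m.ppv, m.npv) == (0.5, 1.0, 1.0, 0.5)
        assert m.f == pytest.approx(2 / 3)

    def test_identity_matrix_gives_perfect_scores(self):
        cm = hk.ConfusionMatrix(tuple(range(1, 13)), np.eye(12, dtype=int) * 30)
        report = hk.compute_report(cm)
        for m in report.per_class.values():
            assert (m.se, m.sp, m.ppv, m.npv, m.f) == (1.0, 1.0, 1.0, 1.0, 1.0)
        assert report.macro_f == 1.0

    def test_total_failure_two_class(self):
        cm = hk.ConfusionMatrix((1, 2), np.array([[0, 5], [5, 0]]))
        for c in (1, 2):
            m = hk.class_metrics(cm, c)
            assert m.se == 0.0 and m.sp == 0.0

    def test_degenerate_ratios_are_flagged_not_nan(self):
        # class 3 never predicted and never present -> SE and PPV are 0/0
        cm = hk.ConfusionMatrix(
            (1, 2, 3), np.array([[4, 0, 0], [0, 3, 0], [0, 0, 0]])
        )
        m = hk.class_metrics(cm, 3)
        assert m.se == 0.0 and m.ppv == 0.0 and m.f == 0.0
        assert {"se", "ppv", "f"} <= set(m.degenerate)
        assert not hk.class_metrics(cm, 1).degenerate

    def test_se_support_identity(self):
        rng = np.random.default_rng(2)
        cm = hk.confusion_matrix(
            rng.integers(1, 4, 200), rng.integers(1, 4, 200), (1, 2, 3)
        )
        for c in cm.classes:
            i = cm.classes.index(c)
            tp = cm.counts[i, i]
            assert hk.class_metrics(cm, c).se * cm.support(c) == pytest.approx(tp)

    def test_metrics_invariant_under_class_permutation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, (4, 4))
        cm = hk.ConfusionMatrix((1, 2, 3, 4), counts)
        perm = [2, 0, 3, 1]
        cm_p = hk.ConfusionMatrix(
            tuple(cm.classes[i] for i in perm), counts[np.ix_(perm, perm)]
        )
        for c in cm.classes:
            assert hk.class_metrics(cm, c) == hk.class_metrics(cm_p, c)

    def test_unknown_class_rejected(self):
        cm = hk.ConfusionMatrix((1,), np.array([[3]]))
        with pytest.raises(ValueError):
            hk.class_metrics(cm, 9)


class TestFscore:
    @pytest.mark.parametrize(
        "se, ppv, expected",
        [(0.95, 0.97, 0.96), (1.00, 0.88, 0.94), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)],
    )
    def test_two_decimal_values(self, se, ppv, expected):
        assert round(hk.fscore(se, ppv), 2) == expected

    def test_symmetric_and_bounded_by_means(self):
        rng = np.random.default_rng(4)
        for se, ppv in rng.uniform(0, 1, (100, 2)):
            f = hk.fscore(se, ppv)
            assert f == hk.fscore(ppv, se)
            assert f <= math.sqrt(se * ppv) + 1e-12  # harmonic <= geometric
            assert f <= (se + ppv) / 2 + 1e-12  # harmonic <= arithmetic

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hk.fscore(1.2, 0.5)
        with pytest.raises(ValueError):
            hk.fscore(0.5, -0.1)


class TestRepeatedKFold:
    def small_fm(self, n=40, classes=2, seed=0):
        rng = np.random.default_rng(seed)
        y = np.tile(np.arange(1, classes + 1), n // classes)
        x = y[:, None] + rng.normal(0, 0.3, (n, 1))
        return hk.FeatureMatrix(("f",), x, y)

    def test_aggregate_total_is_reps_times_windows(self):
        fm = self.small_fm()
        cm, _ = hk.repeated_kfold_cv(
            fm, hk.ModelSpec("zeror"), hk.CVSpec(k=10, repetitions=2, seed=0)
        )
        assert cm.total == 80

    def test_every_row_tested_once_per_repetition(self):
        y = np.tile(np.arange(1, 5), 25)  # 100 rows, 4 classes
        seen = {}
        for rep, fold, train_idx, test_idx in cv_fold_indices(
            y, hk.CVSpec(k=10, repetitions=3, seed=1)
        ):
            assert set(train_idx) & set(test_idx) == set()
            assert len(train_idx) + len(test_idx) == len(y)
            for i in test_idx:
                key = (rep, int(i))
                assert key not in seen, "row tested twice in one repetition"
                seen[key] = fold
        assert len(seen) == 3 * len(y)

    def test_stratified_folds_balance_classes(self):
        y = np.tile(np.arange(1, 3), 50)
        for _, _, _, test_idx in cv_fold_indices(y, hk.CVSpec(k=10, repetitions=1, seed=0)):
            _, counts = np.unique(y[test_idx], return_counts=True)
            assert counts.tolist() == [5, 5]

    def test_small_class_error_advises_unstratified(self):
        y = np.r_[np.ones(30, dtype=int), np.full(3, 2)]
        with pytest.raises(ValueError, match="stratified=False"):
            list(cv_fold_indices(y, hk.CVSpec(k=10, repetitions=1)))
        # and the unstratified route works
        folds = list(cv_fold_indices(y, hk.CVSpec(k=10, repetitions=1, stratified=False)))
        assert len(folds) == 10

    def test_zeror_cv_sensitivity_pattern(self):
        """A constant predictor hits SE=1 on the majority class, 0 elsewhere."""
        rng = np.random.default_rng(5)
        y = np.r_[np.full(60, 3), np.full(20, 1), np.full(20, 2)]
        fm = hk.FeatureMatrix(("f",), rng.normal(size=(100, 1)), y)
        cm, report = hk.repeated_kfold_cv(
            fm, hk.ModelSpec("zeror"), hk.CVSpec(k=10, repetitions=2, seed=0)
        )
        assert report.per_class[3].se == 1.0
        assert report.per_class[1].se == 0.0
        assert report.per_class[2].se == 0.0

    def test_reproducible_given_seed(self):
        fm = self.small_fm(seed=6)
        spec, cv = hk.ModelSpec("decision_tree", seed=1), hk.CVSpec(k=5, repetitions=2, seed=7)
        cm1, _ = hk.repeated_kfold_cv(fm, spec, cv)
        cm2, _ = hk.repeated_kfold_cv(fm, spec, cv)
        assert np.array_equal(cm1.counts, cm2.counts)


class TestOnlineEvaluate:
    def test_perfect_recognizer_is_diagonal(self):
        truth = np.repeat(np.arange(1, 13), 150)  # 12 activities x 3 s at 50 Hz
        preds = []
        for end in range(100, len(truth) + 1, 100):
            seg = truth[end - 100 : end]
            if (seg == seg[0]).all():
                preds.append((end / 50.0, int(seg[0])))
        cm = online_evaluate(preds, truth, 50.0, 2.0, classes=range(1, 13))
        assert cm.diagonal_sum == cm.total > 0

    def test_window_straddling_a_change_is_excluded(self):
        truth = np.r_[np.full(500, 4), np.full(500, 5)]  # change at t = 10 s
        preds = [(10.0, 4), (12.0, 5)]  # [8,10) pure, [10,12) pure
        cm = online_evaluate(preds, truth, 50.0, 2.0, classes=(4, 5))
        assert cm.total == 2
        straddle = [(11.0, 4)]  # [9,11) spans the change -> excluded
        cm2 = online_evaluate(straddle, truth, 50.0, 2.0, classes=(4, 5))
        assert cm2.total == 0

    def test_null_class_windows_are_excluded(self):
        truth = np.r_[np.full(200, 7), np.zeros(100, dtype=int), np.full(200, 8)]
        preds = [(4.0, 7), (5.0, 7), (6.0, 7), (10.0, 8)]
        cm = online_evaluate(preds, truth, 50.0, 2.0, classes=(7, 8))
        # [2,4) scored; [3,5) and [4,6) touch the null gap; [8,10) scored
        assert cm.total == 2 and cm.diagonal_sum == 2

    def test_misalignment_strictly_hurts(self):
        rng = np.random.default_rng(9)
        truth = np.concatenate([np.full(300, c) for c in rng.permutation(range(1, 7))])
        aligned = []
        for end in range(100, len(truth) + 1, 100):
            seg = truth[end - 100 : end]
            if (seg == seg[0]).all():
                aligned.append((end / 50.0, int(seg[0])))
        cm_ok = online_evaluate(aligned, truth, 50.0, 2.0, classes=range(1, 7))
        shifted = [(t + 1.0, l) for t, l in aligned if (t + 1.0) * 50 <= len(truth)]
        cm_bad = online_evaluate(shifted, truth, 50.0, 2.0, classes=range(1, 7))
        assert cm_bad.diagonal_sum < cm_ok.diagonal_sum

    def test_prediction_outside_timeline_rejected(self):
        truth = np.full(100, 1)
        with pytest.raises(ValueError):
            online_evaluate([(1.0, 1)], truth, 50.0, 2.0)  # needs samples < 0
        with pytest.raises(ValueError):
            online_evaluate([(3.0, 1)], truth, 50.0, 2.0)  # beyond the end


def test_report_tsv_shape(tmp_path):
    cm = hk.ConfusionMatrix(tuple(range(1, 13)), np.eye(12, dtype=int) * 10)
    path = tmp_path / "report.tsv"
    hk.compute_report(cm).to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["Activity", "SE", "SP", "PPV", "NPV", "F-score"]
    assert len(lines) == 1 + 12 + 1  # header + one row per class + macro row
    assert lines[1].split("\t") == ["L1", "1.00", "1.00", "1.00", "1.00", "1.00"]
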