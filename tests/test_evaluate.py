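import numpy as np
import pytest

from spectrotex.classify import ClassifierSpec
from spectrotex.errors import ValidationError
from spectrotex.evaluate import (ConfusionMatrix, accuracy,
                                 binomial_chance_sd, class_counts,
                                 class_metrics, confusion_from_predictions,
                                 macro_roc, make_folds, roc_points, run_cv,
                                 run_cv_multi)

CM = ConfusionMatrix(np.array([[5, 1, 0], [2, 6, 1], [0, 0, 5]]),
                     ["a", "b", "c"])


class TestFolds:
    def test_equal_split(self):
        labels = ["x"] * 10
        f = make_folds(labels, n_folds=5, seed=0)
        assert sorted(np.bincount(f.fold_of, minlength=5)) == [2] * 5

    def test_near_equal_split_11(self):
        f = make_folds(["x"] * 11, n_folds=5, seed=0)
        assert sorted(np.bincount(f.fold_of, minlength=5)) == [2, 2, 2, 2, 3]

    def test_multiclass_sizes_differ_by_at_most_one(self, rng):
        # per-class remainders must spread across folds, not stack up
        labels = np.repeat(["a", "b", "c", "d"], 11)
        f = make_folds(labels, n_folds=5, seed=1)
        sizes = np.bincount(f.fold_of, minlength=5)
        assert sizes.max() - sizes.min() <= 1
        for cls in "abcd":
            per = np.bincount(f.fold_of[labels == cls], minlength=5)
            assert per.max() - per.min() <= 1

    def test_every_item_exactly_one_fold(self, rng):
        labels = rng.choice(["a", "b"], 37)
        f = make_folds(labels, n_folds=5, seed=2)
        assert f.fold_of.size == 37
        assert np.all((f.fold_of >= 0) & (f.fold_of < 5))
        covered = np.concatenate([f.test_indices(k) for k in range(5)])
        assert sorted(covered) == list(range(37))

    def test_deterministic_given_seed(self):
        labels = ["a", "b"] * 20
        a = make_folds(labels, n_folds=5, seed=9).fold_of
        b = make_folds(labels, n_folds=5, seed=9).fold_of
        np.testing.assert_array_equal(a, b)

    def test_subject_mode_keeps_subjects_intact(self):
        subjects = np.repeat([f"S{i}" for i in range(5)], 4)
        labels = ["x"] * 20
        f = make_folds(labels, subjects, n_folds=5, mode="subject", seed=0)
        for s in np.unique(subjects):
            assert np.unique(f.fold_of[subjects == s]).size == 1
        assert sorted(np.bincount(f.fold_of, minlength=5)) == [4] * 5

    def test_subject_mode_too_few_subjects(self):
        with pytest.raises(ValidationError):
            make_folds(["x"] * 8, ["A", "B"] * 4, n_folds=5, mode="subject")

    def test_too_few_items(self):
        with pytest.raises(ValidationError):
            make_folds(["x"] * 3, n_folds=5)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_from_predictions(["a", "b", "c"], ["a", "b", "c"],
                                        ["a", "b", "c"])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_hand_counted_entries(self):
        cm = confusion_from_predictions([0, 0, 1, 2], [0, 1, 1, 2], [0, 1, 2])
        np.testing.assert_array_equal(cm.counts,
                                      [[1, 1, 0], [0, 1, 0], [0, 0, 1]])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            confusion_from_predictions([], [], ["a"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_from_predictions(["a"], ["z"], ["a", "b"])


class TestMetrics:
    def test_hand_counted_class0(self):
        # one-vs-rest accounting on the 3x3 example
        k = class_counts(CM, "a")
        assert k == {"TP": 5, "FN": 1, "FP": 2, "TN": 12}
        m = class_metrics(CM, "a")
        assert m["Sen"] == pytest.approx(83.33, abs=0.01)
        assert m["Spec"] == pytest.approx(85.71, abs=0.01)
        assert m["Prec"] == pytest.approx(71.43, abs=0.01)
        assert m["F1"] == pytest.approx(0.769, abs=0.001)

    def test_accuracy_trace_over_total(self):
        assert accuracy(CM) == pytest.approx(80.0)

    def test_diagonal_matrix_perfect_metrics(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]), ["a", "b", "c"])
        assert accuracy(cm) == 100.0
        for c in "abc":
            m = class_metrics(cm, c)
            assert (m["Sen"], m["Spec"], m["Prec"], m["F1"]) == \
                (100.0, 100.0, 100.0, 1.0)

    def test_zero_diagonal_zero_accuracy(self):
        cm = ConfusionMatrix(np.array([[0, 2], [2, 0]]), ["a", "b"])
        assert accuracy(cm) == 0.0

    def test_component_sum_recovers_total_randomized(self, rng):
        for _ in range(25):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 20, (k, k))
            counts[0, 0] += 1  # ensure nonempty
            cm = ConfusionMatrix(counts, [str(i) for i in range(k)])
            for c in range(k):
                parts = class_counts(cm, c)
                assert sum(parts.values()) == cm.total

    def test_micro_average_sensitivity_equals_accuracy(self, rng):
        counts = rng.integers(0, 30, (4, 4)) + 1
        cm = ConfusionMatrix(counts, list("abcd"))
        prevalence = counts.sum(axis=1) / counts.sum()
        micro = sum(prevalence[i] * class_metrics(cm, i)["Sen"]
                    for i in range(4))
        assert micro == pytest.approx(accuracy(cm))

    def test_absent_class_zero_with_warning(self):
        cm = ConfusionMatrix(np.array([[0, 0], [1, 3]]), ["a", "b"])
        with pytest.warns(UserWarning):
            assert class_metrics(cm, "a")["Sen"] == 0.0


class TestRoc:
    def test_perfect_ranking_hits_corner(self):
        actual = ["a"] * 5 + ["b"] * 5
        scores = np.column_stack([np.r_[np.ones(5), np.zeros(5)],
                                  np.r_[np.zeros(5), np.ones(5)]])
        pts = roc_points(actual, scores, "a", ["a", "b"])
        assert pts[0].tolist() == [0.0, 0.0] or (pts[:, 0] == 0).any()
        assert any((f == 0.0 and t == 1.0) for f, t in pts)
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(1.0)

    def test_uninformative_scores_diagonal(self):
        actual = ["a", "b"] * 10
        scores = np.ones((20, 2))
        pts = roc_points(actual, scores, "a", ["a", "b"])
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(0.5)

    def test_area_equals_pair_counting_oracle(self, rng):
        actual = rng.choice(["a", "b"], 50)
        if (actual == "a").sum() in (0, 50):
            actual[0] = "a"
            actual[1] = "b"
        s = rng.normal(size=50)
        scores = np.column_stack([s, -s])
        pts = roc_points(actual, scores, "a", ["a", "b"])
        auc = np.trapezoid(pts[:, 1], pts[:, 0])
        pos = s[actual == "a"]
        neg = s[actual == "b"]
        pairs = (pos[:, None] > neg).sum() + 0.5 * (pos[:, None] == neg).sum()
        np.testing.assert_allclose(auc, pairs / (pos.size * neg.size),
                                   atol=1e-10)

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_points(["b", "b"], np.ones((2, 2)), "a", ["a", "b"])

    def test_macro_curve_monotone_between_corners(self, rng):
        actual = rng.choice(["a", "b", "c"], 60)
        scores = rng.normal(size=(60, 3))
        curve = macro_roc(actual, scores, ["a", "b", "c"])
        assert curve[0, 1] >= 0 and curve[-1, 1] == pytest.approx(1.0)
        assert np.all(np.diff(curve[:, 1]) >= -1e-12)


class TestRunCv:
    def _toy(self, rng, n_per=20):
        # three linearly separated clusters
        X = np.vstack([rng.normal(c, 0.3, (n_per, 3))
                       for c in ([0, 0, 0], [4, 0, 0], [0, 4, 0])])
        y = np.repeat(["a", "b", "c"], n_per)
        subj = np.array([f"{lab}{i % 4}" for i, lab in enumerate(y)])
        return X, y, subj

    def test_each_item_tested_exactly_once(self, rng):
        X, y, subj = self._toy(rng)
        report = run_cv(X, y, subj, ClassifierSpec(kind="lda"), pca_m=2)
        assert report.pooled_confusion().total == len(y)

    def test_perfect_separation_ceiling(self, rng):
        X, y, subj = self._toy(rng)
        report = run_cv(X, y, subj, ClassifierSpec(kind="svm_linear"), pca_m=2)
        assert report.mean_accuracy == 100.0 and report.sd_accuracy == 0.0

    def test_label_permutation_drops_to_chance(self, rng):
        X, y, subj = self._toy(rng, n_per=40)
        yp = y.copy()
        rng.shuffle(yp)
        report = run_cv(X, yp, subj, ClassifierSpec(kind="lda"), pca_m=2,
                        seed=0)
        chance = 100.0 / 3
        assert abs(report.mean_accuracy - chance) <= \
            4 * binomial_chance_sd(len(y), 3)

    def test_report_serialization_reproducible(self, rng):
        X, y, subj = self._toy(rng)
        a = run_cv(X, y, subj, ClassifierSpec(kind="rf", seed=5), pca_m=2,
                   seed=3).to_json()
        b = run_cv(X, y, subj, ClassifierSpec(kind="rf", seed=5), pca_m=2,
                   seed=3).to_json()
        assert a == b

    def test_multi_shares_folds_across_classifiers(self, rng):
        X, y, subj = self._toy(rng)
        reports = run_cv_multi(X, y, subj,
                               {"lda": ClassifierSpec(kind="lda"),
                                "knn": ClassifierSpec(kind="knn", k=3)},
                               pca_m=2, seed=1)
        np.testing.assert_array_equal(reports["lda"].pooled_actual,
                                      reports["knn"].pooled_actual)

    def test_subject_mode_reported(self, rng):
        X, y, subj = self._toy(rng)
        report = run_cv(X, y, subj, ClassifierSpec(kind="lda"), pca_m=2,
                        mode="subject", n_folds=4)
        assert report.mode == "subject"
        assert report.to_dict()["cv_mode"] == "subject"
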