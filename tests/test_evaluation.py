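import math

import numpy as np
import pytest

import accmode as am
from accmode.evaluation import BehaviorMetrics, precision_recall_points
from accmode.exceptions import EvaluationError


def _check_partition(folds, n):
    seen = []
    for train_idx, val_idx in folds:
        assert set(train_idx) | set(val_idx) == set(range(n))
        assert set(train_idx).isdisjoint(val_idx)
        seen.extend(val_idx.tolist())
    assert sorted(seen) == list(range(n))


class TestMakeFolds:
    def test_kfold_partitions_evenly(self):
        scheme = am.CVScheme(kind="kfold", k=3, stratified=False, seed=0)
        folds = am.make_folds(6, scheme)
        assert len(folds) == 3
        assert all(len(v) == 2 for _, v in folds)
        _check_partition(folds, 6)

    def test_leave_one_out_gives_singletons(self):
        scheme = am.CVScheme(kind="leave_one_out", stratified=False, seed=0)
        folds = am.make_folds(6, scheme)
        assert len(folds) == 6
        assert all(len(v) == 1 for _, v in folds)
        _check_partition(folds, 6)

    def test_train_split_is_two_fold(self):
        scheme = am.CVScheme(kind="train_split", stratified=False, seed=0)
        folds = am.make_folds(4, scheme)
        assert len(folds) == 2
        assert all(len(v) == 2 for _, v in folds)

    def test_leave_one_out_equals_kfold_k_n(self):
        loo = am.make_folds(10, am.CVScheme(kind="leave_one_out",
                                            stratified=False, seed=4))
        kf = am.make_folds(10, am.CVScheme(kind="kfold", k=10,
                                           stratified=False, seed=4))
        for (t1, v1), (t2, v2) in zip(loo, kf):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(v1, v2)

    def test_k_greater_than_n_errors(self):
        with pytest.raises(EvaluationError, match="exceeds"):
            am.make_folds(3, am.CVScheme(kind="kfold", k=5, seed=0))

    def test_stratified_preserves_class_counts_within_one(self):
        labels = ["A"] * 30 + ["B"] * 12 + ["C"] * 6
        scheme = am.CVScheme(kind="kfold", k=3, stratified=True, seed=2)
        folds = am.make_folds(len(labels), scheme, labels)
        arr = np.asarray(labels)
        for cls, total in (("A", 30), ("B", 12), ("C", 6)):
            per_fold = [int(np.sum(arr[v] == cls)) for _, v in folds]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == total

    def test_small_class_degrades_stratification_with_warning(self):
        labels = ["A"] * 10 + ["B"] * 2
        scheme = am.CVScheme(kind="kfold", k=4, stratified=True, seed=0)
        with pytest.warns(UserWarning, match="unstratified"):
            folds = am.make_folds(len(labels), scheme, labels)
        _check_partition(folds, 12)

    def test_unstratified_folds_ignore_label_values(self):
        scheme = am.CVScheme(kind="kfold", k=4, stratified=False, seed=9)
        f1 = am.make_folds(20, scheme, ["A"] * 20)
        f2 = am.make_folds(20, scheme, ["A", "B"] * 10)
        for (_, v1), (_, v2) in zip(f1, f2):
            np.testing.assert_array_equal(v1, v2)

    def test_reproducible_under_seed(self):
        scheme = am.CVScheme(kind="kfold", k=5, stratified=False, seed=13)
        f1 = am.make_folds(23, scheme)
        f2 = am.make_folds(23, scheme)
        for (t1, v1), (t2, v2) in zip(f1, f2):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(v1, v2)


class TestMetricsFromConfusion:
    def test_two_class_hand_counts(self):
        # rows true A,B: [[3,1],[2,4]] over 10 outcomes
        cm = am.ConfusionMatrix(["A", "B"], np.array([[3, 1], [2, 4]]))
        per, overall = am.metrics_from_confusion(cm)
        assert per["A"].precision == pytest.approx(3 / 5)
        assert per["A"].recall == pytest.approx(3 / 4)
        assert per["A"].accuracy == pytest.approx(7 / 10)
        assert per["B"].precision == pytest.approx(4 / 5)
        assert per["B"].recall == pytest.approx(4 / 6)
        assert overall == pytest.approx(7 / 10)

    def test_diagonal_matrix_is_perfect(self):
        cm = am.ConfusionMatrix(["A", "B", "C"], np.diag([5, 3, 2]))
        per, overall = am.metrics_from_confusion(cm)
        assert overall == 1.0
        for m in per.values():
            assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_vacuous_behavior_undefined_not_zero(self):
        # C never true and never predicted
        counts = np.array([[3, 0, 0], [1, 2, 0], [0, 0, 0]])
        cm = am.ConfusionMatrix(["A", "B", "C"], counts)
        per, _ = am.metrics_from_confusion(cm)
        assert math.isnan(per["C"].precision)
        assert math.isnan(per["C"].recall)
        assert per["C"].accuracy == 1.0

    def test_empty_matrix_errors(self):
        cm = am.ConfusionMatrix(["A", "B"], np.zeros((2, 2), dtype=int))
        with pytest.raises(EvaluationError, match="empty"):
            am.metrics_from_confusion(cm)

    def test_overall_is_recall_weighted_by_class_frequency(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            size = rng.integers(2, 7)
            counts = rng.integers(0, 9, size=(size, size))
            if counts.sum() == 0:
                counts[0, 0] = 1
            labels = [f"b{i}" for i in range(size)]
            per, overall = am.metrics_from_confusion(
                am.ConfusionMatrix(labels, counts))
            total = counts.sum()
            weighted = sum(
                (counts[i].sum() / total) * per[lbl].recall
                for i, lbl in enumerate(labels) if counts[i].sum() > 0)
            assert overall == pytest.approx(weighted, abs=1e-12)


class TestCrossValidate:
    def test_separable_scenario_is_learned(self, small_separable_table):
        scheme = am.CVScheme(kind="kfold", k=5, stratified=True, seed=1)
        rep = am.cross_validate(am.ModelSpec("knn", random_seed=1),
                                small_separable_table, scheme)
        # far above the 1/6 chance level even at this small n
        assert rep.overall_accuracy >= 0.85
        assert len(rep.fold_accuracies) == 5
        assert rep.confusion.total == small_separable_table.n_rows

    def test_confusion_row_sums_match_class_counts(self, small_separable_table):
        scheme = am.CVScheme(kind="kfold", k=5, stratified=True, seed=1)
        rep = am.cross_validate(am.ModelSpec("tree", random_seed=1),
                                small_separable_table, scheme)
        counts = {lbl: small_separable_table.labels.count(lbl)
                  for lbl in rep.confusion.labels}
        for i, lbl in enumerate(rep.confusion.labels):
            assert rep.confusion.counts[i].sum() == counts[lbl]

    def test_fold_std_uses_sample_divisor(self, small_separable_table):
        scheme = am.CVScheme(kind="kfold", k=3, stratified=True, seed=1)
        rep = am.cross_validate(am.ModelSpec("lda"), small_separable_table,
                                scheme)
        assert rep.std_accuracy == pytest.approx(
            np.std(rep.fold_accuracies, ddof=1))
        assert rep.mean_accuracy == pytest.approx(
            np.mean(rep.fold_accuracies))

    def test_single_class_training_fold_errors(self):
        table = am.FeatureTable(
            ["a"], np.arange(4.0).reshape(-1, 1), ["A", "A", "B", "B"])
        # force folds that isolate one class: unstratified k=2 with a seed
        # that happens to split classes apart is not guaranteed, so build
        # the degenerate case directly via labels sorted and seed scan
        for seed in range(30):
            scheme = am.CVScheme(kind="kfold", k=2, stratified=False,
                                 seed=seed)
            folds = am.make_folds(4, scheme, table.labels)
            if any(len({table.labels[i] for i in tr}) < 2 for tr, _ in folds):
                with pytest.raises(EvaluationError, match="single class"):
                    am.cross_validate(am.ModelSpec("knn", {"n_neighbors": 1}),
                                      table, scheme)
                return
        pytest.skip("no seed produced a single-class training fold")


class TestCompareModels:
    def test_mean_row_of_published_accuracies(self):
        accuracies = {
            "ANN": (84.84, 2.76),
            "Decision tree": (77.68, 5.76),
            "LDA": (80.75, 4.89),
            "Linear SVM": (80.13, 4.18),
            "Nearest neighbors": (80.54, 3.18),
            "Random forest": (84.02, 2.98),
            "RBF SVM": (82.58, 3.91),
        }
        table = am.compare_models(accuracies)
        mean_row = table[table["model"] == "Mean"].iloc[0]
        assert mean_row["accuracy_pct"] == pytest.approx(81.51, abs=0.005)
        assert mean_row["std_pct"] == pytest.approx(3.95, abs=0.005)

    def test_single_report_mean_equals_report(self, small_separable_table):
        scheme = am.CVScheme(kind="kfold", k=3, stratified=True, seed=1)
        rep = am.cross_validate(am.ModelSpec("knn"), small_separable_table,
                                scheme)
        table = am.compare_models({"knn": rep})
        knn_row = table[table["model"] == "knn"].iloc[0]
        mean_row = table[table["model"] == "Mean"].iloc[0]
        assert mean_row["accuracy_pct"] == pytest.approx(knn_row["accuracy_pct"])
        assert mean_row["std_pct"] == pytest.approx(knn_row["std_pct"])

    def test_empty_reports_error(self):
        with pytest.raises(EvaluationError, match="no reports"):
            am.compare_models({})

    def test_precision_recall_points_shape(self, small_separable_table):
        scheme = am.CVScheme(kind="kfold", k=3, stratified=True, seed=1)
        reps = {f: am.cross_validate(am.ModelSpec(f), small_separable_table,
                                     scheme)
                for f in ("knn", "lda")}
        points = precision_recall_points(reps)
        assert set(points["model"]) == {"knn", "lda"}
        assert ((0 <= points["precision_pct"]) & (points["precision_pct"] <= 100)).all()


class TestReportRendering:
    def test_undefined_metrics_render_as_dash(self):
        cm = am.ConfusionMatrix(["A", "B", "C"],
                                np.array([[3, 0, 0], [1, 2, 0], [0, 0, 0]]))
        per, overall = am.metrics_from_confusion(cm)
        rep = am.EvaluationReport(cm, overall, per, [overall], overall, 0.0)
        rendered = rep.rendered_metrics()
        assert rendered.loc["C", "precision"] == "—"
        assert rendered.loc["A", "recall"] == "1.0000"

    def test_macro_averages_exclude_undefined(self):
        per = {"A": BehaviorMetrics(1.0, 1.0, 0.5),
               "B": BehaviorMetrics(1.0, float("nan"), float("nan"))}
        cm = am.ConfusionMatrix(["A", "B"], np.array([[2, 0], [0, 0]]))
        rep = am.EvaluationReport(cm, 1.0, per, [1.0], 1.0, 0.0)
        assert rep.macro_precision() == pytest.approx(1.0)
        assert rep.macro_recall() == pytest.approx(0.5)
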