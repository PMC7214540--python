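import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from thermoraac import (
    ConfusionCounts,
    crossval,
    make_classifier,
    metrics,
    plot_roc,
    roc_points,
)


class TestMetrics:
    def test_worked_confusion_example(self):
        m = metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert (m.sn, m.sp, m.acc) == (90.0, 80.0, 85.0)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc) == (100.0, 100.0, 100.0)

    def test_all_positive_predictor_has_zero_specificity(self):
        m = metrics(ConfusionCounts(tp=6, fp=4, tn=0, fn=0))
        assert m.sp == 0.0 and m.sn == 100.0

    def test_no_positive_class_reports_not_applicable(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert m.sn is None
        assert m.sp == 75.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)

    def test_accuracy_identity_on_random_tables(self, rng):
        """ACC equals the class-size-weighted mean of Sn and Sp."""
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            p, n = tp + fn, tn + fp
            assert m.acc == pytest.approx((m.sn * p + m.sp * n) / (p + n))
            assert min(m.sn, m.sp) <= m.acc <= max(m.sn, m.sp)


class TestROC:
    def test_perfect_separation_area_one(self):
        r = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.area == 1.0
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_reversed_scores_complement_area(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[0], labels[1] = 0, 1
        a = roc_points(scores, labels).area
        b = roc_points(-scores, labels).area
        assert a + b == pytest.approx(1.0)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(42)
        n = 4000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        assert roc_points(scores, labels).area == pytest.approx(0.5, abs=0.05)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.uniform(size=60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = roc_points(scores, labels).area
        b = roc_points(np.exp(3 * scores) + 7, labels).area
        assert a == pytest.approx(b)
        assert a == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points([0.1, 0.2], [1, 1])


def _separable_clouds(n=200, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([
        rng.normal(loc=+3.0, scale=0.3, size=(half, 2)),
        rng.normal(loc=-3.0, scale=0.3, size=(half, 2)),
    ])
    y = np.array([1] * half + [0] * half)
    return X, y


class TestCrossval:
    def test_separable_clouds_perfect_accuracy(self):
        X, y = _separable_clouds()
        report = crossval(X, y, model="svm", folds=10, seed=0)
        assert report.acc == 100.0
        assert report.roc.area == 1.0
        assert report.pooled.total == 200

    def test_deterministic_per_seed(self):
        X, y = _separable_clouds(n=60, seed=3)
        X += np.random.default_rng(1).normal(scale=3.0, size=X.shape)  # make it hard
        a = crossval(X, y, model="svm", folds=5, seed=9)
        b = crossval(X, y, model="svm", folds=5, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_stratified_folds(self):
        X, y = _separable_clouds(n=100)
        report = crossval(X, y, model="decision_tree", folds=10, seed=2)
        for counts in report.fold_counts:
            pos = counts.tp + counts.fn
            neg = counts.tn + counts.fp
            assert abs(pos - neg) <= 1  # global ratio is 1:1

    def test_pooled_counts_sum_folds(self):
        X, y = _separable_clouds(n=80)
        report = crossval(X, y, model="naive_bayes", folds=8, seed=0)
        summed = sum(report.fold_counts, ConfusionCounts())
        assert summed == report.pooled

    def test_small_class_errors(self):
        X = np.zeros((12, 2))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="fewer than"):
            crossval(X, y, folds=5, seed=0)

    @pytest.mark.parametrize(
        "name", ["svm", "random_forest", "decision_tree", "naive_bayes"]
    )
    def test_all_four_model_types_run(self, name):
        X, y = _separable_clouds(n=60)
        report = crossval(X, y, model=name, folds=3, seed=0)
        assert report.acc >= 95.0  # trivially separable

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_classifier("perceptron")

    def test_roc_plot_written(self, tmp_path):
        X, y = _separable_clouds(n=40)
        report = crossval(X, y, model="svm", folds=4, seed=0)
        out = tmp_path / "roc.png"
        plot_roc(report, out)
        assert out.stat().st_size > 0
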