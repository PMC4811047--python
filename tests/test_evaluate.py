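import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosforest.evaluate import (
    ConfusionCounts,
    confusion,
    cross_validate,
    evaluate_predictions,
    metrics_from_counts,
    roc_auc,
)


class TestMetricsFromCounts:
    def test_perfect_classifier_corner(self):
        r = metrics_from_counts(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert r.accuracy == 100.0 and r.mcc == pytest.approx(1.0)
        assert r.f1 == pytest.approx(100.0)

    def test_inverted_classifier_corner(self):
        r = metrics_from_counts(ConfusionCounts(tp=0, fp=5, tn=0, fn=5))
        assert r.accuracy == 0.0 and r.mcc == pytest.approx(-1.0)

    def test_hand_computed_panel(self):
        r = metrics_from_counts(ConfusionCounts(tp=40, fp=10, tn=35, fn=15))
        assert r.accuracy == pytest.approx(75.0)
        assert r.precision == pytest.approx(80.0)
        assert r.sensitivity == pytest.approx(100 * 40 / 55)
        assert r.specificity == pytest.approx(100 * 35 / 45)
        assert r.mcc == pytest.approx(
            (40 * 35 - 10 * 15) / math.sqrt(50 * 55 * 45 * 50)
        )

    def test_zero_denominator_reported_undefined(self):
        r = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert r.precision is None and "precision" in r.undefined
        assert r.f1 is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=1)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_panel_bounds_and_f1_consistency(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))
        for v in (r.accuracy, r.precision, r.sensitivity, r.specificity, r.f1):
            assert v is None or 0.0 <= v <= 100.0
        assert r.mcc is None or -1.0 <= r.mcc <= 1.0
        if r.f1 is not None:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
            )


class TestRocAuc:
    def test_constant_scores_auc_half(self):
        auc, _ = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_perfect_ordering_auc_one(self):
        labels = [0] * 5 + [1] * 5
        scores = np.linspace(0, 1, 10)
        auc, points = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.random(1000)
        labels = np.array([0, 1] * 500)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=60),
           st.randoms(use_true_random=False))
    def test_trapezoid_equals_rank_statistic(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        # roc_auc raises internally if the two formulations ever disagree
        auc, _ = roc_auc(scores, labels)
        assert 0.0 <= auc <= 1.0

    @given(st.randoms(use_true_random=False))
    def test_label_swap_symmetry(self, rnd):
        scores = np.array([rnd.random() for _ in range(50)])
        labels = np.array([rnd.randint(0, 1) for _ in range(50)])
        if len(set(labels.tolist())) < 2:
            labels[:2] = [0, 1]
        auc, _ = roc_auc(scores, labels)
        auc_sw, _ = roc_auc(-scores, 1 - labels)
        assert auc_sw == pytest.approx(auc, abs=1e-12)
        r = evaluate_predictions(labels, scores, threshold=0.5)
        if r.mcc is not None:
            calls = scores >= 0.5
            swapped = metrics_from_counts(confusion(1 - labels, ~calls))
            if swapped.mcc is not None:
                assert swapped.mcc == pytest.approx(r.mcc)


@pytest.fixture(scope="module")
def toy():
    from phosforest.features import FeatureSchema

    schema = FeatureSchema.for_window(5)
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, schema.total_length))
    y = np.array([0, 1] * 60)
    X[y == 1, :8] += 4.0  # several strongly shifted columns
    return X, y, schema


class TestCrossValidate:

    def test_fold_sizes_balanced(self, toy):
        X, y, schema = toy
        res = cross_validate(X, y, k_folds=10, n_trees=10, seed=1, schema=schema)
        sizes = np.bincount(res.fold_assignment)
        assert len(sizes) == 10 and set(sizes) <= {11, 12, 13}

    def test_same_seed_identical_folds_and_metrics(self, toy):
        X, y, schema = toy
        a = cross_validate(X, y, k_folds=5, n_trees=10, seed=7, schema=schema)
        b = cross_validate(X, y, k_folds=5, n_trees=10, seed=7, schema=schema)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.pooled.to_dict() == b.pooled.to_dict()

    def test_stratification_keeps_class_balance(self, toy):
        X, y, schema = toy
        res = cross_validate(X, y, k_folds=10, n_trees=10, seed=1, schema=schema)
        for fold in range(10):
            assert y[res.fold_assignment == fold].mean() == pytest.approx(0.5)

    def test_easy_signal_recovered(self, toy):
        X, y, schema = toy
        res = cross_validate(X, y, k_folds=5, n_trees=25, seed=0, schema=schema)
        assert res.pooled.auc > 0.95

    def test_too_few_windows_names_residue(self, toy):
        X, y, schema = toy
        with pytest.raises(ValueError, match="residue Y"):
            cross_validate(X[:12], y[:12], residue="Y", k_folds=10, schema=schema)

    def test_fold_mean_sd_summary(self, toy):
        X, y, schema = toy
        res = cross_validate(X, y, k_folds=5, n_trees=10, seed=0, schema=schema)
        mean, sd = res.fold_mean_sd("accuracy")
        assert 0 <= mean <= 100 and sd >= 0
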