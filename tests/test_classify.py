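"""Logistic model, ROC machinery and repeated cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from copdwatch.classify import (
    ClassifierError,
    auc,
    compare_feature_sets,
    cost,
    crossvalidate,
    fit_logistic,
    predict_proba,
    roc_curve,
    sigmoid,
    specificity_at_sensitivity,
    wald_standard_errors,
    RocSummary,
    FPR_GRID,
)


def pairwise_auc_oracle(scores, labels):
    """Probability that a random positive outscores a random negative,
    counting ties as 1/2 (O(n^2) enumeration)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def simulate_logistic(rng, theta, n):
    X = rng.normal(size=(n, len(theta) - 1))
    p = sigmoid(theta[0] + X @ np.asarray(theta[1:]))
    return X, (rng.random(n) < p).astype(int)


class TestSigmoid:
    def test_symmetry_and_midpoint(self, rng):
        assert sigmoid(0.0) == 0.5
        y = rng.normal(scale=10, size=50)
        np.testing.assert_allclose(sigmoid(y) + sigmoid(-y), 1.0, atol=1e-15)

    def test_saturation_without_overflow(self):
        assert sigmoid(50.0) == pytest.approx(1.0, abs=1e-15)
        assert sigmoid(-800.0) == 0.0  # no warning, no NaN


class TestCost:
    def test_zero_parameters_on_balanced_labels_is_ln2(self):
        X = np.zeros((10, 3))
        y = np.array([0, 1] * 5)
        assert cost(np.zeros(4), X, y) == pytest.approx(np.log(2), abs=1e-15)

    def test_matches_per_sample_loop_oracle(self, rng):
        X = rng.normal(size=(40, 4))
        y = (rng.random(40) < 0.4).astype(int)
        theta = rng.normal(size=5)
        total = 0.0
        for i in range(40):
            z = theta[0] + float(X[i] @ theta[1:])
            p = 1.0 / (1.0 + np.exp(-z))
            total += -(y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p))
        assert cost(theta, X, y) == pytest.approx(total / 40, abs=1e-12)

    def test_confident_correct_predictions_cost_near_zero(self):
        X = np.array([[-50.0], [50.0]])
        y = np.array([0, 1])
        assert cost(np.array([0.0, 1.0]), X, y) < 1e-12

    def test_invalid_labels_rejected(self):
        with pytest.raises(ClassifierError, match="labels"):
            cost(np.zeros(2), np.zeros((2, 1)), np.array([0, 2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_convexity_along_random_segments(self, seed, t):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        t1, t2 = rng.normal(size=4), rng.normal(size=4)
        mid = t * t1 + (1 - t) * t2
        assert cost(mid, X, y) <= t * cost(t1, X, y) + (1 - t) * cost(t2, X, y) + 1e-9


class TestFitLogistic:
    def test_recovers_generating_parameters_within_3_se(self, rng):
        theta_true = np.array([-0.5, 0.8, -0.6, 0.25])
        X, y = simulate_logistic(rng, theta_true, 5000)
        model = fit_logistic(X, y)
        se = wald_standard_errors(model, X, y)
        assert np.all(np.abs(model.theta_original - theta_true) < 3 * se)

    def test_row_permutation_leaves_fit_unchanged(self, rng):
        X, y = simulate_logistic(rng, [0.0, 1.0, -1.0], 400)
        m1 = fit_logistic(X, y)
        perm = rng.permutation(len(y))
        m2 = fit_logistic(X[perm], y[perm])
        np.testing.assert_allclose(m1.theta, m2.theta, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError, match="single class"):
            fit_logistic(np.zeros((5, 2)), np.ones(5))

    def test_separable_data_still_returns_a_ranking_fit(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(X, y)
        p = predict_proba(model, X)
        assert np.all(p[:3] < 0.5) and np.all(p[3:] > 0.5)


class TestPredictProba:
    def test_zero_model_predicts_half(self):
        model = fit_logistic(np.array([[0.0], [1.0]]), np.array([0, 1]))
        model.theta = np.zeros_like(model.theta)
        assert predict_proba(model, np.array([[123.0]]))[0] == 0.5

    def test_monotone_in_positive_coefficient_feature(self, rng):
        X, y = simulate_logistic(rng, [0.0, 2.0], 500)
        model = fit_logistic(X, y)
        grid = np.linspace(-3, 3, 20)[:, None]
        p = predict_proba(model, grid)
        assert np.all(np.diff(p) > 0)

    def test_matches_hand_arithmetic_on_two_feature_toy(self):
        model = fit_logistic(np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0, 1]))
        model.theta = np.array([0.2, 0.5, -1.0])
        model.center = np.zeros(2)
        model.scale = np.ones(2)
        x = np.array([[2.0, 3.0]])
        expected = 1.0 / (1.0 + np.exp(-(0.2 + 0.5 * 2.0 - 1.0 * 3.0)))
        assert predict_proba(model, x)[0] == pytest.approx(expected, abs=1e-15)

    def test_dimension_mismatch_rejected(self):
        model = fit_logistic(np.array([[0.0], [1.0]]), np.array([0, 1]))
        with pytest.raises(ClassifierError, match="features"):
            predict_proba(model, np.zeros((1, 3)))


class TestRocCurve:
    def test_perfect_separation_reaches_the_corner(self):
        fpr, tpr = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc(fpr, tpr) == 1.0
        assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))

    def test_all_tied_scores_give_the_diagonal(self):
        fpr, tpr = roc_curve([0.5] * 8, [0, 1, 0, 1, 0, 1, 0, 1])
        assert auc(fpr, tpr) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ClassifierError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_auc_equals_pairwise_concordance_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)  # ties likely
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            fpr, tpr = roc_curve(scores, labels)
            assert auc(fpr, tpr) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_auc_invariant_under_strictly_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        a1 = auc(*roc_curve(scores, labels))
        a2 = auc(*roc_curve(np.exp(3 * scores) + 7, labels))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestCrossvalidate:
    def test_same_seed_reproduces_the_summary_exactly(self, rng):
        X, y = simulate_logistic(rng, [-1.0, 1.0, 0.5], 160)
        s1 = crossvalidate(X, y, k=5, reps=8, seed=42)
        s2 = crossvalidate(X, y, k=5, reps=8, seed=42)
        np.testing.assert_array_equal(s1.aucs, s2.aucs)
        np.testing.assert_array_equal(s1.mean_tpr, s2.mean_tpr)
        s3 = crossvalidate(X, y, k=5, reps=8, seed=43)
        assert not np.array_equal(s1.aucs, s3.aucs)

    def test_mean_curve_lies_within_the_percentile_envelope(self, rng):
        X, y = simulate_logistic(rng, [-0.5, 1.0], 200)
        s = crossvalidate(X, y, k=5, reps=30, seed=0)
        assert np.all(s.mean_tpr >= s.tpr_lo - 1e-12)
        assert np.all(s.mean_tpr <= s.tpr_hi + 1e-12)
        assert np.all(np.diff(s.mean_tpr) >= -1e-12)

    def test_permuted_labels_score_at_chance(self, rng):
        X, y = simulate_logistic(rng, [-1.0, 1.5, -1.0], 300)
        y_perm = rng.permutation(y)
        s = crossvalidate(X, y_perm, k=10, reps=20, seed=5)
        assert s.mean_auc == pytest.approx(0.5, abs=0.08)

    def test_matches_analytic_auc_for_separated_gaussians(self, rng):
        # equal-variance gaussian classes: AUC = Phi(delta / (sigma*sqrt(2)))
        delta, sigma, n = 1.5, 1.0, 1500
        y = (rng.random(n) < 0.4).astype(int)
        x = rng.normal(y * delta, sigma)[:, None]
        s = crossvalidate(x, y, k=10, reps=5, seed=3)
        expected = norm.cdf(delta / (sigma * np.sqrt(2)))
        assert s.mean_auc == pytest.approx(expected, abs=0.02)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ClassifierError):
            crossvalidate(np.zeros((10, 1)), np.array([0, 1] * 5), reps=0)

    def test_group_constraint_keeps_patients_in_one_fold(self, rng):
        X, y = simulate_logistic(rng, [-1.0, 1.0], 120)
        groups = np.repeat(np.arange(24), 5)
        s = crossvalidate(X, y, k=4, reps=3, seed=0, groups=groups)
        assert len(s.aucs) == 3  # runs cleanly with grouped folds


class TestOperatingPoints:
    def make_summary(self, tpr):
        g = FPR_GRID
        return RocSummary(fpr_grid=g, mean_tpr=tpr, tpr_lo=tpr, tpr_hi=tpr,
                          aucs=np.array([0.5]))

    def test_perfect_classifier_keeps_full_specificity(self):
        tpr = np.ones_like(FPR_GRID)
        spec = specificity_at_sensitivity(self.make_summary(tpr), (0.6, 0.8))
        assert spec == {0.6: 1.0, 0.8: 1.0}

    def test_diagonal_curve_trades_one_for_one(self):
        spec = specificity_at_sensitivity(self.make_summary(FPR_GRID.copy()), (0.6, 0.8))
        assert spec[0.6] == pytest.approx(0.4)
        assert spec[0.8] == pytest.approx(0.2)

    def test_unattainable_sensitivity_reported_as_none(self):
        tpr = np.minimum(FPR_GRID, 0.55)
        spec = specificity_at_sensitivity(self.make_summary(tpr), (0.9,))
        assert spec[0.9] is None


class TestCompareFeatureSets:
    def frame(self, rng, n=150):
        X = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["pr_mean", "pr_grad", "spo2_mean", "spo2_grad"]
        )
        logit = -1.0 + 2.0 * X["spo2_mean"] + 0.3 * X["pr_mean"]
        y = (rng.random(n) < sigmoid(logit)).astype(int)
        return X, y

    def test_more_informative_subset_wins(self, rng):
        X, y = self.frame(rng)
        subsets = {"PR": ["pr_mean", "pr_grad"], "SpO2": ["spo2_mean", "spo2_grad"],
                   "both": list(X.columns)}
        table = compare_feature_sets(X, y, subsets=subsets, k=5, reps=10, seed=0)
        res = dict(zip(table["subset"], table["mean_auc"]))
        assert res["SpO2"] > res["PR"]
        assert res["both"] >= res["SpO2"] - 0.02

    def test_duplicate_subset_deduplicated_with_warning(self, rng):
        X, y = self.frame(rng, n=80)
        subsets = {"a": ["pr_mean"], "b": ["pr_mean"]}
        with pytest.warns(UserWarning, match="duplicate"):
            table = compare_feature_sets(X, y, subsets=subsets, k=4, reps=2, seed=0)
        assert table["subset"].tolist() == ["a"]

    def test_unknown_feature_name_rejected(self, rng):
        X, y = self.frame(rng, n=80)
        with pytest.raises(ClassifierError, match="unknown"):
            compare_feature_sets(X, y, subsets={"bad": ["nope"]}, k=4, reps=2, seed=0)
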