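"""Nested CV machinery: folds, fold pipeline, AUC, leakage and determinism."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prosodyml.classifier_core import (
    ClassifierError,
    CVConfig,
    DesignMatrix,
    _fit_linear_svc,
    _fit_sigmoid,
    _rep_seeds,
    _svc_decision,
    confusion_stats,
    fit_fold,
    predict_scores,
    repeated_nested_cv,
    roc_auc,
    single_repetition,
    stratified_folds,
    summarize,
)


def _dm(X, y):
    return DesignMatrix(X=X, y=y, speaker_ids=[f"s{i}" for i in range(len(y))])


def brute_force_auc(scores, y):
    pos = np.asarray(scores)[np.asarray(y) == 1]
    neg = np.asarray(scores)[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_frozen_pairwise_example(self):
        # brute force over the 4 positive-negative pairs: 2 wins of 4 -> 0.5
        assert roc_auc([0.8, 0.3, 0.6, 0.2], [1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[: int(rng.integers(1, n))] ] = 1
        if y.min() == y.max():
            return
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
        ours = roc_auc(scores, y)
        assert ours == pytest.approx(brute_force_auc(scores, y), abs=1e-12)
        from sklearn.metrics import roc_auc_score
        assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestConfusionStats:
    @pytest.mark.parametrize("pred,y,expected", [
        ([1, 0, 0, 0], [1, 1, 0, 0], (0.75, 0.5, 1.0)),
        ([1, 1, 0, 0], [1, 1, 0, 0], (1.0, 1.0, 1.0)),
        ([0, 0, 1, 1], [1, 1, 0, 0], (0.0, 0.0, 0.0)),
    ])
    def test_examples(self, pred, y, expected):
        assert confusion_stats(np.array(pred), np.array(y)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ClassifierError):
            confusion_stats(np.array([1, 0]), np.array([1, 0, 1]))


class TestStratifiedFolds:
    def test_balanced_24_24_into_10(self):
        y = np.r_[np.ones(24, int), np.zeros(24, int)]
        folds = stratified_folds(y, 10, seed=1)
        for f in range(10):
            size = np.sum(folds == f)
            assert size in (4, 5)
            per_class = np.sum((folds == f) & (y == 1))
            assert per_class in (2, 3)

    def test_determinism(self):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert np.array_equal(stratified_folds(y, 5, 9), stratified_folds(y, 5, 9))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ClassifierError):
            stratified_folds(np.array([1, 1, 1, 0, 0, 0]), 10, 0)


class TestLinearSVCSolver:
    def test_matches_sklearn_liblinear(self):
        """Independent oracle: sklearn LinearSVC optimizes the same objective."""
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(1)
        for c in (1e-3, 0.1, 1.0, 100.0):
            Z = rng.standard_normal((40, 12))
            y = (Z @ rng.standard_normal(12) + 0.3 * rng.standard_normal(40) > 0).astype(int)
            w = _fit_linear_svc(Z, y, c)
            sk = LinearSVC(C=c, dual=False, tol=1e-10, max_iter=100000).fit(Z, y)
            ref = np.r_[sk.coef_[0], sk.intercept_]
            assert np.linalg.norm(w - ref) / np.linalg.norm(ref) < 1e-4

    def test_sigmoid_calibrator_monotone(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal(60)
        y = (d + 0.5 * rng.standard_normal(60) > 0).astype(int)
        a, b = _fit_sigmoid(d, y)
        assert a > 0  # aligned decisions get an increasing sigmoid


class TestFitFold:
    def test_component_cap_rank_bound(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 500))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        model = fit_fold(X, y, CVConfig(repeats=1), seed=0)
        assert model.n_components <= 39

    def test_single_class_fold_raises(self):
        with pytest.raises(ClassifierError, match="single-class"):
            fit_fold(np.random.default_rng(0).standard_normal((10, 4)),
                     np.ones(10, int), CVConfig(repeats=1))

    def test_separable_training_data_fits_perfectly(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = rng.standard_normal((40, 5)) * 0.1
        X[:, 0] = (2 * y - 1) * 10.0  # margin ~10 SD on feature 1
        model = fit_fold(X, y, CVConfig(repeats=1), seed=0)
        scores = predict_scores(model, X)
        assert np.array_equal(scores >= 0.5, y.astype(bool))

    def test_duplicated_columns_same_predictions(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        X = rng.standard_normal((30, 6))
        X[:, 0] += (2 * y - 1) * 4.0
        X_test = rng.standard_normal((8, 6))
        m1 = fit_fold(X, y, CVConfig(repeats=1), seed=1)
        m2 = fit_fold(np.hstack([X, X]), y, CVConfig(repeats=1), seed=1)
        p1 = predict_scores(m1, X_test) >= 0.5
        p2 = predict_scores(m2, np.hstack([X_test, X_test])) >= 0.5
        assert np.array_equal(p1, p2)


class TestRepeatedNestedCV:
    def test_determinism(self):
        rng = np.random.default_rng(5)
        dm = _dm(rng.standard_normal((20, 30)),
                 np.r_[np.ones(10, int), np.zeros(10, int)])
        cfg = CVConfig(outer_folds=5, repeats=3, seed=11)
        r1 = repeated_nested_cv(dm, cfg)
        r2 = repeated_nested_cv(dm, cfg)
        assert [a.auc for a in r1] == [a.auc for a in r2]
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.scores, b.scores)

    def test_high_variance_signal_feature_perfect_auc(self):
        # the label lives in one feature whose variance dwarfs the rest, so
        # PCA keeps it as the leading component (standardization off, which
        # would otherwise flatten the variance cue)
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(24, int), np.zeros(24, int)]
        X = rng.standard_normal((48, 10))
        X[:, 0] = (2 * y - 1) * 50 + rng.standard_normal(48)
        res = repeated_nested_cv(_dm(X, y),
                                 CVConfig(repeats=3, seed=0, standardize=False))
        assert summarize(res, y).median_auc == 1.0

    def test_null_features_chance_auc(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(24, int), np.zeros(24, int)]
        X = rng.standard_normal((48, 100))
        res = repeated_nested_cv(_dm(X, y), CVConfig(repeats=11, seed=1))
        assert 0.35 <= summarize(res, y).median_auc <= 0.65

    def test_no_leakage_from_heldout_rows(self):
        """Corrupting one speaker's features only changes scores of folds
        that trained on that speaker - never of its own test fold."""
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        X = rng.standard_normal((20, 15))
        cfg = CVConfig(outer_folds=5, repeats=1, seed=21)
        fold_seed, _ = _rep_seeds(cfg.seed, 0)
        assignment = stratified_folds(y, cfg.outer_folds, fold_seed)
        target = 3
        X2 = X.copy()
        X2[target] = 777.0
        r1 = single_repetition(_dm(X, y), cfg, rep=0)
        r2 = single_repetition(_dm(X2, y), cfg, rep=0)
        same_fold = (assignment == assignment[target]) & (np.arange(20) != target)
        np.testing.assert_array_equal(r1.scores[same_fold], r2.scores[same_fold])


class TestSummarize:
    def _fake(self, auc, n=4):
        from prosodyml.classifier_core import RepetitionResult
        pred = np.array([1, 1, 0, 0])
        return RepetitionResult(scores=np.full(n, auc), predicted=pred, auc=auc,
                                acc=auc, sens=1.0, spec=0.5, chosen_c=[1.0])

    def test_median_of_three(self):
        y = np.array([1, 1, 0, 0])
        s = summarize([self._fake(0.8), self._fake(0.6), self._fake(0.7)], y)
        assert s.median_auc == 0.7
        assert s.acc == 0.7  # acc taken from the same (median) repetition

    def test_aggregated_confusion_conservation(self):
        y = np.array([1, 1, 0, 0])
        s = summarize([self._fake(a) for a in (0.5, 0.6, 0.7)], y)
        assert s.aggregated_confusion.sum() == 3 * 4

    def test_empty_rejected(self):
        with pytest.raises(ClassifierError):
            summarize([], np.array([1, 0]))

    def test_even_repeats_rejected(self):
        with pytest.raises(ClassifierError):
            CVConfig(repeats=10)
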