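"""Fold construction, metric oracles, bootstrap inference, baseline, CV harness."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import priorvae as pv
from priorvae.io import LabelTable
from priorvae.training import (
    auc_difference_test,
    bootstrap_ci,
    evaluate,
    lasso_baseline,
    make_folds,
    train_model,
)


class TestMakeFolds:
    def test_balanced_ten_samples_one_of_each_per_fold(self):
        y = LabelTable([f"s{i}" for i in range(10)], [1] * 5 + [0] * 5)
        folds = make_folds(y, n_folds=5, seed=42)
        for k in range(5):
            _, val = folds.split(k)
            assert len(val) == 2
            assert sorted(y.labels[val]) == [0, 1]

    def test_deterministic_and_partition(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(37) < 0.4).astype(int)
        y = LabelTable([f"s{i}" for i in range(37)], labels)
        f1 = make_folds(y, seed=42)
        f2 = make_folds(y, seed=42)
        np.testing.assert_array_equal(f1.fold_index, f2.fold_index)
        covered = np.concatenate([f1.split(k)[1] for k in range(5)])
        assert sorted(covered) == list(range(37))

    def test_stratification_within_one_sample(self):
        labels = np.array([1] * 12 + [0] * 28)
        y = LabelTable([f"s{i}" for i in range(40)], labels)
        folds = make_folds(y, seed=1)
        per_fold_pos = [labels[folds.split(k)[1]].sum() for k in range(5)]
        assert max(per_fold_pos) - min(per_fold_pos) <= 1

    def test_tiny_minority_warns(self):
        y = LabelTable([f"s{i}" for i in range(10)], [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="best-effort"):
            make_folds(y, n_folds=5, seed=0)


def _pairwise_auc(labels, scores):
    """Enumerate positive-negative pairs (independent AUC oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    class _Stub:
        def __init__(self, scores):
            self._scores = np.asarray(scores, float)

        def predict_proba(self, X):
            return self._scores

    def test_auc_matches_pair_enumeration(self):
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        assert _pairwise_auc(labels, scores) == 0.75
        m = evaluate(self._Stub(scores), np.zeros((4, 1)), labels)
        assert m.auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        labels = np.array([0, 0, 1, 1])
        m = evaluate(self._Stub([0.1, 0.2, 0.8, 0.9]), np.zeros((4, 1)), labels)
        assert m.auc == 1.0 and m.aupr == 1.0 and m.accuracy == 1.0

    def test_constant_score_no_skill(self):
        labels = np.array([1, 0, 0, 0, 1, 0])
        m = evaluate(self._Stub([0.5] * 6), np.zeros((6, 1)), labels)
        assert m.auc == pytest.approx(0.5)
        assert m.aupr == pytest.approx(np.mean(labels))  # positive prevalence

    def test_single_class_warns_with_nan(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = evaluate(self._Stub([0.6, 0.7]), np.zeros((2, 1)), np.array([1, 1]))
        assert np.isnan(m.auc) and m.accuracy == 1.0


class TestTrainModel:
    def test_zero_epochs_returns_initialized_weights(self, tiny_config, tiny_prior):
        X = np.random.default_rng(0).standard_normal((8, 9))
        y = np.array([1, 0] * 4, float)
        model, history = train_model(X, y, tiny_prior, tiny_config,
                                     pv.TrainSettings(epochs=0, seed=1))
        ref = pv.PriorFusionVAE(tiny_config, tiny_prior)
        for p, q in zip(model.parameters(), ref.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        assert history == []

    def test_loss_decreases_and_seeded_runs_identical(self, tiny_config, tiny_prior):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((24, 9))
        y = (rng.random(24) < 0.5).astype(float)
        X[y == 1, :3] += 2.0  # learnable signal
        settings = pv.TrainSettings(epochs=20, seed=42)
        m1, h1 = train_model(X, y, tiny_prior, tiny_config, settings)
        m2, h2 = train_model(X, y, tiny_prior, tiny_config, settings)
        assert h1[-1].total < h1[0].total
        for p, q in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        assert [a.total for a in h1] == [b.total for b in h2]


class TestBootstrap:
    def test_perfect_separation_collapses(self):
        labels = np.array([0] * 10 + [1] * 10)
        scores = np.array([0.1] * 10 + [0.9] * 10)
        lo, hi = bootstrap_ci(scores, labels, "auc", n_rep=200, seed=0)
        assert lo == hi == 1.0

    def test_bounds_ordered_and_deterministic(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(60) < 0.5).astype(int)
        scores = rng.random(60)
        a = bootstrap_ci(scores, labels, "auc", n_rep=300, seed=5)
        b = bootstrap_ci(scores, labels, "auc", n_rep=300, seed=5)
        assert a == b and a[0] <= a[1]

    def test_coverage_of_known_auc(self):
        """Binormal scores with true AUC 0.8: the 95% interval should cover
        0.8 in >= 90% of simulated datasets."""
        from scipy.stats import norm

        true_auc = 0.8
        mu = np.sqrt(2) * norm.ppf(true_auc)  # Phi(mu/sqrt(2)) = 0.8
        rng = np.random.default_rng(7)
        hits = 0
        n_sets = 100
        for i in range(n_sets):
            labels = np.array([0] * 50 + [1] * 50)
            scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(mu, 1, 50)])
            lo, hi = bootstrap_ci(scores, labels, "auc", n_rep=1000, seed=i)
            hits += lo <= true_auc <= hi
        assert hits / n_sets >= 0.90

    def test_rank_auc_identity_with_trapezoidal(self):
        """The midrank AUC used inside the bootstrap must equal sklearn's
        trapezoidal ROC AUC, ties included."""
        from priorvae.training import _auc_by_ranks

        rng = np.random.default_rng(11)
        for _ in range(20):
            scores = np.round(rng.random(40), 1)  # heavy ties
            labels = rng.integers(0, 2, 40)
            if len(np.unique(labels)) < 2:
                continue
            assert _auc_by_ranks(scores[None, :], labels[None, :])[0] == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestAucDifference:
    def test_identical_scorers(self):
        rng = np.random.default_rng(8)
        labels = (rng.random(50) < 0.5).astype(int)
        scores = rng.random(50)
        assert auc_difference_test(scores, scores, labels, n_rep=200, seed=0) >= 0.9

    def test_perfect_vs_random(self):
        rng = np.random.default_rng(9)
        labels = np.array([0, 1] * 100)
        perfect = labels.astype(float)
        random_scores = rng.random(200)
        p = auc_difference_test(perfect, random_scores, labels, n_rep=500, seed=1)
        assert 0 <= p < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            auc_difference_test([0.1], [0.2, 0.3], [1, 0])


class TestLassoBaseline:
    def test_separable_data_and_shared_folds(self, small_cohort):
        folds = make_folds(small_cohort.labels, seed=42)
        res = lasso_baseline(small_cohort.abundance, small_cohort.labels, folds)
        assert res.mean_auc >= 0.9
        assert len(res.auc) == 5
        covered = np.concatenate(res.fold_val_indices)
        assert sorted(covered) == list(range(small_cohort.abundance.n_samples))
        for clf in res.fold_models:
            assert (clf.coef_ != 0).sum() <= small_cohort.abundance.n_features


class TestRunCv:
    def test_metrics_structure_and_prediction_coverage(self, small_cv, small_cohort):
        assert len(small_cv.auc) == 5
        covered = np.concatenate(small_cv.fold_val_indices)
        assert sorted(covered) == list(range(small_cohort.abundance.n_samples))
        summary = small_cv.summary()
        assert summary["auc_mean"] == pytest.approx(np.mean(small_cv.auc))
        for vals in (small_cv.accuracy, small_cv.auc, small_cv.aupr):
            assert all(0 <= v <= 1 for v in vals)

    def test_separable_cohort_auc(self, small_cv):
        assert small_cv.mean_auc >= 0.9
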