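"""Stacking ensemble: OOF bookkeeping, stacking layer, greedy selection."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

import cohortshift as cs
from cohortshift.ensemble import StackConfig, _val_loss, make_learner


def _binary_data(n=100, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = (X[:, 0] + rng.normal(scale=0.5, size=n) > 0).astype(int)
    return X, y


class _FoldMeanLearner(BaseEstimator, ClassifierMixin):
    """Predicts the mean label of its training set; exposes what it was shown."""

    def fit(self, X, y, sample_weight=None):
        self.mean_ = float(np.mean(y))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.mean_), np.full(len(X), self.mean_)])


class _ConstantHalf(BaseEstimator, ClassifierMixin):
    def fit(self, X, y, sample_weight=None):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


class TestOOFPredictions:
    def test_full_coverage_and_no_self_prediction(self):
        # the fold-mean learner proves exclusion: the OOF value for each row
        # equals the mean label of the OTHER folds, never including the row's own
        X, y = _binary_data(60, seed=1)
        oof = cs.oof_predictions({"fm": _FoldMeanLearner()}, X, y, k=5, repeats=2, seed=0)
        preds = oof.predictions["fm"]
        assert preds.shape == (60, 2)
        assert np.all(np.isfinite(preds))
        for r in range(2):
            for f in range(5):
                members = oof.fold_assignment[:, r] == f
                others = ~members
                expected = y[others].mean()
                np.testing.assert_allclose(preds[members, r], expected, atol=1e-12)

    def test_constant_learner_gives_constant_column(self):
        X, y = _binary_data(40, seed=2)
        oof = cs.oof_predictions({"c": _ConstantHalf()}, X, y, k=4, repeats=1, seed=0)
        np.testing.assert_array_equal(oof.predictions["c"], 0.5)

    def test_averaged_equals_mean_of_per_repeat_columns(self):
        X, y = _binary_data(50, seed=3)
        oof = cs.oof_predictions({"fm": _FoldMeanLearner()}, X, y, k=5, repeats=2, seed=4)
        manual = oof.predictions["fm"].mean(axis=1)
        np.testing.assert_allclose(oof.averaged()[:, 0], manual, atol=1e-15)

    def test_small_class_errors_with_guidance(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        y = np.r_[np.ones(2), np.zeros(18)].astype(int)
        with pytest.raises(ValueError, match="smaller k"):
            cs.oof_predictions({"c": _ConstantHalf()}, X, y, k=5)


class TestFitStack:
    def test_oracle_oof_feature_gives_perfect_training_discrimination(self):
        X, y = _binary_data(80, seed=5)
        oof = cs.OOFMatrix(
            predictions={"oracle": y[:, None].astype(float)},
            fold_assignment=np.zeros((80, 1), dtype=int),
            k=5, repeats=1, seed=0,
        )
        stacked = cs.fit_stack(oof, X, y, stack_learners={"lr": LogisticRegression(max_iter=1000)})
        scores = stacked["lr"].predict_proba(np.hstack([y[:, None], X]))[:, 1]
        assert cs.auc(scores, y) == 1.0

    def test_constant_oof_columns_reduce_to_plain_fit(self):
        X, y = _binary_data(100, seed=6)
        oof = cs.OOFMatrix(
            predictions={"c": np.full((100, 1), 0.5)},
            fold_assignment=np.zeros((100, 1), dtype=int),
            k=5, repeats=1, seed=0,
        )
        stacked = cs.fit_stack(oof, X, y, stack_learners={"lr": LogisticRegression(max_iter=1000)})
        plain = LogisticRegression(max_iter=1000).fit(X, y)
        s1 = stacked["lr"].predict_proba(np.hstack([np.full((100, 1), 0.5), X]))[:, 1]
        s2 = plain.predict_proba(X)[:, 1]
        assert abs(cs.auc(s1, y) - cs.auc(s2, y)) < 1e-6

    def test_uniform_weights_match_omitted_weights(self):
        X, y = _binary_data(60, seed=7)
        oof = cs.OOFMatrix(
            predictions={"c": np.full((60, 1), 0.5)},
            fold_assignment=np.zeros((60, 1), dtype=int),
            k=5, repeats=1, seed=0,
        )
        a = cs.fit_stack(oof, X, y, sample_weight=np.ones(60),
                         stack_learners={"lr": LogisticRegression(max_iter=1000, tol=1e-12)})
        b = cs.fit_stack(oof, X, y, sample_weight=None,
                         stack_learners={"lr": LogisticRegression(max_iter=1000, tol=1e-12)})
        np.testing.assert_allclose(a["lr"].coef_, b["lr"].coef_, atol=1e-9)

    def test_misalignment_errors(self):
        X, y = _binary_data(30, seed=8)
        oof = cs.OOFMatrix(
            predictions={"c": np.full((29, 1), 0.5)},
            fold_assignment=np.zeros((29, 1), dtype=int),
            k=5, repeats=1, seed=0,
        )
        with pytest.raises(ValueError, match="misaligned"):
            cs.fit_stack(oof, X, y)


class TestEnsembleSelection:
    def test_single_candidate_gets_weight_one(self):
        y = np.array([0, 1, 0, 1])
        w = cs.ensemble_selection(np.array([[0.2, 0.8, 0.1, 0.9]]), y, iters=10)
        np.testing.assert_array_equal(w, [1.0])

    def test_dominant_candidate_takes_all_weight(self):
        y = np.array([0, 1] * 10)
        good = np.where(y == 1, 0.9, 0.1)
        bad = np.where(y == 1, 0.6, 0.4)
        w = cs.ensemble_selection(np.vstack([bad, good]), y, iters=15)
        np.testing.assert_array_equal(w, [0.0, 1.0])

    def test_complementary_candidates_blend_at_least_as_well(self):
        # each candidate perfect on half the validation set, at chance elsewhere
        y = np.array([0, 1] * 8)
        a = np.where(np.arange(16) < 8, np.where(y == 1, 0.99, 0.01), 0.5)
        b = np.where(np.arange(16) >= 8, np.where(y == 1, 0.99, 0.01), 0.5)
        P = np.vstack([a, b])
        w = cs.ensemble_selection(P, y, iters=5)
        blend_loss = _val_loss(w @ P, y, "classification")
        singles = [_val_loss(P[i], y, "classification") for i in range(2)]
        assert blend_loss <= min(singles) + 1e-12

    def test_selection_never_beaten_by_best_single_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n_models, n_val = int(rng.integers(1, 6)), 30
            y = rng.integers(0, 2, n_val)
            P = rng.uniform(0.01, 0.99, (n_models, n_val))
            w = cs.ensemble_selection(P, y, iters=12)
            assert w.sum() == pytest.approx(1.0)
            blend = _val_loss(w @ P, y, "classification")
            best = min(_val_loss(P[i], y, "classification") for i in range(n_models))
            assert blend <= best + 1e-12

    def test_empty_or_nonfinite_candidates_error(self):
        with pytest.raises(ValueError):
            cs.ensemble_selection(np.empty((0, 4)), np.zeros(4))
        with pytest.raises(ValueError):
            cs.ensemble_selection(np.array([[np.nan, 0.5]]), np.array([0, 1]))


class TestStackingEnsemble:
    def test_fit_predict_round_trip_and_weight_support(self):
        X, y = _binary_data(150, d=5, seed=10)
        cfg = StackConfig(base_learners=("knn", "linear"), bag_repeats=1, selection_iters=5, seed=0)
        model = cs.StackingEnsemble(config=cfg, task="classification")
        w = np.ones(150)
        model.fit(X, y, sample_weight=w)
        p = model.predict_proba(X)[:, 1]
        assert p.shape == (150,)
        assert np.all((p >= 0) & (p <= 1))
        assert cs.auc(p, y) > 0.7
        assert model.selection_weights_.sum() == pytest.approx(1.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            StackConfig(stack_levels=3)
        with pytest.raises(ValueError):
            StackConfig(bag_folds=1)

    def test_learner_registry_covers_the_five_families(self):
        for name in ("knn", "random_forest", "gbt", "mlp", "linear"):
            for task in ("classification", "regression"):
                assert make_learner(name, task) is not None
        with pytest.raises(KeyError):
            make_learner("svm")


def test_stacked_ensemble_competitive_with_single_mlp():
    """On shifted AD-like cohorts the stack's target AUC matches or beats one MLP."""
    from sklearn.neural_network import MLPClassifier

    wins = 0
    reps = 10
    for seed in range(reps):
        cohort = cs.generate_cohort(cs.adaptation_benchmark_spec(m=250, n=150, seed=300 + seed))
        frame = cohort.frame
        tgt = frame[frame["group"] == "target"].reset_index(drop=True)
        numeric = [c for c, k in cohort.feature_kinds.items() if k == "numeric"]
        X = tgt[numeric].to_numpy()
        y = tgt["label"].to_numpy()
        tr, te = np.arange(0, 100), np.arange(100, 150)
        cfg = StackConfig(base_learners=("knn", "random_forest", "linear"), bag_repeats=1,
                          selection_iters=10, seed=seed)
        stack = cs.StackingEnsemble(config=cfg).fit(X[tr], y[tr])
        mlp = MLPClassifier(hidden_layer_sizes=(32, 32), max_iter=300, random_state=seed).fit(X[tr], y[tr])
        auc_stack = cs.auc(stack.predict_proba(X[te])[:, 1], y[te])
        auc_mlp = cs.auc(mlp.predict_proba(X[te])[:, 1], y[te])
        wins += auc_stack >= auc_mlp
    assert wins >= reps // 2
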