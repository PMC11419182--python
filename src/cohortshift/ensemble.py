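"""Stacking ensemble with repeated k-fold bagging and greedy selection.

A deliberately small reimplementation of the multi-layer-stacking recipe:
five base learner families (k-nearest neighbours, random forest,
gradient-boosted trees, MLP, logistic/linear model) produce out-of-fold
(OOF) predictions via repeated stratified k-fold bagging; the OOF columns,
concatenated with the original features (a skip connection), feed a second
and final layer of stacked learners; the stacked models are combined by
greedy forward ensemble selection with replacement on a validation set.
Sample weights from the weighted-ERM objective are threaded through every
layer; learners without native weight support fall back to a seeded
weighted resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.model_selection import StratifiedKFold, KFold

DEFAULT_BASE_LEARNERS = ("knn", "random_forest", "gbt", "mlp", "linear")


@dataclass
class StackConfig:
    """Configuration of the two-level stack."""

    base_learners: Sequence[str] = DEFAULT_BASE_LEARNERS
    bag_folds: int = 5
    bag_repeats: int = 2
    stack_levels: int = 2  # base layer + one stacking layer, by design
    selection_iters: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.stack_levels != 2:
            raise ValueError("stacking is fixed at two levels")
        if self.bag_folds < 2:
            raise ValueError("bag_folds must be >= 2")


class _ResampleWrapper(BaseEstimator):
    """Realise sample weights for weight-blind learners by weighted resampling."""

    def __init__(self, base, seed=0):
        self.base = base
        self.seed = seed

    def fit(self, X, y, sample_weight=None):
        self.model_ = clone(self.base)
        if sample_weight is None or np.allclose(sample_weight, sample_weight[0]):
            self.model_.fit(X, y)
            return self
        rng = np.random.default_rng(self.seed)
        p = np.asarray(sample_weight, dtype=float)
        p = p / p.sum()
        idx = rng.choice(len(X), size=len(X), replace=True, p=p)
        self.model_.fit(np.asarray(X)[idx], np.asarray(y)[idx])
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def make_learner(name: str, task: str = "classification", seed: int = 0):
    """Registry of the five base learner families (small fixed settings)."""
    cls = task == "classification"
    if name == "knn":
        base = KNeighborsClassifier(n_neighbors=10) if cls else KNeighborsRegressor(n_neighbors=10)
        return _ResampleWrapper(base, seed=seed)
    if name == "random_forest":
        return (
            RandomForestClassifier(n_estimators=100, random_state=seed)
            if cls
            else RandomForestRegressor(n_estimators=100, random_state=seed)
        )
    if name == "gbt":
        return (
            HistGradientBoostingClassifier(max_iter=100, random_state=seed)
            if cls
            else HistGradientBoostingRegressor(max_iter=100, random_state=seed)
        )
    if name == "mlp":
        base = (
            MLPClassifier(hidden_layer_sizes=(32, 32), max_iter=300, random_state=seed)
            if cls
            else MLPRegressor(hidden_layer_sizes=(32, 32), max_iter=300, random_state=seed)
        )
        return _ResampleWrapper(base, seed=seed)  # sklearn MLP lacks sample_weight
    if name == "linear":
        return LogisticRegression(max_iter=2000) if cls else Ridge(alpha=1.0)
    raise KeyError(f"unknown learner {name!r}")


def _predict_scores(model, X, task):
    if task == "classification":
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


@dataclass
class OOFMatrix:
    """Out-of-fold predictions: (n_samples, n_repeats) per learner.

    Every training sample has exactly one OOF prediction per repeat, made
    by a model that never saw it; ``fold_assignment`` records which fold
    each sample sat in for each repeat.
    """

    predictions: dict[str, np.ndarray]
    fold_assignment: np.ndarray  # (n_samples, n_repeats)
    k: int
    repeats: int
    seed: int

    def averaged(self) -> np.ndarray:
        """(n_samples, n_learners) matrix of repeat-averaged OOF predictions."""
        return np.column_stack([self.predictions[name].mean(axis=1) for name in self.predictions])

    @property
    def learner_names(self) -> list[str]:
        return list(self.predictions)


def oof_predictions(
    learners: dict[str, object],
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
    task: str = "classification",
) -> OOFMatrix:
    """Repeated stratified k-fold bagging producing OOF predictions.

    For each repeat the rows are split into k folds (stratified by label
    for classification); each sample's prediction comes from the model
    trained on the other k-1 folds, so no model predicts a row it saw.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError("need at least k rows")
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(f"smallest class has {counts.min()} members < k={k}; use smaller k")
    preds = {name: np.zeros((n, repeats)) for name in learners}
    fold_assignment = np.zeros((n, repeats), dtype=int)
    for r in range(repeats):
        if task == "classification":
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
            split_iter = splitter.split(X, y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed + r)
            split_iter = splitter.split(X)
        for f, (tr, te) in enumerate(split_iter):
            fold_assignment[te, r] = f
            for name, learner in learners.items():
                model = clone(learner)
                w = None if sample_weight is None else np.asarray(sample_weight)[tr]
                try:
                    model.fit(X[tr], y[tr], sample_weight=w)
                except TypeError:
                    model.fit(X[tr], y[tr])
                preds[name][te, r] = _predict_scores(model, X[te], task)
    return OOFMatrix(predictions=preds, fold_assignment=fold_assignment, k=k, repeats=repeats, seed=seed)


def fit_stack(
    base_oof: OOFMatrix,
    original_features: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    stack_learners: dict[str, object] | None = None,
    task: str = "classification",
    seed: int = 0,
) -> dict[str, object]:
    """Train the second-layer learners on [OOF columns || original features]."""
    Xorig = np.asarray(original_features, dtype=float)
    oof = base_oof.averaged()
    if oof.shape[0] != Xorig.shape[0]:
        raise ValueError(f"OOF rows ({oof.shape[0]}) misaligned with features ({Xorig.shape[0]})")
    Xstack = np.hstack([oof, Xorig])
    if stack_learners is None:
        stack_learners = {
            "stack_linear": make_learner("linear", task, seed),
            "stack_gbt": make_learner("gbt", task, seed),
        }
    fitted = {}
    for name, learner in stack_learners.items():
        model = clone(learner)
        try:
            model.fit(Xstack, y, sample_weight=sample_weight)
        except TypeError:
            model.fit(Xstack, y)
        fitted[name] = model
    return fitted


def _val_loss(scores: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "classification":
        p = np.clip(scores, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((scores - y) ** 2))


def ensemble_selection(
    validation_preds: np.ndarray,
    validation_labels: np.ndarray,
    iters: int = 25,
    task: str = "classification",
) -> np.ndarray:
    """Greedy forward selection with replacement; returns weights summing to 1.

    ``validation_preds`` is (n_models, n_validation).  Each step adds the
    candidate whose inclusion minimizes validation loss (log loss for
    classification, squared error for regression) of the running average;
    a model may be picked repeatedly, so the final weights are the pick
    frequencies.  The selected blend's loss never exceeds the best single
    model's (the first pick is exactly that model).
    """
    P = np.atleast_2d(np.asarray(validation_preds, dtype=float))
    if P.shape[0] < 1 or P.size == 0:
        raise ValueError("need at least one candidate model")
    if not np.all(np.isfinite(P)):
        raise ValueError("validation predictions must be finite")
    y = np.asarray(validation_labels)
    counts = np.zeros(P.shape[0], dtype=int)
    running = np.zeros(P.shape[1])
    for step in range(iters):
        losses = [_val_loss((running + P[m]) / (step + 1), y, task) for m in range(P.shape[0])]
        pick = int(np.argmin(losses))  # ties: lowest index, deterministic
        counts[pick] += 1
        running = running + P[pick]
    return counts / counts.sum()


class StackingEnsemble(BaseEstimator):
    """Two-level stack + greedy selection, usable as a weight-accepting learner.

    ``fit`` carves a seeded validation split for ensemble selection, runs
    repeated k-fold bagging on the rest, trains the stacking layer, and
    blends the stacked models with the selected weights.
    """

    def __init__(self, config: StackConfig | None = None, task: str = "classification", seed: int = 0):
        self.config = config
        self.task = task
        self.seed = seed

    def fit(self, X, y, sample_weight=None):
        cfg = self.config or StackConfig(seed=self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(cfg.seed)
        n = len(y)
        # hold out ~20% for ensemble selection
        if self.task == "classification":
            order = []
            for c in np.unique(y):
                order.extend(rng.permutation(np.flatnonzero(y == c)).tolist())
            order = np.array(order)
        else:
            order = rng.permutation(n)
        n_val = max(2, n // 5)
        val_idx = order[:n_val]
        tr_idx = np.setdiff1d(np.arange(n), val_idx)

        w_tr = None if sample_weight is None else np.asarray(sample_weight)[tr_idx]
        learners = {name: make_learner(name, self.task, cfg.seed) for name in cfg.base_learners}
        oof = oof_predictions(
            learners, X[tr_idx], y[tr_idx], sample_weight=w_tr,
            k=cfg.bag_folds, repeats=cfg.bag_repeats, seed=cfg.seed, task=self.task,
        )
        self.stacked_ = fit_stack(oof, X[tr_idx], y[tr_idx], sample_weight=w_tr, task=self.task, seed=cfg.seed)
        # refit base learners on the full training part for inference-time features
        self.base_ = {}
        for name, learner in learners.items():
            model = clone(learner)
            try:
                model.fit(X[tr_idx], y[tr_idx], sample_weight=w_tr)
            except TypeError:
                model.fit(X[tr_idx], y[tr_idx])
            self.base_[name] = model

        val_preds = np.vstack([
            _predict_scores(m, self._stack_features(X[val_idx]), self.task) for m in self.stacked_.values()
        ])
        self.selection_weights_ = ensemble_selection(val_preds, y[val_idx], iters=cfg.selection_iters, task=self.task)
        self.classes_ = np.unique(y) if self.task == "classification" else None
        return self

    def _stack_features(self, X):
        base_scores = np.column_stack([_predict_scores(m, X, self.task) for m in self.base_.values()])
        return np.hstack([base_scores, X])

    def _blend(self, X):
        Xs = self._stack_features(np.asarray(X, dtype=float))
        preds = np.vstack([_predict_scores(m, Xs, self.task) for m in self.stacked_.values()])
        return self.selection_weights_ @ preds

    def predict_proba(self, X):
        p = np.clip(self._blend(X), 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        if self.task == "classification":
            return (self._blend(X) >= 0.5).astype(int)
        return self._blend(X)


class StackingEnsembleClassifier(StackingEnsemble, ClassifierMixin):
    def __init__(self, config: StackConfig | None = None, seed: int = 0):
        super().__init__(config=config, task="classification", seed=seed)


class StackingEnsembleRegressor(StackingEnsemble, RegressorMixin):
    def __init__(self, config: StackConfig | None = None, seed: int = 0):
        super().__init__(config=config, task="regression", seed=seed)
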