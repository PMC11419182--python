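"""The alpha-weighted empirical-risk objective and nested-CV alpha selection.

Given m labelled samples from a source group and n << m from a target
group, the weighted ERM objective

    (1-alpha)/m * sum_source NLL  +  alpha/n * sum_target NLL  +  Omega

interpolates between source-only training (alpha = 0) and target-only
training (alpha = 1); alpha = n/(m+n) recovers unweighted pooled training.
The weighting is realised as per-sample weights so any weight-accepting
learner (logistic/linear model, MLP, boosted trees, the stacking ensemble)
plugs in.  The candidate grid alpha = k/(k+1), k = 1..10, becomes finer as
alpha approaches 1; alpha is chosen by an inner stratified five-fold
cross-validation with target rows spread evenly across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, KFold

from cohortshift.evaluation import auc as _auc

PROB_CLIP = 1e-12


@dataclass
class AdaptationConfig:
    """Settings for one source -> target adaptation run."""

    alpha: float = 0.5
    alpha_grid: Sequence[float] = field(default_factory=lambda: alpha_grid())
    source_group: str | None = None
    target_group: str | None = None
    target_fraction: str = "10%"  # one of {"0%", "10%", "all"}
    regularization_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        g = np.asarray(list(self.alpha_grid), dtype=float)
        if g.size and (np.any(np.diff(g) <= 0) or np.any(g <= 0) or np.any(g > 1)):
            raise ValueError("alpha_grid must be strictly increasing with values in (0, 1]")
        if self.target_fraction not in ("0%", "10%", "all"):
            raise ValueError(f"target_fraction must be one of 0%/10%/all, got {self.target_fraction}")
        if self.target_fraction == "0%":
            self.alpha = 0.0
        if self.regularization_strength < 0:
            raise ValueError("regularization_strength must be >= 0")


@dataclass
class FitResult:
    """A trained predictor plus the provenance of its fit.

    ``model`` exposes the predictive law p_theta(y|x) through
    ``predict_proba`` (classification) or ``predict`` (regression).
    """

    model: object
    alpha: float
    task: str  # "classification" | "regression"
    seed: int
    m: int
    n: int
    cv_table: pd.DataFrame | None = None
    fold_provenance: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per row."""
        if self.task != "classification":
            raise ValueError("predict_proba is for classification fits")
        return self.model.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        if self.task == "classification":
            return self.predict_proba(X)
        return self.model.predict(X)


def alpha_grid(k_max: int = 10) -> np.ndarray:
    """The candidate grid alpha = k/(k+1), k = 1..k_max.

    The spacing 1/((k+1)(k+2)) shrinks with k, so the grid is finest close
    to alpha = 1 where the bound is most sensitive when the shift is large.
    """
    k = np.arange(1, k_max + 1, dtype=float)
    return k / (k + 1.0)


def sample_weights(m: int, n: int, alpha: float) -> np.ndarray:
    """Per-sample weights realising the weighted objective; sum to 1.

    First m entries (source) get (1-alpha)/m, last n (target) alpha/n.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if m < 1:
        raise ValueError("need m >= 1 source samples")
    if alpha > 0 and n < 1:
        raise ValueError("target samples required when alpha > 0")
    w_src = np.full(m, (1.0 - alpha) / m)
    w_tgt = np.full(max(n, 0), alpha / n if n else 0.0)
    return np.concatenate([w_src, w_tgt])


def weighted_nll(source_probs: np.ndarray, target_probs: np.ndarray, alpha: float) -> float:
    """The weighted objective for given per-sample probabilities of the true labels.

    ``source_probs`` / ``target_probs`` are p_theta(y_i | x_i) for each
    source / target training sample.  Probabilities are clipped at 1e-12
    before the log so degenerate learners yield a finite objective.
    """
    source_probs = np.asarray(source_probs, dtype=float)
    target_probs = np.asarray(target_probs, dtype=float)
    m, n = source_probs.size, target_probs.size
    if m < 1:
        raise ValueError("need m >= 1 source samples")
    if alpha > 0 and n < 1:
        raise ValueError("target samples required when alpha > 0")
    if np.any(source_probs > 1) or np.any(target_probs > 1) or np.any(source_probs < 0) or np.any(target_probs < 0):
        raise ValueError("probabilities must lie in [0, 1]")
    src = -np.log(np.clip(source_probs, PROB_CLIP, 1.0)).sum() / m
    tgt = -np.log(np.clip(target_probs, PROB_CLIP, 1.0)).sum() / n if n else 0.0
    return float((1.0 - alpha) * src + alpha * tgt)


def fit_weighted(
    learner,
    X_source: np.ndarray,
    y_source: np.ndarray,
    X_target: np.ndarray,
    y_target: np.ndarray,
    alpha: float,
    task: str = "classification",
    seed: int = 0,
) -> FitResult:
    """Train any weight-accepting learner under the weighted objective.

    The normalized weights (summing to 1) are rescaled by (m+n) before
    being handed to the learner so a uniformly weighted fit coincides
    exactly with an unweighted one (and regularization strengths keep their
    unweighted meaning); the rescaling is a uniform factor and does not
    change the minimizer of the data term.
    """
    X_source = np.asarray(X_source, float)
    X_target = np.asarray(X_target, float) if len(np.atleast_1d(y_target)) else np.empty((0, X_source.shape[1]))
    m, n = X_source.shape[0], X_target.shape[0]
    if alpha == 1.0:
        X, y, w = X_target, np.asarray(y_target), np.ones(n)
    elif alpha == 0.0 or n == 0:
        X, y, w = X_source, np.asarray(y_source), np.ones(m)
    else:
        X = np.vstack([X_source, X_target])
        y = np.concatenate([np.asarray(y_source), np.asarray(y_target)])
        w = sample_weights(m, n, alpha) * (m + n)
    model = clone(learner)
    try:
        model.fit(X, y, sample_weight=w)
    except TypeError as exc:  # pragma: no cover - depends on learner roster
        raise TypeError(f"learner {type(learner).__name__} does not accept sample weights") from exc
    return FitResult(model=model, alpha=alpha, task=task, seed=seed, m=m, n=n)


def _interleaved_folds(y, folds, seed, task):
    """Stratified fold indices (plain KFold on shuffled order for regression)."""
    y = np.asarray(y)
    if task == "classification":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(len(y)), y)]
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(y)))]


def select_alpha(
    learner,
    X_source: np.ndarray,
    y_source: np.ndarray,
    X_target: np.ndarray,
    y_target: np.ndarray,
    grid: Sequence[float] | None = None,
    task: str = "classification",
    folds: int = 5,
    seed: int = 0,
    include_zero: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Choose alpha by inner cross-validation over the candidate grid.

    Source and target rows are folded separately (stratified by label) and
    paired, so every inner fold carries an equal share of the scarce target
    data.  For each candidate alpha the model is fitted on the inner-train
    part and scored on the held-out target rows, pooling held-out
    predictions across the five folds into a single AUC (classification)
    or negative MAE (regression) — per-fold AUC over a handful of target
    rows is frequently undefined.  Ties return the smallest alpha
    (preferring more source data).  alpha = 0 is evaluated as the explicit
    source-only baseline row of the table but is never selected.

    Returns ``(alpha_chosen, cv_table)``.
    """
    grid = alpha_grid() if grid is None else np.asarray(list(grid), dtype=float)
    y_target = np.asarray(y_target)
    if len(y_target) < folds:
        raise ValueError(f"need >= {folds} target rows for {folds}-fold inner CV; reduce folds")

    src_folds = _interleaved_folds(y_source, folds, seed, task)
    tgt_folds = _interleaved_folds(y_target, folds, seed + 1, task)
    candidates = np.concatenate([[0.0], grid]) if include_zero else grid

    rows = []
    best_alpha, best_score = None, -np.inf
    for a in candidates:
        preds, truth = [], []
        for f in range(folds):
            src_val, tgt_val = src_folds[f], tgt_folds[f]
            src_tr = np.setdiff1d(np.arange(len(y_source)), src_val)
            tgt_tr = np.setdiff1d(np.arange(len(y_target)), tgt_val)
            fit = fit_weighted(
                learner,
                X_source[src_tr],
                np.asarray(y_source)[src_tr],
                X_target[tgt_tr],
                y_target[tgt_tr],
                alpha=float(a),
                task=task,
                seed=seed,
            )
            preds.append(fit.predict(X_target[tgt_val]))
            truth.append(y_target[tgt_val])
        preds = np.concatenate(preds)
        truth = np.concatenate(truth)
        if task == "classification":
            if len(np.unique(truth)) < 2:
                score = np.nan
            else:
                score = _auc(preds, truth)
        else:
            score = -float(np.mean(np.abs(preds - truth)))
        rows.append({"alpha": float(a), "score": score, "selectable": a > 0})
        if a > 0 and np.isfinite(score) and score > best_score + 1e-12:
            best_score, best_alpha = score, float(a)
    table = pd.DataFrame(rows)
    if best_alpha is None:
        best_alpha = float(grid[0])  # all scores tied/undefined: smallest candidate
    return best_alpha, table
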