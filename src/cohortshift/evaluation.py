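"""Nested cross-validation protocol, metrics, and fairness audit.

The outer protocol splits the target group into five label-stratified
folds.  In the "all" setting four folds train and one tests (the usual
five-fold loop).  In the "10%" setting the train set is all source data
plus 10% of the target group (half of the held-in fold), the test set is
the other four folds (80%); the remaining 10% stays unused, which keeps
the bookkeeping uniform across the hundreds of source/target pairs the
protocol is designed for.  In the "0%" setting the model never sees target
data and is scored once on the whole target group without test folds.

Metrics are AUC for classification and MAE (years, for brain age) for
regression, reported fold-wise as mean +/- sd; configurations are compared
with a paired t-test over outer-fold metrics.  The fairness audit reports
demographic parity difference (DPD) and equalized odds difference (EOD);
zero indicates a fair model under these metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold


@dataclass
class SplitPlan:
    """Row indices for one outer fold of the source -> target protocol."""

    fold: int
    source_train: np.ndarray
    target_train: np.ndarray
    test: np.ndarray
    unused: np.ndarray
    setting: str
    seed: int

    def check(self) -> None:
        train = np.concatenate([self.source_train, self.target_train])
        if np.intersect1d(train, self.test).size:
            raise AssertionError("train and test overlap")


def _target_folds(y, indices, n_splits, seed, task):
    y = np.asarray(y)
    if task == "classification":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [indices[test] for _, test in splitter.split(np.zeros(len(indices)), y[indices])]
    splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [indices[test] for _, test in splitter.split(np.zeros(len(indices)))]


def make_split_plan(
    group: np.ndarray,
    labels: np.ndarray,
    source_group: str,
    target_group: str,
    setting: str = "10%",
    seed: int = 0,
    task: str = "classification",
) -> list[SplitPlan]:
    """Build the outer split plans for one (source, target, setting) triple.

    Returns five plans ("10%" / "all") or a single fold-less plan ("0%").
    In the "10%" setting each plan holds floor(0.1 n) target-train rows,
    tests on the four complementary folds (~80%), and leaves the remainder
    of the held-in fold unused; the union of the five test sets covers the
    whole target group.
    """
    if setting not in ("0%", "10%", "all"):
        raise ValueError(f"setting must be one of 0%/10%/all, got {setting!r}")
    group = np.asarray(group).astype(str)
    labels = np.asarray(labels)
    src_idx = np.flatnonzero(group == str(source_group))
    tgt_idx = np.flatnonzero(group == str(target_group))
    if src_idx.size == 0 or tgt_idx.size == 0:
        raise ValueError("source or target group is empty")

    if setting == "0%":
        return [
            SplitPlan(
                fold=0,
                source_train=src_idx,
                target_train=np.array([], dtype=int),
                test=tgt_idx,
                unused=np.array([], dtype=int),
                setting=setting,
                seed=seed,
            )
        ]

    if task == "classification":
        _, counts = np.unique(labels[tgt_idx], return_counts=True)
        if counts.min() < 5:
            raise ValueError(f"target class counts {counts.tolist()} too small for 5 stratified folds")
    folds = _target_folds(labels, tgt_idx, 5, seed, task)

    plans = []
    n = tgt_idx.size
    rng = np.random.default_rng(seed)
    for f in range(5):
        held_in = folds[f]
        test = np.concatenate([folds[g] for g in range(5) if g != f])
        if setting == "all":
            plans.append(
                SplitPlan(
                    fold=f,
                    source_train=src_idx,
                    target_train=test,  # the four complementary folds (80%) train
                    test=held_in,
                    unused=np.array([], dtype=int),
                    setting=setting,
                    seed=seed,
                )
            )
            continue
        # "10%": half of the held-in fold trains, the rest is unused
        k = n // 10
        if task == "classification":
            order = _stratified_order(labels[held_in], rng)
        else:
            order = rng.permutation(held_in.size)
        tgt_train = held_in[order[:k]]
        unused = held_in[order[k:]]
        plans.append(
            SplitPlan(
                fold=f,
                source_train=src_idx,
                target_train=tgt_train,
                test=test,
                unused=unused,
                setting=setting,
                seed=seed,
            )
        )
    for p in plans:
        p.check()
    return plans


def _stratified_order(y, rng):
    """Permutation whose prefixes are approximately label-balanced."""
    y = np.asarray(y)
    buckets = [rng.permutation(np.flatnonzero(y == c)) for c in np.unique(y)]
    order = []
    i = 0
    while any(i < len(b) for b in buckets):
        for b in buckets:
            if i < len(b):
                order.append(b[i])
        i += 1
    return np.asarray(order, dtype=int)


def auc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative; ties 1/2."""
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mae(predicted: np.ndarray, true_values: np.ndarray) -> float:
    """Mean absolute error (years for brain-age models)."""
    predicted = np.asarray(predicted, dtype=float)
    true_values = np.asarray(true_values, dtype=float)
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.shape != true_values.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(predicted - true_values)))


def fairness_audit(
    predictions: np.ndarray,
    binary_labels: np.ndarray,
    sensitive_attribute: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Demographic parity difference and equalized odds difference.

    DPD = max_g P(yhat=1 | g) - min_g P(yhat=1 | g).
    EOD = max over y in {0,1} of the corresponding max-min gap of
    P(yhat=1 | Y=y, g) across groups.  Both lie in [0, 1]; zero indicates
    a fair model.  Continuous scores are thresholded at ``threshold``.
    A group empty at some Y stratum is skipped for that stratum.
    """
    yhat = (np.asarray(predictions, dtype=float) >= threshold).astype(int)
    y = np.asarray(binary_labels).astype(int)
    attr = np.asarray(sensitive_attribute).astype(str)
    groups = np.unique(attr)
    if groups.size < 2:
        raise ValueError("need >= 2 attribute groups")
    rates = [yhat[attr == g].mean() for g in groups]
    dpd = float(max(rates) - min(rates))

    eod = 0.0
    for yv in (0, 1):
        stratum_rates = []
        for g in groups:
            mask = (attr == g) & (y == yv)
            if mask.any():
                stratum_rates.append(yhat[mask].mean())
        if len(stratum_rates) >= 2:
            eod = max(eod, float(max(stratum_rates) - min(stratum_rates)))
    return dpd, eod


def compare_configurations(fold_metrics_a: np.ndarray, fold_metrics_b: np.ndarray) -> float:
    """Two-sided paired t-test p-value over outer-fold metrics."""
    a = np.asarray(fold_metrics_a, dtype=float)
    b = np.asarray(fold_metrics_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length fold-metric vectors of size >= 2")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class EvalReport:
    """Per-(source, target, setting) fold-wise results."""

    source_group: str
    target_group: str
    setting: str
    task: str
    fold_metrics: list[float]
    chosen_alphas: list[float]
    fairness: dict[str, tuple[float, float]] = field(default_factory=dict)
    fold_tables: list[pd.DataFrame] = field(default_factory=list)

    @property
    def metric_mean(self) -> float:
        return float(np.mean(self.fold_metrics))

    @property
    def metric_sd(self) -> float:
        # sd of the 5 fold metrics, not a pooled recomputation
        return float(np.std(self.fold_metrics, ddof=1)) if len(self.fold_metrics) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source_group,
                "target": self.target_group,
                "setting": self.setting,
                "fold": range(len(self.fold_metrics)),
                "metric": self.fold_metrics,
                "alpha": self.chosen_alphas if self.chosen_alphas else np.nan,
            }
        )


def evaluate_adaptation(
    cohort,
    learner,
    source_group: str,
    target_group: str,
    setting: str = "10%",
    task: str = "classification",
    select_alpha_by_cv: bool = True,
    alpha: float | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    sensitive_attributes: list[str] | None = None,
) -> EvalReport:
    """Run the full outer protocol for one (source, target, setting) triple.

    Per outer fold: fit the preprocessor on that fold's training rows only,
    choose alpha by inner cross-validation (unless ``alpha`` is fixed or the
    setting is "0%"), train under the weighted objective and score the test
    rows.  Returns fold-wise metrics, chosen alphas, and a fairness audit
    over the pooled test predictions.
    """
    from cohortshift.preprocess import Preprocessor
    from cohortshift.weighting import fit_weighted, select_alpha

    frame = cohort.frame
    plans = make_split_plan(
        cohort.group.to_numpy(),
        cohort.label.to_numpy(),
        source_group,
        target_group,
        setting=setting,
        seed=seed,
        task=task,
    )
    fold_metrics, alphas, tables = [], [], []
    pooled_scores, pooled_labels, pooled_idx = [], [], []
    for plan in plans:
        train_idx = np.concatenate([plan.source_train, plan.target_train])
        pp = Preprocessor().fit(frame.iloc[train_idx], cohort.feature_kinds)
        Xs = pp.transform(frame.iloc[plan.source_train]).to_numpy()
        ys = cohort.label.to_numpy()[plan.source_train]
        Xt = pp.transform(frame.iloc[plan.target_train]).to_numpy() if plan.target_train.size else np.empty((0, Xs.shape[1]))
        yt = cohort.label.to_numpy()[plan.target_train]
        Xtest = pp.transform(frame.iloc[plan.test]).to_numpy()
        ytest = cohort.label.to_numpy()[plan.test]

        if setting == "0%" or plan.target_train.size == 0:
            a, table = 0.0, None
        elif alpha is not None or not select_alpha_by_cv:
            a, table = (alpha if alpha is not None else 0.5), None
        else:
            a, table = select_alpha(
                learner, Xs, ys, Xt, yt, task=task, folds=inner_folds, seed=seed + plan.fold
            )
        fit = fit_weighted(learner, Xs, ys, Xt, yt, alpha=a, task=task, seed=seed)
        scores = fit.predict(Xtest)
        metric = auc(scores, ytest) if task == "classification" else mae(scores, ytest)
        fold_metrics.append(metric)
        alphas.append(a)
        if table is not None:
            tables.append(table)
        pooled_scores.append(scores)
        pooled_labels.append(ytest)
        pooled_idx.append(plan.test)

    fairness = {}
    if sensitive_attributes and task == "classification":
        sc = np.concatenate(pooled_scores)
        lb = np.concatenate(pooled_labels)
        ix = np.concatenate(pooled_idx)
        for attr in sensitive_attributes:
            vals = frame[attr].to_numpy()[ix]
            fairness[attr] = fairness_audit(sc, lb, vals)

    return EvalReport(
        source_group=source_group,
        target_group=target_group,
        setting=setting,
        task=task,
        fold_metrics=fold_metrics,
        chosen_alphas=alphas,
        fairness=fairness,
        fold_tables=tables,
    )
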