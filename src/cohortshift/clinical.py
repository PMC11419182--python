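"""Downstream clinical procedures built on the adapted predictors.

(a) MCI progression: an AD-vs-CN classifier applied to baseline MCI
subjects yields an (uncalibrated) AD probability; a one-dimensional linear
discriminant analysis on that probability, trained on 20% of the
retrospectively created pMCI/sMCI/nMCI labels and tested on the rest in a
five-fold rotation, separates progressors from stable/reverting subjects.

(b) Brain-age residuals: BAR = predicted age - chronological age; a
positive BAR suggests accelerated aging.  Pearson correlations between BAR
and neuropsychological or cardiovascular variables are reported with
two-sided p-values (t-transform of r) and a significance flag at p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from cohortshift.evaluation import auc


@dataclass
class ProgressionResult:
    """Per class-pair progression AUCs and the fitted 1-D LDA parameters."""

    pair: tuple[str, str]
    fold_aucs: list[float]
    lda_means: tuple[float, float]  # class means on the probability axis (last fold)
    lda_pooled_var: float
    lda_priors: tuple[float, float]
    skipped_folds: int = 0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0

    def boundary(self) -> float:
        """Decision boundary of the 1-D LDA; the class-mean midpoint under equal priors."""
        mu0, mu1 = self.lda_means
        p0, p1 = self.lda_priors
        if np.isclose(mu0, mu1):
            raise ValueError("degenerate LDA: equal class means")
        # solve the linear discriminant equality for the 1-D pooled-variance model
        return float(0.5 * (mu0 + mu1) + self.lda_pooled_var * np.log(p0 / p1) / (mu1 - mu0))


def lda_progression(
    ad_probabilities: np.ndarray,
    progression_labels: np.ndarray,
    pair: tuple[str, str] = ("pMCI", "sMCI"),
    folds: int = 5,
    label_fraction: float = 0.2,
    seed: int = 0,
) -> ProgressionResult:
    """Two-class LDA on the AD-probability covariate for one progression pair.

    Each of the ``folds`` stratified folds serves once as the training
    fraction (~``label_fraction`` of the labelled rows); the complementary
    rows are the test set.  Folds whose training part misses a class are
    skipped with a warning.  Uses pooled within-class variance and
    empirical priors.
    """
    probs = np.asarray(ad_probabilities, dtype=float)
    labels = np.asarray(progression_labels, dtype=object).astype(str)
    mask = np.isin(labels, list(pair))
    x = probs[mask]
    y = (labels[mask] == pair[0]).astype(int)  # 1 = first class of the pair (pMCI)
    if len(np.unique(y)) < 2:
        raise ValueError(f"both classes of {pair} must be present")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs, skipped = [], 0
    lda_params = None
    for _, train_idx in splitter.split(np.zeros(len(y)), y):  # each fold = the 20% train part
        test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("fold skipped: a progression class is absent from the training fraction")
            skipped += 1
            continue
        if np.std(x[train_idx]) == 0:
            # degenerate covariate: LDA undefined, fall back to prior scores
            scores = np.full(len(test_idx), y[train_idx].mean())
        else:
            lda = LinearDiscriminantAnalysis()
            lda.fit(x[train_idx, None], y[train_idx])
            scores = lda.predict_proba(x[test_idx, None])[:, 1]
        if len(np.unique(y[test_idx])) < 2:
            skipped += 1
            continue
        fold_aucs.append(auc(scores, y[test_idx]))
        x0, x1 = x[train_idx][y[train_idx] == 0], x[train_idx][y[train_idx] == 1]
        pooled = ((len(x0) - 1) * x0.var(ddof=1) + (len(x1) - 1) * x1.var(ddof=1)) / (len(x0) + len(x1) - 2)
        lda_params = (
            (float(x0.mean()), float(x1.mean())),
            float(pooled),
            (len(x0) / len(train_idx), len(x1) / len(train_idx)),
        )
    if not fold_aucs:
        raise ValueError("no usable folds")
    return ProgressionResult(
        pair=pair,
        fold_aucs=fold_aucs,
        lda_means=lda_params[0],
        lda_pooled_var=lda_params[1],
        lda_priors=lda_params[2],
        skipped_folds=skipped,
    )


@dataclass
class BARTable:
    """Per-subject brain-age residuals plus per-variable correlations."""

    table: pd.DataFrame  # columns: predicted_age, chronological_age, bar
    dropped_rows: int = 0
    correlations: pd.DataFrame | None = None

    @property
    def bar(self) -> np.ndarray:
        return self.table["bar"].to_numpy()

    def summary(self) -> dict:
        return {"mean_bar": float(self.bar.mean()), "sd_bar": float(self.bar.std(ddof=1)), "n": len(self.table)}


def brain_age_residuals(predicted_ages: np.ndarray, chronological_ages: np.ndarray) -> BARTable:
    """BAR = predicted - chronological age (years); rows with missing age dropped."""
    pred = np.asarray(predicted_ages, dtype=float)
    chrono = np.asarray(chronological_ages, dtype=float)
    if pred.shape != chrono.shape:
        raise ValueError("length mismatch")
    ok = ~np.isnan(chrono) & ~np.isnan(pred)
    if (chrono[ok] <= 0).any():
        raise ValueError("chronological ages must be positive")
    table = pd.DataFrame(
        {
            "predicted_age": pred[ok],
            "chronological_age": chrono[ok],
            "bar": pred[ok] - chrono[ok],
        }
    )
    return BARTable(table=table, dropped_rows=int((~ok).sum()))


def bar_correlations(
    bar_table: BARTable,
    clinical_vars: pd.DataFrame,
    significance_level: float = 0.01,
) -> BARTable:
    """Pearson r between BAR and each clinical variable over observed pairs.

    Rows of ``clinical_vars`` align with the BAR table.  Variables with
    fewer than 3 observed pairs or zero variance are reported as missing
    with a reason.  p-values are two-sided via the exact t-transform of r.
    """
    bar = bar_table.bar
    if len(clinical_vars) != len(bar):
        raise ValueError("clinical variable table must align with the BAR table rows")
    rows = []
    for col in clinical_vars.columns:
        v = clinical_vars[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        n = int(ok.sum())
        if n < 3:
            rows.append({"variable": col, "r": np.nan, "p": np.nan, "n": n,
                         "significant": False, "note": "fewer than 3 observed pairs"})
            continue
        if np.std(v[ok]) == 0 or np.std(bar[ok]) == 0:
            rows.append({"variable": col, "r": np.nan, "p": np.nan, "n": n,
                         "significant": False, "note": "constant variable"})
            continue
        r, p = stats.pearsonr(bar[ok], v[ok])
        rows.append({"variable": col, "r": float(r), "p": float(p), "n": n,
                     "significant": bool(p < significance_level), "note": ""})
    bar_table.correlations = pd.DataFrame(rows)
    return bar_table
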