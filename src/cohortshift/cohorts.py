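"""Synthetic multi-group clinical cohorts with controlled distribution shift.

Real consortium feature tables (ROI volumes, WML volume, demographics,
cognitive scores) are access-restricted, so every downstream stage of the
package is exercised on synthetic cohorts that emulate their structure:
multiple population groups whose numeric features are drawn from
group-shifted Gaussians (with optional log-normal columns to exercise
quantile normalization), group-dependent label models (logistic for
diagnosis, linear for age), sparse missingness in non-imaging columns,
class imbalance, and cross-sectionally simulated MCI-progression labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

PROGRESSION_CLASSES = ("pMCI", "sMCI", "nMCI")


class CohortValidationError(ValueError):
    """A CohortSpec field violates its invariant."""


@dataclass(frozen=True)
class GroupLabelModel:
    """Per-group label model: logistic (binary) or linear (continuous).

    ``coef`` acts on the group's numeric features; ``intercept`` shifts the
    linear predictor; ``noise_sd`` is Gaussian noise added to continuous
    labels (ignored for logistic labels).
    """

    coef: np.ndarray
    intercept: float = 0.0
    kind: str = "logistic"  # "logistic" | "linear"
    noise_sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=float))
        if self.kind not in ("logistic", "linear"):
            raise CohortValidationError(f"label model kind must be logistic or linear, got {self.kind!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic multi-group cohort.

    Parameters
    ----------
    n_per_group
        Subject counts per group, e.g. ``{"A": 500, "B": 50}``. All >= 1.
    n_numeric
        Number of numeric feature columns (defaults emulate a reduced set
        of regional brain volumes plus clinical covariates).
    n_categorical
        Category lists per categorical column, e.g. ``{"sex": ["M", "F"]}``.
    shift_vector
        Per-group additive mean offset (length ``n_numeric``), in feature
        units (features have unit variance before shift/scale).
    shift_scale
        Per-group multiplicative scale on the feature covariance.
    label_model
        Per-group :class:`GroupLabelModel`.
    lognormal_columns
        Indices of numeric columns transformed to a log-normal (skewed)
        marginal, to exercise quantile normalization downstream.
    missing_rate
        Default per-column missingness probability in [0, 1] applied by
        :func:`inject_missingness` when no per-column map is given.
    class_balance
        Target positive fraction in (0, 1) for logistic labels; realised by
        calibrating each group's intercept on the sampled linear predictor.
        ``None`` leaves the stated intercepts untouched.
    """

    n_per_group: Mapping[str, int]
    n_numeric: int = 20
    n_categorical: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"sex": ["M", "F"], "apoe4": ["0", "1", "2"]}
    )
    shift_vector: Mapping[str, np.ndarray] | None = None
    shift_scale: Mapping[str, float] | None = None
    label_model: Mapping[str, GroupLabelModel] | None = None
    lognormal_columns: Sequence[int] = ()
    missing_rate: float = 0.0
    class_balance: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group:
            raise CohortValidationError("n_per_group: at least one group is required")
        for g, n in self.n_per_group.items():
            if int(n) < 1:
                raise CohortValidationError(f"n_per_group[{g!r}]: counts must be >= 1, got {n}")
        if self.n_numeric < 1:
            raise CohortValidationError(f"n_numeric: must be >= 1, got {self.n_numeric}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise CohortValidationError(f"missing_rate: must be in [0, 1], got {self.missing_rate}")
        if self.class_balance is not None and not (0.0 < self.class_balance < 1.0):
            raise CohortValidationError(f"class_balance: must be in (0, 1), got {self.class_balance}")
        for idx in self.lognormal_columns:
            if not (0 <= idx < self.n_numeric):
                raise CohortValidationError(f"lognormal_columns: index {idx} out of range")
        if self.shift_vector is not None:
            for g, v in self.shift_vector.items():
                if len(np.atleast_1d(v)) not in (1, self.n_numeric):
                    raise CohortValidationError(
                        f"shift_vector[{g!r}]: length must be 1 or n_numeric={self.n_numeric}"
                    )


@dataclass
class GroupedCohort:
    """A feature table with group assignments and labels; the universal input.

    ``frame`` holds one row per subject.  ``feature_kinds`` maps each
    feature column to ``"numeric"`` or ``"categorical"``; ``categories``
    lists the declared category set of each categorical column.  ``group``
    is the stratification column used for source/target roles;
    ``attribute_labels`` names extra stratification columns (sex, age band,
    race, study) used by the shift-quantification stage.
    """

    frame: pd.DataFrame
    feature_kinds: dict[str, str]
    group_col: str = "group"
    label_col: str = "label"
    categories: dict[str, list[str]] = field(default_factory=dict)
    attribute_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.group_col not in self.frame.columns:
            raise CohortValidationError(f"group column {self.group_col!r} missing from frame")
        if self.label_col not in self.frame.columns:
            raise CohortValidationError(f"label column {self.label_col!r} missing from frame")
        if self.frame[self.label_col].isna().any():
            raise CohortValidationError("label must be present for every subject")
        for col, cats in self.categories.items():
            observed = self.frame[col].dropna()
            bad = set(observed) - set(cats)
            if bad:
                raise CohortValidationError(f"column {col!r} contains undeclared categories {sorted(bad)}")

    @property
    def feature_columns(self) -> list[str]:
        return list(self.feature_kinds)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def group(self) -> pd.Series:
        return self.frame[self.group_col]

    @property
    def label(self) -> pd.Series:
        return self.frame[self.label_col]

    def subset(self, mask) -> "GroupedCohort":
        return GroupedCohort(
            frame=self.frame.loc[mask].reset_index(drop=True),
            feature_kinds=dict(self.feature_kinds),
            group_col=self.group_col,
            label_col=self.label_col,
            categories={k: list(v) for k, v in self.categories.items()},
            attribute_labels=list(self.attribute_labels),
        )

    def copy(self) -> "GroupedCohort":
        return GroupedCohort(
            frame=self.frame.copy(),
            feature_kinds=dict(self.feature_kinds),
            group_col=self.group_col,
            label_col=self.label_col,
            categories={k: list(v) for k, v in self.categories.items()},
            attribute_labels=list(self.attribute_labels),
        )

    # -- plain-text persistence: CSV table + JSON sidecar ------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV (missing cells empty) plus a ``.json`` sidecar."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = {
            "feature_kinds": self.feature_kinds,
            "group_col": self.group_col,
            "label_col": self.label_col,
            "categories": self.categories,
            "attribute_labels": self.attribute_labels,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupedCohort":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cat_cols = [c for c, k in meta["feature_kinds"].items() if k == "categorical"]
        frame = pd.read_csv(path, dtype={c: str for c in cat_cols})
        return cls(
            frame=frame,
            feature_kinds=meta["feature_kinds"],
            group_col=meta["group_col"],
            label_col=meta["label_col"],
            categories=meta["categories"],
            attribute_labels=meta["attribute_labels"],
        )


def _group_shift(spec: CohortSpec, group: str) -> np.ndarray:
    if spec.shift_vector is None or group not in spec.shift_vector:
        return np.zeros(spec.n_numeric)
    return np.broadcast_to(np.atleast_1d(np.asarray(spec.shift_vector[group], float)), (spec.n_numeric,)).copy()


def _group_scale(spec: CohortSpec, group: str) -> float:
    if spec.shift_scale is None or group not in spec.shift_scale:
        return 1.0
    return float(spec.shift_scale[group])


def _default_label_model(spec: CohortSpec, rng: np.random.Generator) -> GroupLabelModel:
    # moderate signal on the first few features; shared across groups unless overridden
    coef = np.zeros(spec.n_numeric)
    k = min(5, spec.n_numeric)
    coef[:k] = 1.0
    return GroupLabelModel(coef=coef, intercept=0.0, kind="logistic")


def generate_cohort(spec: CohortSpec) -> GroupedCohort:
    """Draw a multi-group cohort from the spec; no missingness yet.

    Numeric features are standard Gaussian per group, shifted by the
    group's ``shift_vector`` and scaled by ``shift_scale``; columns listed
    in ``lognormal_columns`` are exponentiated to give skewed marginals.
    Labels follow each group's label model.  Identical ``(spec, seed)``
    gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    default_model = _default_label_model(spec, rng)

    frames = []
    for group in spec.n_per_group:
        n = int(spec.n_per_group[group])
        shift = _group_shift(spec, group)
        scale = _group_scale(spec, group)
        X = rng.standard_normal((n, spec.n_numeric)) * scale + shift

        model = default_model
        if spec.label_model is not None and group in spec.label_model:
            model = spec.label_model[group]
        eta = X @ model.coef + model.intercept
        if model.kind == "logistic":
            if spec.class_balance is not None:
                eta = eta - eta.mean() + _balance_intercept(eta - eta.mean(), spec.class_balance)
            p = 1.0 / (1.0 + np.exp(-eta))
            y = (rng.uniform(size=n) < p).astype(int)
        else:
            y = eta + rng.standard_normal(n) * model.noise_sd

        Xout = X.copy()
        for idx in spec.lognormal_columns:
            Xout[:, idx] = np.exp(Xout[:, idx])

        cols = {f"x{j:03d}": Xout[:, j] for j in range(spec.n_numeric)}
        for cname, cats in spec.n_categorical.items():
            cols[cname] = rng.choice(list(cats), size=n)
        cols["group"] = group
        cols["label"] = y
        frames.append(pd.DataFrame(cols))

    frame = pd.concat(frames, ignore_index=True)
    feature_kinds = {f"x{j:03d}": "numeric" for j in range(spec.n_numeric)}
    feature_kinds.update({c: "categorical" for c in spec.n_categorical})
    return GroupedCohort(
        frame=frame,
        feature_kinds=feature_kinds,
        categories={c: list(v) for c, v in spec.n_categorical.items()},
        attribute_labels=[c for c in spec.n_categorical],
    )


def _balance_intercept(eta_centered: np.ndarray, target: float) -> float:
    """Intercept b such that mean sigmoid(eta + b) == target (bisection)."""
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(eta_centered + mid)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def inject_missingness(
    cohort: GroupedCohort,
    missing_rate_by_column: Mapping[str, float],
    seed: int = 0,
) -> GroupedCohort:
    """Set cells to missing independently (MCAR) at per-column rates.

    The group and label columns may not be masked.  The input cohort is
    left unmodified.
    """
    for col, rate in missing_rate_by_column.items():
        if not (0.0 <= rate <= 1.0):
            raise CohortValidationError(f"missing rate for {col!r} must be in [0, 1], got {rate}")
        if col in (cohort.group_col, cohort.label_col):
            raise CohortValidationError(f"column {col!r} (group/label) may not be masked")
        if col not in cohort.feature_kinds:
            raise CohortValidationError(f"unknown column {col!r}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    n = len(out.frame)
    for col, rate in missing_rate_by_column.items():
        mask = rng.uniform(size=n) < rate
        if out.feature_kinds[col] == "categorical":
            vals = out.frame[col].astype("object")
            vals[mask] = np.nan
            out.frame[col] = vals
        else:
            vals = out.frame[col].to_numpy(dtype=float, copy=True)
            vals[mask] = np.nan
            out.frame[col] = vals
    return out


def make_progression_labels(
    cohort: GroupedCohort,
    progression_coef: np.ndarray,
    class_priors: Mapping[str, float] | None = None,
    flag_col: str | None = None,
    seed: int = 0,
) -> GroupedCohort:
    """Assign pMCI/sMCI/nMCI labels to the flagged intermediate stratum.

    A latent severity score ``s = x @ progression_coef`` (aligned with the
    AD direction of the label model) tilts the class probabilities: each
    flagged subject draws its class from softmax of per-class logits
    ``b_c + w_c * s`` with ordered tilts w_pMCI > w_sMCI > w_nMCI, so
    subjects who look more AD-like are more likely to progress.  The
    intercepts ``b_c`` are calibrated by iterative proportional fitting so
    the marginal class frequencies match ``class_priors``.  When the
    per-class scores are all equal (zero coef, uniform priors) assignment
    is uniform.

    ``flag_col`` names a boolean column marking the MCI stratum; ``None``
    flags every subject.  Adds a ``progression`` column; other columns are
    untouched.
    """
    if class_priors is None:
        class_priors = {"pMCI": 1 / 3, "sMCI": 1 / 3, "nMCI": 1 / 3}
    priors = np.array([class_priors[c] for c in PROGRESSION_CLASSES], dtype=float)
    priors = priors / priors.sum()

    if flag_col is None:
        flagged = np.ones(len(cohort.frame), dtype=bool)
    else:
        flagged = cohort.frame[flag_col].astype(bool).to_numpy()
    if not flagged.any():
        raise CohortValidationError("no flagged subjects to label")

    numeric_cols = [c for c, k in cohort.feature_kinds.items() if k == "numeric"]
    X = cohort.frame.loc[flagged, numeric_cols].to_numpy(dtype=float)
    coef = np.asarray(progression_coef, dtype=float)
    if coef.shape[0] != X.shape[1]:
        raise CohortValidationError(
            f"progression_coef length {coef.shape[0]} != number of numeric features {X.shape[1]}"
        )
    s = X @ coef
    if s.std() > 0:
        s = (s - s.mean()) / s.std()

    # ordered tilts: pMCI most AD-like, nMCI least
    tilts = np.array([1.0, 0.0, -1.0])
    logits = np.outer(s, tilts)
    b = np.log(priors)
    for _ in range(200):  # IPF on the intercepts so marginals hit the priors
        P = _softmax(logits + b)
        marg = P.mean(axis=0)
        b = b + np.log(priors / np.maximum(marg, 1e-300))
        b = b - b.max()
    P = _softmax(logits + b)

    rng = np.random.default_rng(seed)
    u = rng.uniform(size=P.shape[0])
    cum = np.cumsum(P, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = np.array(PROGRESSION_CLASSES)[idx]

    out = cohort.copy()
    col = np.full(len(out.frame), None, dtype=object)
    col[flagged] = labels
    out.frame["progression"] = col
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def adaptation_benchmark_spec(
    m: int = 1000,
    n: int = 200,
    n_numeric: int = 15,
    seed: int = 0,
) -> CohortSpec:
    """Two-group benchmark condition with a moderate source -> target shift.

    The source group ("source") carries a diagnostic signal on the first
    five numeric features; the target group ("target") combines a 0.5-sigma
    covariate shift on those features with a partially rotated label model
    (part of the signal moves onto other features and one coefficient flips
    sign), emulating a population whose diagnostic signature overlaps with
    but differs from the source's.  A source-only model transfers with
    degraded accuracy, and a small amount of target data recovers much of
    it — the regime the weighted objective is designed for.  Labels are
    balanced within each group.
    """
    if n_numeric < 6:
        raise CohortValidationError("benchmark condition needs n_numeric >= 6")
    coef_src = np.zeros(n_numeric)
    coef_src[:5] = 1.0
    coef_tgt = coef_src.copy()
    theta = np.pi / 3
    coef_tgt[0] = np.cos(theta)
    coef_tgt[5] = 2.0 * np.sin(theta)
    coef_tgt[1] = -1.0
    shift = np.zeros(n_numeric)
    shift[:5] = 0.5
    return CohortSpec(
        n_per_group={"source": m, "target": n},
        n_numeric=n_numeric,
        shift_vector={"target": shift},
        label_model={
            "source": GroupLabelModel(coef=coef_src),
            "target": GroupLabelModel(coef=coef_tgt),
        },
        class_balance=0.5,
        seed=seed,
    )
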