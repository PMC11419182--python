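"""Feature pipeline for sparse clinical tables, fitted on training rows only.

Continuous features: median imputation, then z-scoring to zero mean and
unit variance (population convention, divide by n); columns whose sample
skewness exceeds a threshold are instead quantile-normalized to standard
normal scores.  Discrete features: an explicit "unknown" category absorbs
both missing entries and categories unseen at fit time, and columns are
one-hot encoded.  For each feature that had any missing value at fit time
an additional binary indicator column records whether the entry was
missing.  No batch or site harmonization is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

UNKNOWN = "__unknown__"

#: default |sample skewness| above which a column is quantile-normalized
SKEW_THRESHOLD = 1.0


class SchemaError(ValueError):
    """Transform input does not match the fitted schema."""


@dataclass
class _NumericState:
    median: float
    center: float
    scale: float  # population sd; 1.0 when constant
    constant: bool
    skewed: bool
    # quantile map: sorted observed training values -> normal scores
    q_values: list[float] = field(default_factory=list)
    q_scores: list[float] = field(default_factory=list)


@dataclass
class Preprocessor:
    """Fit on training rows; transform is a pure function of (state, rows).

    The state never sees held-out rows, which is the leakage contract the
    nested cross-validation protocol depends on.
    """

    skew_threshold: float = SKEW_THRESHOLD
    numeric_cols: list[str] = field(default_factory=list)
    categorical_cols: list[str] = field(default_factory=list)
    numeric_state: dict[str, _NumericState] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)
    indicator_cols: list[str] = field(default_factory=list)
    fitted: bool = False

    def fit(self, rows: pd.DataFrame, feature_kinds: dict[str, str]) -> "Preprocessor":
        if len(rows) < 2:
            raise ValueError("at least 2 training rows are required")
        self.numeric_cols = [c for c, k in feature_kinds.items() if k == "numeric"]
        self.categorical_cols = [c for c, k in feature_kinds.items() if k == "categorical"]
        self.numeric_state = {}
        self.categories = {}
        self.indicator_cols = []

        for col in self.numeric_cols:
            v = rows[col].to_numpy(dtype=float)
            obs = v[~np.isnan(v)]
            if obs.size == 0:
                raise ValueError(f"numeric column {col!r} is fully missing in the training rows")
            med = float(np.median(obs))
            imputed = np.where(np.isnan(v), med, v)
            constant = bool(np.all(imputed == imputed[0]))
            skewed = False
            state = _NumericState(median=med, center=0.0, scale=1.0, constant=constant, skewed=False)
            if not constant:
                g1 = float(stats.skew(imputed, bias=True))
                skewed = abs(g1) > self.skew_threshold
            if skewed:
                state.skewed = True
                ranks = stats.rankdata(imputed, method="average")
                scores = stats.norm.ppf((ranks - 0.5) / imputed.size)
                order = np.argsort(imputed, kind="stable")
                # collapse ties so the map is a function of the value
                sv, si = np.unique(imputed[order], return_index=True)
                state.q_values = imputed[order][si].tolist()
                state.q_scores = scores[order][si].tolist()
                state.center, state.scale = 0.0, 1.0
            elif not constant:
                state.center = float(imputed.mean())
                state.scale = float(imputed.std(ddof=0))  # population convention
            self.numeric_state[col] = state
            if np.isnan(v).any():
                self.indicator_cols.append(col)

        for col in self.categorical_cols:
            v = rows[col]
            observed = sorted({str(x) for x in v.dropna().tolist()})
            self.categories[col] = observed + [UNKNOWN]
            if v.isna().any():
                self.indicator_cols.append(col)

        self.fitted = True
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Return the numeric design matrix (one-hot categoricals, indicators appended)."""
        if not self.fitted:
            raise SchemaError("Preprocessor is not fitted")
        missing_cols = [c for c in self.numeric_cols + self.categorical_cols if c not in rows.columns]
        if missing_cols:
            raise SchemaError(f"rows are missing fitted columns {missing_cols}")

        out: dict[str, np.ndarray] = {}
        for col in self.numeric_cols:
            st = self.numeric_state[col]
            v = rows[col].to_numpy(dtype=float)
            was_missing = np.isnan(v)
            imputed = np.where(was_missing, st.median, v)
            if st.constant:
                out[col] = np.zeros_like(imputed)
            elif st.skewed:
                out[col] = np.interp(imputed, st.q_values, st.q_scores)
            else:
                out[col] = (imputed - st.center) / st.scale
            if col in self.indicator_cols:
                out[f"{col}__missing"] = was_missing.astype(float)

        for col in self.categorical_cols:
            cats = self.categories[col]
            raw = rows[col]
            vals = raw.astype("object").where(~raw.isna(), UNKNOWN)
            vals = vals.map(lambda x: str(x) if str(x) in cats else UNKNOWN)
            for cat in cats:
                out[f"{col}={cat}"] = (vals == cat).to_numpy(dtype=float)
            if col in self.indicator_cols:
                out[f"{col}__missing"] = raw.isna().to_numpy(dtype=float)

        return pd.DataFrame(out, index=rows.index)

    def fit_transform(self, rows: pd.DataFrame, feature_kinds: dict[str, str]) -> pd.DataFrame:
        return self.fit(rows, feature_kinds).transform(rows)

    # -- JSON round-trip for exact reuse across folds ----------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "skew_threshold": self.skew_threshold,
            "numeric_cols": self.numeric_cols,
            "categorical_cols": self.categorical_cols,
            "numeric_state": {
                c: {
                    "median": s.median,
                    "center": s.center,
                    "scale": s.scale,
                    "constant": s.constant,
                    "skewed": s.skewed,
                    "q_values": s.q_values,
                    "q_scores": s.q_scores,
                }
                for c, s in self.numeric_state.items()
            },
            "categories": self.categories,
            "indicator_cols": self.indicator_cols,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Preprocessor":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        pp = cls(
            skew_threshold=payload.get("skew_threshold", SKEW_THRESHOLD),
            numeric_cols=payload["numeric_cols"],
            categorical_cols=payload["categorical_cols"],
            categories=payload["categories"],
            indicator_cols=payload["indicator_cols"],
        )
        pp.numeric_state = {c: _NumericState(**s) for c, s in payload["numeric_state"].items()}
        pp.fitted = True
        return pp
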