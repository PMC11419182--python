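"""Distribution-shift quantification between population groups.

A maximum mean discrepancy (MMD) two-sample statistic is computed on
features learned by a shared multi-head MLP trained to predict group
membership for each stratification attribute (sex, age band, race, study).
The trunk embedding serves as the canonical feature map phi, the kernel is
the inner product k(x, x') = <phi(x), phi(x')>, and the unbiased U-statistic
estimator of MMD^2 (which may be negative) is attached a permutation
p-value.  Pairwise group matrices feed an average-linkage dendrogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from cohortshift._mlp import MultiHeadMLP

Kernel = Callable[[np.ndarray, np.ndarray], np.ndarray]


def linear_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gram matrix of inner products; the RKHS reading of a learned feature map."""
    return np.asarray(X, float) @ np.asarray(Y, float).T


def rbf_kernel(bandwidth: float = 1.0) -> Kernel:
    """Gaussian kernel on the (learned) feature space; non-default option."""

    def k(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        X, Y = np.asarray(X, float), np.asarray(Y, float)
        sq = (X * X).sum(1)[:, None] + (Y * Y).sum(1)[None, :] - 2 * X @ Y.T
        return np.exp(-sq / (2.0 * bandwidth**2))

    return k


def _check_pair(Xp, Xq):
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xp.shape[1] != Xq.shape[1]:
        raise ValueError(f"dimension mismatch: {Xp.shape[1]} vs {Xq.shape[1]}")
    if Xp.shape[0] != Xq.shape[0]:
        raise ValueError("the unbiased estimator requires equal sample counts; subsample first")
    if Xp.shape[0] < 2:
        raise ValueError("need n >= 2 samples per side")
    return Xp, Xq


def mmd2_unbiased(features_p: np.ndarray, features_q: np.ndarray, kernel: Kernel = linear_kernel) -> float:
    """Unbiased MMD^2 U-statistic for equal sample counts n per side.

    (1/(n^2-n)) * sum_{i != j} [k(x_i,x_j) + k(x'_i,x'_j)
                                - k(x_i,x'_j) - k(x_j,x'_i)].

    Unbiasedness means the value can be negative; identical inputs give
    exactly zero.
    """
    Xp, Xq = _check_pair(features_p, features_q)
    n = Xp.shape[0]
    Kpp = kernel(Xp, Xp)
    Kqq = kernel(Xq, Xq)
    Kpq = kernel(Xp, Xq)
    off_pp = Kpp.sum() - np.trace(Kpp)
    off_qq = Kqq.sum() - np.trace(Kqq)
    off_pq = Kpq.sum() - np.trace(Kpq)
    return float((off_pp + off_qq - 2.0 * off_pq) / (n * n - n))


def permutation_test(
    features_p: np.ndarray,
    features_q: np.ndarray,
    kernel: Kernel = linear_kernel,
    B: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the MMD^2 statistic.

    Pools the 2n feature vectors, reassigns group membership B times
    preserving group sizes, and reports
    p = (1 + #{permuted >= observed}) / (1 + B), so p >= 1/(B+1).
    """
    if B < 1:
        raise ValueError("B >= 1 permutations required")
    Xp, Xq = _check_pair(features_p, features_q)
    n = Xp.shape[0]
    pooled = np.vstack([Xp, Xq])
    K = kernel(pooled, pooled)
    diag = np.diag(K)

    def stat_from(idx_p: np.ndarray, idx_q: np.ndarray) -> float:
        s = np.zeros(2 * n)
        s[idx_p] = 1.0
        Ks = K @ s
        tot_p = s @ Ks
        tot_pq = Ks.sum() - tot_p  # s' K (1-s)
        sq = 1.0 - s
        tot_q = sq @ (K @ sq)
        off_pp = tot_p - diag[idx_p].sum()
        off_qq = tot_q - diag[idx_q].sum()
        cross_diag = K[idx_p, idx_q].sum()  # paired terms k(x_i, x'_i)
        off_pq = tot_pq - cross_diag
        return float((off_pp + off_qq - 2.0 * off_pq) / (n * n - n))

    observed = stat_from(np.arange(n), np.arange(n, 2 * n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(2 * n)
        if stat_from(perm[:n], perm[n:]) >= observed:
            count += 1
    p = (1 + count) / (1 + B)
    return observed, p


@dataclass
class FeatureMap:
    """Trained shared-trunk multi-head group classifier.

    ``phi`` (the ``features`` method of the network) is deterministic given
    the parameters, and the induced linear kernel is symmetric PSD.
    """

    network: MultiHeadMLP
    attributes: list[str]
    skipped_attributes: list[str] = field(default_factory=list)
    class_levels: dict[str, list[str]] = field(default_factory=dict)

    def features(self, X: np.ndarray) -> np.ndarray:
        return self.network.features(X)

    @property
    def feature_dim(self) -> int:
        return self.network.feature_dim


def train_feature_map(
    X: np.ndarray,
    attribute_labels: dict[str, np.ndarray],
    hidden: tuple[int, ...] = (64, 64, 32),
    epochs: int = 200,
    lr: float = 1e-3,
    seed: int = 0,
) -> FeatureMap:
    """Fit one joint MLP predicting every attribute through its own head.

    ``X`` is the preprocessed design matrix; ``attribute_labels`` maps each
    attribute name to a per-subject label vector (string or integer codes;
    missing entries allowed and excluded from that head's loss).
    Attributes with fewer than two observed groups are skipped with a
    warning.  A single joint network keeps the feature space shared, so MMD
    values are comparable across attributes.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    heads: dict[str, int] = {}
    targets: dict[str, np.ndarray] = {}
    levels: dict[str, list[str]] = {}
    skipped: list[str] = []
    for name, raw in attribute_labels.items():
        arr = np.asarray(raw, dtype=object)
        mask = np.array([x is not None and x == x for x in arr])
        if not mask.any():
            raise ValueError(f"attribute {name!r} is entirely missing")
        lv = sorted({str(x) for x in arr[mask]})
        if len(lv) < 2:
            warnings.warn(f"attribute {name!r} has a single group; skipped")
            skipped.append(name)
            continue
        codes = np.full(len(arr), -1, dtype=int)
        lut = {v: i for i, v in enumerate(lv)}
        codes[mask] = [lut[str(x)] for x in arr[mask]]
        heads[name] = len(lv)
        targets[name] = codes
        levels[name] = lv
    if not heads:
        raise ValueError("need at least one attribute with >= 2 groups")

    net = MultiHeadMLP(in_dim=X.shape[1], head_classes=heads, hidden=hidden, seed=seed)
    net.fit(X, targets, epochs=epochs, lr=lr)
    return FeatureMap(network=net, attributes=list(heads), skipped_attributes=skipped, class_levels=levels)


@dataclass
class ShiftReport:
    """Pairwise shift matrices for one attribute.

    ``mmd2`` and ``p_values`` are symmetric with zero / unit diagonal;
    ``linkage_matrix`` is a scipy average-linkage tree on distances
    max(MMD^2, 0).
    """

    attribute: str
    groups: list[str]
    mmd2: np.ndarray
    p_values: np.ndarray
    linkage_matrix: np.ndarray
    B: int
    seed: int
    subsample_n: dict[str, int] = field(default_factory=dict)
    dropped_groups: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "attribute": self.attribute,
            "groups": self.groups,
            "mmd2": self.mmd2.tolist(),
            "p_values": self.p_values.tolist(),
            "linkage_matrix": self.linkage_matrix.tolist(),
            "B": self.B,
            "seed": self.seed,
            "subsample_n": self.subsample_n,
            "dropped_groups": self.dropped_groups,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ShiftReport":
        d = json.loads(text)
        return cls(
            attribute=d["attribute"],
            groups=d["groups"],
            mmd2=np.array(d["mmd2"]),
            p_values=np.array(d["p_values"]),
            linkage_matrix=np.array(d["linkage_matrix"]),
            B=d["B"],
            seed=d["seed"],
            subsample_n=d["subsample_n"],
            dropped_groups=d["dropped_groups"],
        )


def pairwise_shift(
    feature_map: FeatureMap,
    X: np.ndarray,
    attribute_values: np.ndarray,
    attribute: str = "group",
    kernel: Kernel = linear_kernel,
    B: int = 999,
    seed: int = 0,
) -> ShiftReport:
    """MMD^2 and permutation p-value for every pair of attribute groups.

    Unequal group sizes are handled by subsampling the larger group to the
    smaller (seeded); the subsample size per pair is recorded.  Groups with
    fewer than 2 subjects are dropped with a warning recorded in the
    report.  Distances for the dendrogram clamp negative MMD^2 to zero.
    """
    phi = feature_map.features(np.asarray(X, dtype=float))
    values = np.asarray(attribute_values, dtype=object).astype(str)
    group_names = sorted(set(values))
    dropped = [g for g in group_names if (values == g).sum() < 2]
    if dropped:
        warnings.warn(f"groups with < 2 subjects dropped: {dropped}")
    groups = [g for g in group_names if g not in dropped]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")

    G = len(groups)
    mmd2 = np.zeros((G, G))
    pvals = np.eye(G) * 0 + np.where(np.eye(G, dtype=bool), 1.0, 0.0)
    sub_n: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    for i in range(G):
        for j in range(i + 1, G):
            Fi = phi[values == groups[i]]
            Fj = phi[values == groups[j]]
            n = min(len(Fi), len(Fj))
            if len(Fi) > n:
                Fi = Fi[rng.choice(len(Fi), size=n, replace=False)]
            if len(Fj) > n:
                Fj = Fj[rng.choice(len(Fj), size=n, replace=False)]
            stat, p = permutation_test(Fi, Fj, kernel=kernel, B=B, seed=int(rng.integers(2**31 - 1)))
            mmd2[i, j] = mmd2[j, i] = stat
            pvals[i, j] = pvals[j, i] = p
            sub_n[f"{groups[i]}|{groups[j]}"] = n

    dist = np.maximum(mmd2, 0.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return ShiftReport(
        attribute=attribute,
        groups=groups,
        mmd2=mmd2,
        p_values=pvals,
        linkage_matrix=Z,
        B=B,
        seed=seed,
        subsample_n=sub_n,
        dropped_groups=dropped,
    )
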