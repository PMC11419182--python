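"""Compact numpy multi-head MLP trained with Adam.

A shared ReLU trunk feeds one softmax head per attribute (sex, age band,
race, study, ...); the training loss is the sum of per-head cross
entropies.  Using a single joint network keeps the learned feature space
shared across attributes, so discrepancy statistics computed on the trunk
output are comparable between attributes.  Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _relu(z):
    return np.maximum(z, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MultiHeadMLP:
    """Shared trunk (three ReLU hidden layers) + per-attribute softmax heads."""

    in_dim: int
    head_classes: dict[str, int]
    hidden: tuple[int, ...] = (64, 64, 32)
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        dims = (self.in_dim,) + tuple(self.hidden)
        for i in range(len(self.hidden)):
            fan_in = dims[i]
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (dims[i], dims[i + 1]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        for name, k in self.head_classes.items():
            self.params[f"Wh_{name}"] = rng.normal(0.0, np.sqrt(1.0 / self.hidden[-1]), (self.hidden[-1], k))
            self.params[f"bh_{name}"] = np.zeros(k)

    @property
    def feature_dim(self) -> int:
        return self.hidden[-1]

    def _trunk(self, X: np.ndarray, keep_cache: bool = False):
        acts = [X]
        h = X
        for i in range(len(self.hidden)):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = _relu(z)
            acts.append(h)
        return (h, acts) if keep_cache else (h, None)

    def features(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer embedding: the learned canonical feature map."""
        h, _ = self._trunk(np.asarray(X, dtype=float))
        return h

    def head_probs(self, X: np.ndarray, name: str) -> np.ndarray:
        h, _ = self._trunk(np.asarray(X, dtype=float))
        return _softmax(h @ self.params[f"Wh_{name}"] + self.params[f"bh_{name}"])

    def fit(
        self,
        X: np.ndarray,
        head_targets: dict[str, np.ndarray],
        epochs: int = 200,
        batch_size: int = 128,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
    ) -> "MultiHeadMLP":
        """Minimize the summed per-head cross-entropy with Adam."""
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite inputs")
        n = X.shape[0]
        rng = np.random.default_rng(self.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        t = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                grads, loss = self._backward(X[idx], {k: y[idx] for k, y in head_targets.items()})
                epoch_loss += loss * len(idx)
                t += 1
                for k in self.params:
                    g = grads[k] + weight_decay * self.params[k]
                    m[k] = 0.9 * m[k] + 0.1 * g
                    v[k] = 0.999 * v[k] + 0.001 * g * g
                    mhat = m[k] / (1 - 0.9**t)
                    vhat = v[k] / (1 - 0.999**t)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            self.history.append(epoch_loss / n)
        return self

    def _backward(self, X, head_targets):
        nb = X.shape[0]
        h, acts = self._trunk(X, keep_cache=True)
        grads = {k: np.zeros_like(p) for k, p in self.params.items()}
        dh = np.zeros_like(h)
        loss = 0.0
        for name, k in self.head_classes.items():
            y = head_targets[name]
            ok = y >= 0  # -1 marks rows without this attribute
            if not ok.any():
                continue
            logits = h[ok] @ self.params[f"Wh_{name}"] + self.params[f"bh_{name}"]
            p = _softmax(logits)
            loss -= np.log(np.maximum(p[np.arange(ok.sum()), y[ok]], 1e-300)).sum() / nb
            dlogits = p.copy()
            dlogits[np.arange(ok.sum()), y[ok]] -= 1.0
            dlogits /= nb
            grads[f"Wh_{name}"] = h[ok].T @ dlogits
            grads[f"bh_{name}"] = dlogits.sum(axis=0)
            dh[ok] += dlogits @ self.params[f"Wh_{name}"].T
        # back through the trunk
        delta = dh
        for i in reversed(range(len(self.hidden))):
            delta = delta * (acts[i + 1] > 0)
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.params[f"W{i}"].T
        return grads, loss

    def head_accuracy(self, X: np.ndarray, name: str, y: np.ndarray) -> float:
        p = self.head_probs(X, name)
        ok = y >= 0
        return float((p[ok].argmax(axis=1) == y[ok]).mean())
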