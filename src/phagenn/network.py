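"""A small feed-forward softmax classifier trained with Adam.

The architecture is fixed by design: an input layer, two ReLU hidden
layers of 200 units with dropout (p = 0.2) after each, and a softmax
output with one unit per class. Loss is class-weighted categorical
cross-entropy. Training runs until the training loss has seen no
improvement for `patience_epochs` consecutive epochs (or `max_epochs`),
and the parameters kept are those from the epoch with the lowest
validation loss.

Implemented directly on numpy: the networks are small (a few hundred
units) and batched matrix products dominate, so this stays fast on one
CPU while keeping every numerical choice explicit and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class NetworkConfig:
    n_features: int
    n_classes: int
    hidden_width: int = 200
    n_hidden: int = 2
    dropout_p: float = 0.2
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    patience_epochs: int = 10
    max_epochs: int = 200
    batch_size: int = 256
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.optimizer_name != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Epoch (0-based) with minimum validation loss."""
        return int(np.argmin(self.val_loss))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class Standardizer:
    """Per-feature z-score transform fitted on training data only."""

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = mean
        self.scale = scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant features pass through centered
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


class MLPClassifier:
    """Two-hidden-layer softmax network with dropout, trained by Adam on
    class-weighted cross-entropy."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed)
        sizes = (
            [config.n_features]
            + [config.hidden_width] * config.n_hidden
            + [config.n_classes]
        )
        # He initialization for the ReLU layers.
        self.W = [
            self.rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.log = TrainingLog()
        self._adam_state: list[dict] | None = None

    # ----- forward / loss -------------------------------------------------

    def _forward(self, X: np.ndarray, *, train: bool = False):
        """Returns (activations, dropout masks, probabilities)."""
        acts = [X]
        masks = []
        a = X
        n_layers = len(self.W)
        p = self.config.dropout_p
        for i in range(n_layers - 1):
            a = _relu(a @ self.W[i] + self.b[i])
            if train and p > 0:
                mask = (self.rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        probs = softmax(a @ self.W[-1] + self.b[-1])
        return acts, masks, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, _, probs = self._forward(X, train=False)
        return probs

    def loss(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None) -> float:
        probs = self.predict_proba(X)
        nll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        if sample_weight is not None:
            nll = nll * sample_weight
        return float(nll.mean())

    # ----- training -------------------------------------------------------

    def _adam_step(self, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        if self._adam_state is None:
            self._adam_state = [
                {"mW": np.zeros_like(W), "vW": np.zeros_like(W),
                 "mb": np.zeros_like(b), "vb": np.zeros_like(b)}
                for W, b in zip(self.W, self.b)
            ]
            self._adam_t = 0
        self._adam_t += 1
        t = self._adam_t
        lr = self.config.learning_rate
        for i, (gW, gb) in enumerate(grads):
            s = self._adam_state[i]
            s["mW"] = beta1 * s["mW"] + (1 - beta1) * gW
            s["vW"] = beta2 * s["vW"] + (1 - beta2) * gW**2
            s["mb"] = beta1 * s["mb"] + (1 - beta1) * gb
            s["vb"] = beta2 * s["vb"] + (1 - beta2) * gb**2
            mW_hat = s["mW"] / (1 - beta1**t)
            vW_hat = s["vW"] / (1 - beta2**t)
            mb_hat = s["mb"] / (1 - beta1**t)
            vb_hat = s["vb"] / (1 - beta2**t)
            self.W[i] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
            self.b[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)

    def _batch_update(self, Xb: np.ndarray, yb: np.ndarray, wb: np.ndarray) -> None:
        acts, masks, probs = self._forward(Xb, train=True)
        n = len(yb)
        delta = probs.copy()
        delta[np.arange(n), yb] -= 1.0
        delta *= wb[:, None] / n
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        for i in range(len(self.W) - 1, -1, -1):
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            grads.append((gW, gb))
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta *= masks[i - 1]
                delta *= acts[i] > 0
        self._adam_step(grads[::-1])

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        class_weight: np.ndarray | None = None,
    ) -> "MLPClassifier":
        """Train with early stopping on the training loss; keep the
        parameters from the epoch with minimum validation loss."""
        cfg = self.config
        if class_weight is None:
            class_weight = np.ones(cfg.n_classes)
        w_train = class_weight[y_train]
        w_val = class_weight[y_val]

        best_train = np.inf
        stale = 0
        best_val = np.inf
        best_params: tuple[list[np.ndarray], list[np.ndarray]] | None = None

        n = len(y_train)
        for _epoch in range(cfg.max_epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                self._batch_update(X_train[sel], y_train[sel], w_train[sel])

            train_loss = self.loss(X_train, y_train, w_train)
            val_loss = self.loss(X_val, y_val, w_val)
            self.log.train_loss.append(train_loss)
            self.log.val_loss.append(val_loss)
            if not np.isfinite(train_loss) or not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}: train={train_loss}, val={val_loss}"
                )

            if val_loss < best_val:
                best_val = val_loss
                best_params = ([W.copy() for W in self.W], [b.copy() for b in self.b])

            if train_loss < best_train - 1e-12:
                best_train = train_loss
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience_epochs:
                    break

        if best_params is not None:
            self.W, self.b = best_params
        return self

    # ----- persistence ----------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        n = len(self.W)
        self.W = [np.asarray(params[f"W{i}"]) for i in range(n)]
        self.b = [np.asarray(params[f"b{i}"]) for i in range(n)]
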