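"""Minimal dense autoencoder with manual backpropagation.

Architecture (fixed): encoder = linear(d→500) → dropout(0.2) → tanh →
linear(500→100); decoder mirrors it back to d.  Training minimizes mean
squared reconstruction error with Adam, holds out 20% of samples as a
validation split, and stops early once the validation loss has failed to
improve for five consecutive epochs; the weights from the best validation
epoch are kept.  Dropout is active only during training, so encoding is
deterministic.

Everything is plain numpy: all randomness (initialization, the validation
split, batch shuffling, dropout masks) flows from a single integer seed, so
training is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

HIDDEN_DIM = 500
LATENT_DIM = 100
DROPOUT_P = 0.2

_WEIGHT_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters (architecture itself is fixed)."""

    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 5
    batch_size: int = 32
    validation_fraction: float = 0.2


@dataclass
class AEModel:
    """A trained autoencoder: weight arrays, seed, and loss history."""

    input_dim: int
    weights: dict = field(default_factory=dict)
    seed: int = 0
    training_history: list = field(default_factory=list)  # (train, val) per epoch
    stopped_epoch: int = -1

    def state_arrays(self) -> dict:
        return {k: self.weights[k] for k in _WEIGHT_KEYS}

    @classmethod
    def from_npz(cls, path) -> "AEModel":
        with np.load(path) as z:
            weights = {k: z[k].copy() for k in _WEIGHT_KEYS}
            hist = [tuple(row) for row in z["history"]]
            return cls(
                input_dim=weights["W1"].shape[0],
                weights=weights,
                seed=int(z["seed"]),
                training_history=hist,
                stopped_epoch=int(z["stopped_epoch"]),
            )

    def copy(self) -> "AEModel":
        return AEModel(
            input_dim=self.input_dim,
            weights={k: v.copy() for k, v in self.weights.items()},
            seed=self.seed,
            training_history=list(self.training_history),
            stopped_epoch=self.stopped_epoch,
        )

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Deterministic map to the 100-dimensional bottleneck."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected (n, {self.input_dim}) input, got {X.shape}"
            )
        w = self.weights
        h = np.tanh(X @ w["W1"] + w["b1"])
        return h @ w["W2"] + w["b2"]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        z = self.encode(X)
        w = self.weights
        h = np.tanh(z @ w["W3"] + w["b3"])
        return h @ w["W4"] + w["b4"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_weights(rng: np.random.Generator, d: int) -> dict:
    return {
        "W1": _glorot(rng, d, HIDDEN_DIM),
        "b1": np.zeros(HIDDEN_DIM),
        "W2": _glorot(rng, HIDDEN_DIM, LATENT_DIM),
        "b2": np.zeros(LATENT_DIM),
        "W3": _glorot(rng, LATENT_DIM, HIDDEN_DIM),
        "b3": np.zeros(HIDDEN_DIM),
        "W4": _glorot(rng, HIDDEN_DIM, d),
        "b4": np.zeros(d),
    }


def _forward_backward(
    w: dict, X: np.ndarray, rng: np.random.Generator
) -> tuple[float, dict]:
    """One training forward/backward pass with fresh dropout masks.

    Returns (mse, gradients).  Inverted dropout: masks scale kept units by
    1/(1-p) so inference needs no rescaling.
    """
    n, d = X.shape
    keep = 1.0 - DROPOUT_P
    m1 = (rng.random((n, HIDDEN_DIM)) < keep) / keep
    m2 = (rng.random((n, HIDDEN_DIM)) < keep) / keep

    # encoder: linear -> dropout -> tanh -> linear
    h1 = X @ w["W1"] + w["b1"]
    h1d = h1 * m1
    a1 = np.tanh(h1d)
    z = a1 @ w["W2"] + w["b2"]
    # decoder
    h3 = z @ w["W3"] + w["b3"]
    h3d = h3 * m2
    a3 = np.tanh(h3d)
    xhat = a3 @ w["W4"] + w["b4"]

    resid = xhat - X
    loss = float(np.mean(resid**2))

    g = {}
    dxhat = (2.0 / (n * d)) * resid
    g["W4"] = a3.T @ dxhat
    g["b4"] = dxhat.sum(axis=0)
    da3 = dxhat @ w["W4"].T
    dh3 = da3 * (1.0 - a3**2) * m2
    g["W3"] = z.T @ dh3
    g["b3"] = dh3.sum(axis=0)
    dz = dh3 @ w["W3"].T
    g["W2"] = a1.T @ dz
    g["b2"] = dz.sum(axis=0)
    da1 = dz @ w["W2"].T
    dh1 = da1 * (1.0 - a1**2) * m1
    g["W1"] = X.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return loss, g


def _eval_loss(w: dict, X: np.ndarray) -> float:
    h = np.tanh(X @ w["W1"] + w["b1"])
    z = h @ w["W2"] + w["b2"]
    h3 = np.tanh(z @ w["W3"] + w["b3"])
    xhat = h3 @ w["W4"] + w["b4"]
    return float(np.mean((xhat - X) ** 2))


def train_autoencoder(
    X: np.ndarray, seed: int, config: Optional[TrainingConfig] = None
) -> AEModel:
    """Train one autoencoder on a scaled samples × features matrix.

    20% of the samples (at least one) are reserved as a validation set;
    training halts when validation loss has not improved for
    ``config.patience`` consecutive epochs, and the best-epoch weights are
    restored.  Identical (X, seed, config) give identical weights.
    """
    cfg = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 samples to train, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("training data contains non-finite values")

    rng = np.random.default_rng(seed)
    w = _init_weights(rng, d)

    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = X[train_idx], X[val_idx]
    n_tr = len(train_idx)
    batch = min(cfg.batch_size, n_tr)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(val) for k, val in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    history: list[tuple[float, float]] = []
    best_val = np.inf
    best_w = {k: arr.copy() for k, arr in w.items()}
    best_epoch = 0
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_tr, batch):
            idx = order[start : start + batch]
            loss, g = _forward_backward(w, Xtr[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            epoch_loss += loss
            n_batches += 1
            t += 1
            for k in w:
                m[k] = beta1 * m[k] + (1 - beta1) * g[k]
                v[k] = beta2 * v[k] + (1 - beta2) * g[k] ** 2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                w[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val_loss = _eval_loss(w, Xval)
        history.append((epoch_loss / n_batches, val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_w = {k: arr.copy() for k, arr in w.items()}
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    return AEModel(
        input_dim=d,
        weights=best_w,
        seed=int(seed),
        training_history=history,
        stopped_epoch=best_epoch,
    )
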