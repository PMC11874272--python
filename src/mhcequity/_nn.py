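"""Minimal deterministic feed-forward networks with RMSProp.

Both neural models in this package are small fully connected networks
trained with root-mean-square-propagation gradient descent, sigmoid
output, optional per-layer skip connections (a hidden layer's input is
concatenated with its output before the next layer) and optional dropout
on hidden activations. The implementation is plain numpy with explicit
backpropagation so that

* the loss can be the inequality-censored squared error,
* initial weights are a pure function of an integer seed and are reused
  verbatim on every retraining of the same configuration,
* training is bit-reproducible on one thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

Array = np.ndarray

# y-space inequality codes: 0 -> "=", +1 -> ">=" (pred below y penalized),
# -1 -> "<=" (pred above y penalized)
INEQ_EQ, INEQ_GE, INEQ_LE = 0, 1, -1

_INEQ_CODE = {"=": INEQ_EQ, ">=": INEQ_GE, "<=": INEQ_LE}


def encode_inequalities(symbols: Sequence[str]) -> Array:
    """Map y-space inequality symbols to integer codes."""
    try:
        return np.array([_INEQ_CODE[s] for s in symbols], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"invalid inequality symbol {e.args[0]!r}") from None


def censored_residual(pred: Array, y: Array, ineq: Array) -> Array:
    """Residual (pred - y) zeroed wherever the inequality is satisfied."""
    r = pred - y
    satisfied = ((ineq == INEQ_GE) & (r >= 0)) | ((ineq == INEQ_LE) & (r <= 0))
    return np.where(satisfied, 0.0, r)


def censored_mse(pred: Array, y: Array, ineq: Array) -> float:
    """Mean inequality-censored squared error."""
    r = censored_residual(pred, y, ineq)
    return float(np.mean(r * r))


def _sigmoid(z: Array) -> Array:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPParams:
    """Weights/biases for hidden layers plus the sigmoid output unit."""

    weights: list[Array]
    biases: list[Array]

    def copy(self) -> "MLPParams":
        return MLPParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def astype(self, dtype) -> "MLPParams":
        return MLPParams(
            [w.astype(dtype) for w in self.weights],
            [b.astype(dtype) for b in self.biases],
        )

    def flat(self) -> Array:
        return np.concatenate([a.ravel() for a in self.weights + self.biases])


def init_params(
    n_inputs: int,
    hidden_units: Sequence[int],
    skip: Sequence[bool],
    seed: int,
) -> MLPParams:
    """He-style initialization, a pure function of the seed."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    fan_in = n_inputs
    for h, sk in zip(hidden_units, skip):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, h)))
        biases.append(np.zeros(h))
        fan_out = h + fan_in if sk else h
        fan_in = fan_out
    weights.append(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, 1)))
    biases.append(np.zeros(1))
    return MLPParams(weights, biases)


def forward(
    params: MLPParams,
    X: Array,
    skip: Sequence[bool],
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Array, list]:
    """Forward pass; returns (predictions in (0,1), cache for backprop).

    With ``dropout`` > 0 and an rng, inverted dropout is applied to each
    hidden layer's ReLU output (training mode). Without an rng the pass
    is deterministic (inference mode).
    """
    cache = []
    a = X
    for i, sk in enumerate(skip):
        z = a @ params.weights[i] + params.biases[i]
        h = np.maximum(z, 0.0)
        mask = None
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        cache.append((a, z, mask, sk))
        a = np.concatenate([a, h], axis=1) if sk else h
    z_out = a @ params.weights[-1] + params.biases[-1]
    pred = _sigmoid(z_out)[:, 0]
    cache.append((a, z_out))
    return pred, cache


def backward(
    params: MLPParams,
    cache: list,
    dloss_dpred: Array,
    skip: Sequence[bool],
) -> MLPParams:
    """Gradients of the loss w.r.t. all parameters."""
    a_last, z_out = cache[-1]
    sig = _sigmoid(z_out)[:, 0]
    dz = (dloss_dpred * sig * (1.0 - sig))[:, None]
    gw = [None] * len(params.weights)
    gb = [None] * len(params.biases)
    gw[-1] = a_last.T @ dz
    gb[-1] = dz.sum(axis=0)
    da = dz @ params.weights[-1].T
    for i in range(len(skip) - 1, -1, -1):
        a_in, z, mask, sk = cache[i]
        if sk:
            n_in = a_in.shape[1]
            da_in_direct = da[:, :n_in]
            dh = da[:, n_in:]
        else:
            da_in_direct = 0.0
            dh = da
        if mask is not None:
            dh = dh * mask
        dz_h = dh * (z > 0.0)
        gw[i] = a_in.T @ dz_h
        gb[i] = dz_h.sum(axis=0)
        da = dz_h @ params.weights[i].T + da_in_direct
    return MLPParams(gw, gb)


@dataclass
class TrainResult:
    params: MLPParams
    n_epochs: int
    best_val_loss: float
    history: list[float] = field(default_factory=list)


def train_rmsprop(
    params: MLPParams,
    skip: Sequence[bool],
    X: Array,
    y: Array,
    ineq: Array,
    X_val: Array,
    y_val: Array,
    ineq_val: Array,
    learning_rate: float = 1e-3,
    rho: float = 0.9,
    eps: float = 1e-7,
    batch_size: int = 128,
    max_epochs: int = 200,
    patience: int = 20,
    min_delta: float = 1e-4,
    dropout: float = 0.0,
    seed: int = 0,
) -> TrainResult:
    """Minibatch RMSProp on the censored MSE with early stopping.

    The validation loss is the censored MSE; training halts when it has
    not improved by at least ``min_delta`` for ``patience`` epochs, and
    the best-validation parameter state is returned.
    """
    params = params.copy()
    rng = np.random.default_rng(seed)
    caches_w = [np.zeros_like(w) for w in params.weights]
    caches_b = [np.zeros_like(b) for b in params.biases]
    n = X.shape[0]
    best = params.copy()
    best_loss = np.inf
    stale = 0
    history = []
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb, ib = X[idx], y[idx], ineq[idx]
            drop_rng = rng if dropout > 0.0 else None
            pred, cache = forward(params, xb, skip, dropout=dropout, rng=drop_rng)
            r = censored_residual(pred, yb, ib)
            dloss = 2.0 * r / len(idx)
            grads = backward(params, cache, dloss, skip)
            for j in range(len(params.weights)):
                caches_w[j] = rho * caches_w[j] + (1 - rho) * grads.weights[j] ** 2
                caches_b[j] = rho * caches_b[j] + (1 - rho) * grads.biases[j] ** 2
                params.weights[j] -= learning_rate * grads.weights[j] / (
                    np.sqrt(caches_w[j]) + eps
                )
                params.biases[j] -= learning_rate * grads.biases[j] / (
                    np.sqrt(caches_b[j]) + eps
                )
        val_pred, _ = forward(params, X_val, skip)
        val_loss = censored_mse(val_pred, y_val, ineq_val)
        history.append(val_loss)
        if val_loss < best_loss - min_delta:
            best_loss = val_loss
            best = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return TrainResult(params=best, n_epochs=epoch, best_val_loss=float(best_loss), history=history)
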