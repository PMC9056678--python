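"""Fully connected regression network with per-block batch normalization,
dropout and L2 weight decay, trained by minibatch Adam or RMSprop.

Architecture (one block per hidden layer):

    input → [FC(width) → BatchNorm (optional) → activation → dropout]* → FC(1)

The loss is mean squared error plus ``l2_lambda × Σ‖W‖²`` over the FC weight
matrices only (not biases, not batch-norm scale/shift).  Everything is plain
numpy: given the same data, hyperparameters and seed, training is bitwise
reproducible.

Batch normalization uses batch statistics during training and exponential
running averages (momentum 0.9) at inference, so prediction is deterministic.
Dropout is inverted dropout, active only during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["NeuralNet", "TrainingDivergedError", "ACTIVATIONS", "OPTIMIZERS"]

ACTIVATIONS = ("tanh", "relu", "sigmoid")
OPTIMIZERS = ("adam", "rmsprop")

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation '{name}'")


def _act_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y = act(x) is passed in to reuse the forward value
    if name == "tanh":
        return 1.0 - y * y
    if name == "relu":
        return (x > 0.0).astype(x.dtype)
    if name == "sigmoid":
        return y * (1.0 - y)
    raise ValueError(f"unknown activation '{name}'")


@dataclass
class _Dense:
    W: np.ndarray
    b: np.ndarray


@dataclass
class _BatchNorm:
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray


class _Optimizer:
    """Adam / RMSprop over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, kind: str, params: List[np.ndarray], lr: float):
        if kind not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer '{kind}'; expected one of {OPTIMIZERS}")
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.v = [np.zeros_like(p) for p in params]  # 2nd moment
        self.m = [np.zeros_like(p) for p in params]  # 1st moment (adam only)

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        if self.kind == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            for p, g, m, v in zip(params, grads, self.m, self.v):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        else:  # rmsprop
            rho, eps = 0.9, 1e-8
            for p, g, v in zip(params, grads, self.v):
                v *= rho
                v += (1 - rho) * g * g
                p -= self.lr * g / (np.sqrt(v) + eps)


class NeuralNet:
    """The regression network.

    Parameters
    ----------
    n_features : input dimensionality (pruned descriptor length).
    hidden : sequence of ``(width, batch_norm)`` pairs, one per hidden block.
    activation : "tanh" | "relu" | "sigmoid".
    dropout : dropout ratio in [0, 1), applied after each block's activation.
    seed : controls weight initialization, shuffling and dropout masks.
    """

    def __init__(
        self,
        n_features: int,
        hidden: Sequence[Tuple[int, bool]],
        activation: str = "tanh",
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation '{activation}'")
        if not 0.0 <= dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {dropout}")
        if n_features < 1 or any(w < 1 for w, _ in hidden):
            raise ValueError("layer widths must be >= 1")
        self.n_features = int(n_features)
        self.hidden = [(int(w), bool(bn)) for w, bn in hidden]
        self.activation = activation
        self.dropout = float(dropout)
        self.rng = np.random.default_rng(seed)

        self.layers: List[_Dense] = []
        self.bns: List[Optional[_BatchNorm]] = []
        fan_in = self.n_features
        for width, bn in self.hidden:
            limit = np.sqrt(6.0 / (fan_in + width))  # Glorot uniform
            self.layers.append(
                _Dense(
                    W=self.rng.uniform(-limit, limit, size=(fan_in, width)),
                    b=np.zeros(width),
                )
            )
            self.bns.append(
                _BatchNorm(
                    gamma=np.ones(width),
                    beta=np.zeros(width),
                    running_mean=np.zeros(width),
                    running_var=np.ones(width),
                )
                if bn
                else None
            )
            fan_in = width
        limit = np.sqrt(6.0 / (fan_in + 1))
        self.out = _Dense(
            W=self.rng.uniform(-limit, limit, size=(fan_in, 1)), b=np.zeros(1)
        )

    # ---------------------------------------------------------------- params
    def _params(self) -> List[np.ndarray]:
        ps: List[np.ndarray] = []
        for lay, bn in zip(self.layers, self.bns):
            ps += [lay.W, lay.b]
            if bn is not None:
                ps += [bn.gamma, bn.beta]
        ps += [self.out.W, self.out.b]
        return ps

    # --------------------------------------------------------------- forward
    def _forward_train(self, X: np.ndarray, drop_rng: np.random.Generator):
        """Forward pass with batch statistics + dropout; caches for backprop."""
        caches = []
        h = X
        for lay, bn in zip(self.layers, self.bns):
            z = h @ lay.W + lay.b
            cache: Dict[str, np.ndarray] = {"x": h, "z": z}
            if bn is not None:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv_std
                zbn = bn.gamma * zhat + bn.beta
                bn.running_mean *= _BN_MOMENTUM
                bn.running_mean += (1 - _BN_MOMENTUM) * mu
                bn.running_var *= _BN_MOMENTUM
                bn.running_var += (1 - _BN_MOMENTUM) * var
                cache.update(zhat=zhat, inv_std=inv_std, zc=z - mu)
            else:
                zbn = z
            a = _act(self.activation, zbn)
            cache.update(zbn=zbn, a=a)
            if self.dropout > 0.0:
                mask = (
                    drop_rng.random(a.shape) >= self.dropout
                ).astype(a.dtype) / (1.0 - self.dropout)
                a = a * mask
                cache["mask"] = mask
            caches.append(cache)
            h = a
        yhat = (h @ self.out.W + self.out.b).ravel()
        return yhat, h, caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference: running batch-norm statistics, no dropout."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects {self.n_features}"
            )
        h = X
        for lay, bn in zip(self.layers, self.bns):
            z = h @ lay.W + lay.b
            if bn is not None:
                z = bn.gamma * (z - bn.running_mean) / np.sqrt(
                    bn.running_var + _BN_EPS
                ) + bn.beta
            h = _act(self.activation, z)
        return (h @ self.out.W + self.out.b).ravel()

    def forward_stages(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        """Inference-mode feature maps of the first hidden block.

        Returns ``input`` (X itself), ``linear`` (first FC pre-activation),
        ``batch_norm`` (normalized pre-activation; present only when the
        first block carries a bN layer) and ``activation`` (the block's
        output).  The computation order matches the architecture
        FC → bN → activation.
        """
        X = np.asarray(X, dtype=float)
        lay, bn = self.layers[0], self.bns[0]
        z = X @ lay.W + lay.b
        stages: Dict[str, np.ndarray] = {"input": X, "linear": z}
        if bn is not None:
            zbn = bn.gamma * (z - bn.running_mean) / np.sqrt(
                bn.running_var + _BN_EPS
            ) + bn.beta
            stages["batch_norm"] = zbn
            stages["activation"] = _act(self.activation, zbn)
        else:
            stages["activation"] = _act(self.activation, z)
        return stages

    # -------------------------------------------------------------- backward
    def _backward(self, X, y, yhat, h_last, caches, l2_lambda):
        m = X.shape[0]
        grads: List[np.ndarray] = []
        dy = (2.0 / m) * (yhat - y)[:, None]  # d MSE / d output
        g_out_W = h_last.T @ dy + 2.0 * l2_lambda * self.out.W
        g_out_b = dy.sum(axis=0)
        dh = dy @ self.out.W.T
        for lay, bn, cache in zip(
            reversed(self.layers), reversed(self.bns), reversed(caches)
        ):
            if "mask" in cache:
                dh = dh * cache["mask"]
            da = dh * _act_grad(self.activation, cache["zbn"], cache["a"])
            if bn is not None:
                zhat, inv_std, zc = cache["zhat"], cache["inv_std"], cache["zc"]
                g_gamma = (da * zhat).sum(axis=0)
                g_beta = da.sum(axis=0)
                dzhat = da * bn.gamma
                dvar = (dzhat * zc).sum(axis=0) * (-0.5) * inv_std**3
                dmu = -(dzhat.sum(axis=0)) * inv_std + dvar * (-2.0 / m) * zc.sum(axis=0)
                dz = dzhat * inv_std + dvar * (2.0 / m) * zc + dmu / m
            else:
                dz = da
            g_W = cache["x"].T @ dz + 2.0 * l2_lambda * lay.W
            g_b = dz.sum(axis=0)
            dh = dz @ lay.W.T
            block = [g_W, g_b] + ([g_gamma, g_beta] if bn is not None else [])
            grads = block + grads
        grads += [g_out_W, g_out_b]
        return grads

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        optimizer: str = "adam",
        lr: float = 1e-3,
        batch_size: int = 32,
        l2_lambda: float = 0.0,
        seed: int = 0,
    ) -> List[float]:
        """Train in place; returns the per-epoch mean training loss.

        Raises :class:`TrainingDivergedError` (naming the hyperparameters)
        if the loss goes non-finite.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-d with one row per target value")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {epochs}")
        opt = _Optimizer(optimizer, self._params(), lr)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        history: List[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                if idx.size < 2:  # batch statistics need >= 2 rows
                    continue
                xb, yb = X[idx], y[idx]
                yhat, h_last, caches = self._forward_train(xb, rng)
                loss = float(np.mean((yhat - yb) ** 2))
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"loss diverged (optimizer={optimizer}, lr={lr}, "
                        f"l2_lambda={l2_lambda}, hidden={self.hidden}, "
                        f"activation={self.activation}, dropout={self.dropout})"
                    )
                grads = self._backward(xb, yb, yhat, h_last, caches, l2_lambda)
                params = self._params()
                opt.step(params, grads)
                epoch_loss += loss * idx.size
            history.append(epoch_loss / n)
        return history

    def l2_penalty(self, l2_lambda: float) -> float:
        """λ Σ‖W‖² over FC weight matrices (the regularized part of the loss)."""
        s = sum(float(np.sum(l.W**2)) for l in self.layers) + float(
            np.sum(self.out.W**2)
        )
        return l2_lambda * s
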