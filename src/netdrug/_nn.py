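"""Minimal dense neural-network machinery (NumPy, explicit gradients).

Provides a feed-forward regressor with ReLU hidden layers trained by Adam
on mean-squared error, plus the Adam update rule reused by the graph
models.  Deliberately tiny: dense layers only, full-batch training,
deterministic under a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "MLPRegressor"]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class MLPRegressor:
    """Fully connected feed-forward regressor.

    Parameters
    ----------
    n_features
        Input width.
    hidden
        Widths of the ReLU hidden layers, e.g. ``(64, 64)`` for the
        two-hidden-layer configuration.
    output
        "linear" (default) for a scalar regression head, or "softmax" to
        apply a softmax across the output units — degenerate for a single
        output (constantly 1) but kept available for comparison runs.
    seed
        Weight-initialization seed; training is fully deterministic for a
        fixed seed.
    """

    def __init__(self, n_features: int, hidden: tuple[int, ...] = (64, 64),
                 output: str = "linear", seed: int = 0):
        if output not in ("linear", "softmax"):
            raise ValueError(f"unknown output head {output!r}")
        rng = np.random.default_rng(seed)
        dims = [n_features, *hidden, 1]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.output = output

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if cache is not None:
            cache.append(h)
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < last:
                h = _relu(z)
            elif self.output == "softmax":
                h = _softmax(z)
            else:
                h = z
            if cache is not None:
                cache.append(h)
        return h[:, 0]

    def _backward(self, cache: list, d_out: np.ndarray) -> list[np.ndarray]:
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        d = d_out[:, None]
        if self.output == "softmax":
            # single-output softmax is constant; jacobian p*(1-p) with p = 1 -> 0
            p = cache[-1]
            d = d * p * (1.0 - p)
        for i in range(len(self.W) - 1, -1, -1):
            h_in = cache[i]
            if i < len(self.W) - 1:
                d = d * (cache[i + 1] > 0)
            gW[i] = h_in.T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return [*gW, *gb]

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 200,
            lr: float = 1e-3) -> list[float]:
        """Full-batch Adam on MSE; returns the per-epoch loss history."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        opt = Adam(self.params, lr=lr)
        history: list[float] = []
        n = len(y)
        for _ in range(epochs):
            cache: list = []
            pred = self.forward(X, cache)
            resid = pred - y
            loss = float(resid @ resid / n)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            history.append(loss)
            if lr > 0:
                opt.step(self._backward(cache, 2.0 * resid / n))
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)
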