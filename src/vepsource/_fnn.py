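"""Small feedforward net with a leading 1-D convolution, in plain numpy.

Architecture: conv1d (F filters, kernel k) over the time axis -> ReLU ->
flatten -> dense hidden layer -> ReLU -> 2-way softmax.  Trained full-batch
with Adam and cross-entropy for a fixed number of passes; weight
initialization and the whole trajectory are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class FnnParams:
    n_filters: int = 8
    kernel: int = 7
    hidden: int = 32
    epochs: int = 50
    lr: float = 0.01


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvFnn:
    """conv1d -> dense -> 2-way classifier with manual gradients."""

    def __init__(self, n_time: int, params: FnnParams = FnnParams(),
                 seed: int = 0) -> None:
        p = params
        if n_time <= p.kernel:
            raise ValueError("input shorter than the convolution kernel")
        self.params = p
        self.n_time = n_time
        L = n_time - p.kernel + 1
        rng = np.random.default_rng(seed)
        he = lambda fan_in, shape: rng.standard_normal(shape) * np.sqrt(
            2.0 / fan_in)
        self.W1 = he(p.kernel, (p.kernel, p.n_filters))
        self.b1 = np.zeros(p.n_filters)
        self.W2 = he(L * p.n_filters, (L * p.n_filters, p.hidden))
        self.b2 = np.zeros(p.hidden)
        self.W3 = he(p.hidden, (p.hidden, 2))
        self.b3 = np.zeros(2)
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)]
                      for k, v in self._weights().items()}
        self._t = 0

    def _weights(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "W3": self.W3, "b3": self.b3}

    def _forward(self, X: np.ndarray):
        Xc = sliding_window_view(X, self.params.kernel, axis=1)  # n,L,k
        Z1 = Xc @ self.W1 + self.b1                              # n,L,F
        A1 = np.maximum(Z1, 0.0)
        A1f = A1.reshape(X.shape[0], -1)
        Z2 = A1f @ self.W2 + self.b2
        A2 = np.maximum(Z2, 0.0)
        Z3 = A2 @ self.W3 + self.b3
        return Xc, Z1, A1f, Z2, A2, Z3

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvFnn":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        Y = np.zeros((n, 2))
        Y[np.arange(n), y] = 1.0
        b1, b2 = 0.9, 0.999
        eps = 1e-8
        for _ in range(self.params.epochs):
            Xc, Z1, A1f, Z2, A2, Z3 = self._forward(X)
            P = _softmax(Z3)
            dZ3 = (P - Y) / n
            grads = {
                "W3": A2.T @ dZ3,
                "b3": dZ3.sum(axis=0),
            }
            dA2 = dZ3 @ self.W3.T
            dZ2 = dA2 * (Z2 > 0)
            grads["W2"] = A1f.T @ dZ2
            grads["b2"] = dZ2.sum(axis=0)
            dA1f = dZ2 @ self.W2.T
            dZ1 = dA1f.reshape(Z1.shape) * (Z1 > 0)
            grads["W1"] = np.einsum("nlk,nlf->kf", Xc, dZ1)
            grads["b1"] = dZ1.sum(axis=(0, 1))
            self._t += 1
            weights = self._weights()
            for k, g in grads.items():
                m, v = self._adam[k]
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self._t)
                vhat = v / (1 - b2 ** self._t)
                weights[k] -= self.params.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        *_, Z3 = self._forward(np.asarray(X, dtype=float))
        return Z3.argmax(axis=1)
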