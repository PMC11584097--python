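"""Minimal feed-forward building blocks with explicit backpropagation.

The networks in this package are tiny (single affine maps and 2x32 MLPs),
so they are implemented directly on NumPy arrays with hand-written
gradients and an Adam optimizer.  Gradients are exercised by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "softmax", "sigmoid", "log_softmax"]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Dense:
    """Affine layer y = x W + b with cached input for backward."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Glorot-uniform init
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # forward without caching (inference)
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def state(self) -> dict:
        return {"W": self.W.tolist(), "b": self.b.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "Dense":
        W = np.asarray(state["W"], dtype=float)
        obj = cls.__new__(cls)
        obj.W = W
        obj.b = np.asarray(state["b"], dtype=float)
        obj.dW = np.zeros_like(obj.W)
        obj.db = np.zeros_like(obj.b)
        obj._x = None
        return obj


class MLP:
    """Fully connected net with ReLU hidden layers and a linear output."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator):
        dims = [n_in, *hidden, n_out]
        self.layers = [Dense(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        self._relu_masks: list[np.ndarray] = []

    @property
    def n_in(self) -> int:
        return self.layers[0].W.shape[0]

    @property
    def n_out(self) -> int:
        return self.layers[-1].W.shape[1]

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Training forward pass; inverted dropout on hidden activations."""
        self._relu_masks = []
        h = x
        for layer in self.layers[:-1]:
            h = layer.forward(h)
            mask = (h > 0).astype(float)
            if dropout > 0.0:
                keep = rng.random(h.shape) >= dropout
                mask *= keep / (1.0 - dropout)
            self._relu_masks.append(mask)
            h = h * mask
        return self.layers[-1].forward(h)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers[:-1]:
            h = np.maximum(layer(h), 0.0)
        return self.layers[-1](h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.layers[-1].backward(dy)
        for layer, mask in zip(reversed(self.layers[:-1]),
                               reversed(self._relu_masks)):
            d = layer.backward(d * mask)
        return d

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> dict:
        return {"layers": [l.state() for l in self.layers]}

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        obj = cls.__new__(cls)
        obj.layers = [Dense.from_state(s) for s in state["layers"]]
        obj._relu_masks = []
        return obj

    def copy(self) -> "MLP":
        return MLP.from_state(self.state())


class Adam:
    """Adam optimizer updating a fixed list of parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                # decoupled decay, applied to weights only (bias arrays
                # are 1-D)
                if p.ndim > 1:
                    p *= 1.0 - self.lr * self.weight_decay
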