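"""A compact numpy neural-network engine for small image classifiers.

Implements exactly the layer vocabulary the colony classifier needs —
2-D convolution (im2col), ReLU, 2x2 max pooling, global average pooling,
dense layers, and a fused softmax/cross-entropy head — together with Adam,
seeded He initialization, and HDF5 persistence.  Everything is plain
numpy with NHWC tensors; sizes in this package are desk-scale (tens of
thousands of parameters, 64x64 inputs), where vectorized numpy is fast
enough for full training runs in seconds to minutes on one core.

Gradient correctness is pinned by finite-difference tests rather than by
construction, so the implementations favour clarity over micro-optimisation.
"""

from __future__ import annotations

import json
from typing import Iterable

import h5py
import numpy as np

__all__ = [
    "InputCenter",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAveragePooling",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "save_weights_h5",
    "load_weights_h5",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of integer targets ``y``."""
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), y] + eps).mean())


class Layer:
    trainable = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def spec(self) -> dict:  # serialization descriptor
        return {"type": type(self).__name__}


class InputCenter(Layer):
    """Map [0, 1] inputs to [-1, 1]; zero-centred inputs speed up ReLU nets."""

    trainable = False

    def forward(self, x):
        return x * 2.0 - 1.0

    def backward(self, dout):
        return dout * 2.0


class Conv2D(Layer):
    """Same-padded 3x3 (or kxk) convolution, NHWC, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        n, h, w = x.shape[:3]
        return win.reshape(n * h * w, k * k * self.c_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        n, h, w, _ = x.shape
        out = cols @ self.W.reshape(-1, self.c_out) + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._xshape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(-1, self.c_out)
        self.dW[...] = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = dflat @ self.W.reshape(-1, self.c_out).T
        dcols = dcols.reshape(n, h, w, k, k, self.c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]

    def spec(self):
        return {"type": "Conv2D", "c_in": self.c_in, "c_out": self.c_out, "k": self.k}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        xt = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = xt.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._inshape
        h2, w2 = h // 2, w // 2
        dxt = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=-1)
        dxt = dxt.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * h2, : 2 * w2, :] = dxt.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class GlobalAveragePooling(Layer):
    def forward(self, x):
        self._inshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._inshape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        self.d_in, self.d_out = d_in, d_out
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def spec(self):
        return {"type": "Dense", "d_in": self.d_in, "d_out": self.d_out}


_LAYER_TYPES = {
    "Conv2D": lambda s: Conv2D(s["c_in"], s["c_out"], s["k"]),
    "InputCenter": lambda s: InputCenter(),
    "Dense": lambda s: Dense(s["d_in"], s["d_out"]),
    "ReLU": lambda s: ReLU(),
    "MaxPool2": lambda s: MaxPool2(),
    "GlobalAveragePooling": lambda s: GlobalAveragePooling(),
}


class Sequential:
    """A feed-forward stack ending in logits; the softmax lives in the loss."""

    def __init__(self, layers: Iterable[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One forward/backward pass; returns (mean CE loss, batch accuracy).

        Parameter gradients are left in each layer's ``grads()`` buffers.
        """
        logits = self.forward(x)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        acc = float((probs.argmax(axis=1) == y).mean())
        n = x.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, acc

    def evaluate(self, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 64) -> tuple[float, float]:
        losses, hits, total = 0.0, 0, 0
        for i in range(0, len(x), batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            probs = self.predict_proba(xb)
            losses += -np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum()
            hits += int((probs.argmax(axis=1) == yb).sum())
            total += len(yb)
        return losses / total, hits / total

    # --- weights ---
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params():
                p[...] = next(it)

    def trainable_params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(zip(layer.params(), layer.grads()))
        return out

    def arch_spec(self) -> list[dict]:
        return [layer.spec() for layer in self.layers]

    @classmethod
    def from_arch_spec(cls, spec: list[dict]) -> "Sequential":
        layers = []
        for s in spec:
            if s["type"] not in _LAYER_TYPES:
                raise ValueError(f"unknown layer type {s['type']!r}")
            layers.append(_LAYER_TYPES[s["type"]](s))
        return cls(layers)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(params_and_grads):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_weights_h5(group: h5py.Group, model: Sequential) -> None:
    group.attrs["arch"] = json.dumps(model.arch_spec())
    for i, w in enumerate(model.get_weights()):
        group.create_dataset(f"w{i}", data=w)


def load_weights_h5(group: h5py.Group) -> Sequential:
    model = Sequential.from_arch_spec(json.loads(group.attrs["arch"]))
    n_expected = len(model.get_weights())
    weights = []
    for i in range(n_expected):
        if f"w{i}" not in group:
            raise ValueError(f"model file is missing weight tensor w{i}")
        weights.append(np.asarray(group[f"w{i}"]))
    model.set_weights(weights)
    return model
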