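"""Minimal seeded NumPy neural-network engine.

Layers (dense, 2-D convolution with same-padding, batch normalization,
dropout, spatial dropout, average pooling, flatten), ReLU/sigmoid/tanh
activations, softmax + categorical cross-entropy and sigmoid + binary
cross-entropy heads, and the Adam optimizer.  Everything draws from one
``numpy.random.Generator``, so training is bit-reproducible for a fixed
seed under single-threaded execution.

Shapes: dense layers take (N, D); convolutional layers take
(N, C, H, W) with stride 1 and same padding.  Batch normalization follows
the running-average convention ``running = momentum * running +
(1 - momentum) * batch`` and normalizes per feature (2-D input) or per
channel (4-D input).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

_EPS = 1e-7
_BN_EPS = 1e-3


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train, rng):
        if self.kind == "relu":
            self._y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-x))
        else:
            self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        if self.kind == "relu":
            return grad * (self._y > 0)
        if self.kind == "sigmoid":
            return grad * self._y * (1.0 - self._y)
        return grad * (1.0 - self._y ** 2)


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class SpatialDropout(Layer):
    """Drops whole channels of a (N, C, H, W) feature map."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        mask = (rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.rate)
        self._mask = mask / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Per-feature (2-D) or per-channel (4-D) batch normalization."""

    def __init__(self, dim: int, momentum: float = 0.99):
        self.momentum = momentum
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def _to2d(self, x):
        if x.ndim == 2:
            return x, None
        n, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1).reshape(-1, c), (n, c, h, w)

    def _from2d(self, y, shape):
        if shape is None:
            return y
        n, c, h, w = shape
        return y.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def forward(self, x, train, rng):
        x2, self._shape = self._to2d(x)
        if train:
            mu = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _BN_EPS)
        self._xn = (x2 - mu) / self._std
        return self._from2d(self.gamma * self._xn + self.beta, self._shape)

    def backward(self, grad):
        g2, shape = self._to2d(grad)
        n = g2.shape[0]
        self.dgamma[...] = (g2 * self._xn).sum(axis=0)
        self.dbeta[...] = g2.sum(axis=0)
        dx = (self.gamma / (n * self._std)) * (
            n * g2 - self.dbeta - self._xn * self.dgamma)
        return self._from2d(dx, shape)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


def _pad_same(x: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, tuple[int, int]]:
    ph, pw = kh - 1, kw - 1
    pads = ((0, 0), (0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    return np.pad(x, pads), (ph // 2, pw // 2)


class Conv2D(Layer):
    """Stride-1, same-padding 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int,
                 rng: np.random.Generator):
        fan_in = c_in * kh * kw
        self.kh, self.kw = kh, kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        xp, _ = _pad_same(x, self.kh, self.kw)
        cols = np.empty((n, c, self.kh, self.kw, h, w), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
        self._cols = cols.reshape(n, c * self.kh * self.kw, h * w)
        self._in_shape = (n, c, h, w)
        out = np.einsum("of,nfp->nop", self.W, self._cols) + self.b[:, None]
        return out.reshape(n, -1, h, w)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        g = grad.reshape(n, -1, h * w)
        self.dW[...] = np.einsum("nop,nfp->of", g, self._cols)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.W, g) \
            .reshape(n, c, self.kh, self.kw, h, w)
        ph, pw = self.kh - 1, self.kw - 1
        dxp = np.zeros((n, c, h + ph, w + pw))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, ph // 2:ph // 2 + h, pw // 2:pw // 2 + w]


class AvgPool2D(Layer):
    """Non-overlapping average pooling; trailing remainders are dropped."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise ValueError("feature map smaller than pooling window")
        self._in_shape = x.shape
        xt = x[:, :, : ho * self.ph, : wo * self.pw]
        return xt.reshape(n, c, ho, self.ph, wo, self.pw).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        ho, wo = h // self.ph, w // self.pw
        g = grad[:, :, :, None, :, None] / (self.ph * self.pw)
        g = np.broadcast_to(g, (n, c, ho, self.ph, wo, self.pw))
        dx = np.zeros((n, c, h, w))
        dx[:, :, : ho * self.ph, : wo * self.pw] = g.reshape(n, c, ho * self.ph,
                                                             wo * self.pw)
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CategoricalCrossEntropy:
    """Softmax head; targets are one-hot rows."""

    n_outputs_for = staticmethod(lambda n_classes: n_classes)

    def probs(self, z):
        return softmax(z)

    def loss_and_grad(self, z, y):
        p = softmax(z)
        loss = -np.mean(np.sum(y * np.log(p + _EPS), axis=1))
        return loss, (p - y) / z.shape[0]


class BinaryCrossEntropy:
    """Sigmoid head; targets are a (N, 1) column of 0/1."""

    n_outputs_for = staticmethod(lambda n_classes: 1)

    def probs(self, z):
        return 1.0 / (1.0 + np.exp(-z))

    def loss_and_grad(self, z, y):
        p = self.probs(z)
        loss = -np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS))
        return loss, (p - y) / z.shape[0]


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]):
        self.t += 1
        bc1 = 1 - self.beta1 ** self.t
        bc2 = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class Network:
    """A layer stack with a loss head, trained by mini-batch Adam."""

    def __init__(self, layers: Sequence[Layer],
                 loss: CategoricalCrossEntropy | BinaryCrossEntropy,
                 seed: int, lr: float = 1e-3):
        self.layers = list(layers)
        self.loss = loss
        self.rng = np.random.default_rng(seed)
        params = [p for l in self.layers for p in l.params]
        self.optimizer = Adam(params, lr=lr)
        self.fitted = False

    def _forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.loss.probs(self._forward(x[i:i + batch_size], train=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 256) -> float:
        total, n = 0.0, len(x)
        for i in range(0, n, batch_size):
            z = self._forward(x[i:i + batch_size], train=False)
            loss, _ = self.loss.loss_and_grad(z, y[i:i + batch_size])
            total += loss * len(z)
        return total / n

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            validation: tuple[np.ndarray, np.ndarray] | None = None,
            metric: Callable[["Network", np.ndarray, np.ndarray], float] | None = None,
            ) -> list[dict[str, float]]:
        """Train for exactly ``epochs`` epochs; returns the per-epoch history
        (train loss plus validation loss/metric when a validation set and a
        metric callback are given)."""
        params = [p for l in self.layers for p in l.params]
        grads = [g for l in self.layers for g in l.grads]
        history: list[dict[str, float]] = []
        n = len(x)
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                z = self._forward(x[idx], train=True)
                loss, dz = self.loss.loss_and_grad(z, y[idx])
                for layer in reversed(self.layers):
                    dz = layer.backward(dz)
                self.optimizer.step(params, grads)
                epoch_loss += loss * len(idx)
                seen += len(idx)
            row = {"epoch": float(epoch), "train_loss": epoch_loss / seen}
            if validation is not None:
                xv, yv = validation
                row["val_loss"] = self.evaluate_loss(xv, yv)
                if metric is not None:
                    row["val_metric"] = metric(self, xv, yv)
            history.append(row)
        self.fitted = True
        return history

    def weight_state(self) -> list[np.ndarray]:
        """Copies of every trainable array, for serialization/comparison."""
        return [p.copy() for l in self.layers for p in l.params]
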