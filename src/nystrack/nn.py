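"""Minimal numpy neural-network layer library with manual backpropagation.

Supports exactly what the pupil segmenter (2D U-Net) and the clip
classifiers (CNN1D, CNN-LSTM1D) need: channels-last convolutions, max
pooling, global average pooling, dense layers, batch normalisation, a
single-output LSTM, nearest-neighbour upsampling and the Adam optimiser.

Conventions
-----------
* 1D feature maps have shape ``(N, L, C)``; 2D maps ``(N, H, W, C)``.
* Every layer exposes ``params`` / ``grads`` (parallel lists of arrays),
  ``forward(x, train=True)`` and ``backward(grad)``. ``backward`` must be
  called with the same batch that was last forwarded.
* Parameters are float32 by default; ``dtype=np.float64`` is available so
  gradients can be verified against finite differences in tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "Sigmoid", "BatchNorm", "Conv1D", "MaxPool1D",
    "GlobalAvgPool1D", "LSTM", "Conv2D", "MaxPool2D", "Upsample2D",
    "Sequential", "Adam", "sigmoid",
    "bce_with_logits", "mae_on_sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.result_type(z, np.float32))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class; stateless layers reuse these empty param lists.

    ``buffers`` holds non-trainable state (e.g. batch-norm running moments)
    that must travel with the weights when a model is copied or saved.
    """

    params: list[np.ndarray]
    grads: list[np.ndarray]
    buffers: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []
        self.buffers = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# dense / pointwise
# ---------------------------------------------------------------------------

class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class BatchNorm(Layer):
    """Batch normalisation over the leading (batch) axis of ``(N, F)``."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.buffers = [self.running_mean, self.running_var]
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.grads[0][...] = (grad * self._xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        gx = grad * self.gamma
        return self._istd * (gx - gx.mean(axis=0)
                             - self._xhat * (gx * self._xhat).mean(axis=0))


# ---------------------------------------------------------------------------
# 1D convolutional stack
# ---------------------------------------------------------------------------

class Conv1D(Layer):
    """'Same'-padded 1D convolution on ``(N, L, C)`` maps."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (kernel_size * c_in))
        self.W = (rng.standard_normal((kernel_size * c_in, c_out))
                  * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        n, length, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (N, L, C, k) -> (N, L, k, C) so W rows are ordered tap-major
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        self._cols = cols.reshape(n * length, self.k * c)
        self._shape = (n, length, c)
        out = self._cols @ self.W + self.b
        return out.reshape(n, length, self.c_out)

    def backward(self, grad):
        n, length, c = self._shape
        g = grad.reshape(n * length, self.c_out)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, length, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, length + 2 * p, c), dtype=grad.dtype)
        for tap in range(self.k):
            dxp[:, tap:tap + length, :] += dcols[:, :, tap, :]
        return dxp[:, p:p + length, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=True):
        n, length, c = x.shape
        if length % self.pool:
            raise ValueError(f"length {length} not divisible by {self.pool}")
        xr = x.reshape(n, length // self.pool, self.pool, c)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, length, c = self._shape
        dxr = np.zeros((n, length // self.pool, self.pool, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], grad[:, :, None, :],
                          axis=2)
        return dxr.reshape(n, length, c)


class GlobalAvgPool1D(Layer):
    """Mean over the time axis: ``(N, L, C) -> (N, C)``."""

    def forward(self, x, train=True):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class LSTM(Layer):
    """Single LSTM layer returning the last hidden state ``(N, U)``.

    Gate order in the packed weight matrices is input, forget, cell, output;
    the forget-gate bias is initialised to one.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.units = units
        sx = np.sqrt(1.0 / n_in)
        sh = np.sqrt(1.0 / units)
        self.Wx = (rng.standard_normal((n_in, 4 * units)) * sx).astype(dtype)
        self.Wh = (rng.standard_normal((units, 4 * units)) * sh).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units:2 * units] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=True):
        n, steps, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        for t in range(steps):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h

    def backward(self, grad):
        x = self._x
        n, steps, _ = x.shape
        u = self.units
        for gbuf in self.grads:
            gbuf[...] = 0.0
        dx = np.zeros_like(x)
        dh = grad
        dc = np.zeros((n, u), dtype=grad.dtype)
        for t in range(steps - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.grads[0] += x[:, t, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


# ---------------------------------------------------------------------------
# 2D convolutional stack (U-Net building blocks)
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """'Same'-padded square 2D convolution on ``(N, H, W, C)`` maps."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel_size * kernel_size * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((fan_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C): rows ordered tap-major
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(n * h * w, k * k * c)
        self._shape = (n, h, w, c)
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad):
        n, h, w, c = self._shape
        k, p = self.k, self.k // 2
        g = grad.reshape(n * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for ky in range(k):
            for kx in range(k):
                dxp[:, ky:ky + h, kx:kx + w, :] += dcols[:, :, :, ky, kx, :]
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool2D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        p = self.pool
        if h % p or w % p:
            raise ValueError(f"spatial size {(h, w)} not divisible by {p}")
        xr = x.reshape(n, h // p, p, w // p, p, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // p, w // p, c, p * p)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, h, w, c = self._shape
        p = self.pool
        dxr = np.zeros((n, h // p, w // p, c, p * p), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(n, h // p, w // p, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class Upsample2D(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x, train=True):
        f = self.factor
        return x.repeat(f, axis=1).repeat(f, axis=2)

    def backward(self, grad):
        n, h, w, c = grad.shape
        f = self.factor
        gr = grad.reshape(n, h // f, f, w // f, f, c)
        return gr.sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# containers, losses, optimiser
# ---------------------------------------------------------------------------

class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def _state(self):
        buffers = [b for layer in self.layers for b in layer.buffers]
        return self.parameters() + buffers

    def get_weights(self):
        """Trainable parameters followed by non-trainable buffers."""
        return [p.copy() for p in self._state()]

    def set_weights(self, weights):
        for p, w in zip(self._state(), weights, strict=True):
            p[...] = w


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(z.dtype)


def mae_on_sigmoid(logits: np.ndarray, targets: np.ndarray):
    """Mean absolute error between sigmoid(logits) and binary targets.

    Returns (loss, dloss/dlogits).
    """
    p = sigmoid(logits)
    err = p - targets
    loss = float(np.abs(err).mean())
    grad = np.sign(err) * p * (1.0 - p) / logits.size
    return loss, grad.astype(logits.dtype)


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
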