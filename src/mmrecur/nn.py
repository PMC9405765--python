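"""Minimal numpy neural-network layers with manual backpropagation.

Just enough machinery for the imaging branch: 2D/3D convolutions (im2col),
batch normalization, ReLU, max/global-average pooling, dense layers, residual
blocks, a sigmoid/binary-cross-entropy head and Adam. Everything is plain
numpy with explicit ``forward``/``backward`` methods, seeded He
initialization, and therefore bit-deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Compute dtype of the whole backend; single precision halves memory traffic
#: in the im2col convolutions and is ample for these small networks.
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Conv2d(Layer):
    """3x3 (or kxk) convolution with stride and same-style padding via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # n,c,ho,wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class Conv3d(Layer):
    """Small 3D convolution over (depth, height, width), stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int], rng: np.random.Generator):
        kd, kh, kw = kernel
        scale = np.sqrt(2.0 / (c_in * kd * kh * kw))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in * kd * kh * kw)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        n, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))  # n,c,do,ho,wo,kd,kh,kw
        do, ho, wo = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * kd * kh * kw)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, do, ho, wo)
        return out.reshape(n, do, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        cols, xshape, do, ho, wo = self._cache
        n, c, d, h, w = xshape
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        g = grad.transpose(0, 2, 3, 4, 1).reshape(n * do * ho * wo, self.c_out)
        self.W.grad += g.T @ cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value).reshape(n, do, ho, wo, c, kd, kh, kw)
        dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n, c, d + 2 * pd, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
        for a in range(kd):
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, a : a + do, i : i + ho, j : j + wo] += dcols[:, :, :, :, :, a, i, j]
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) / self._std.reshape(sh)
        self._axes, self._sh = axes, sh
        self._n = x.size // x.shape[1]
        return self.gamma.value.reshape(sh) * self._xhat + self.beta.value.reshape(sh)

    def backward(self, grad):
        axes, sh, n = self._axes, self._sh, self._n
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value.reshape(sh)
        mean_g = gxhat.mean(axis=axes).reshape(sh)
        mean_gx = (gxhat * self._xhat).mean(axis=axes).reshape(sh)
        return (gxhat - mean_g - self._xhat * mean_gx) / self._std.reshape(sh)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "max pooling expects even spatial dims"
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        self._mask = r == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Average over every axis after the channel axis."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        shape = self._shape
        n_spatial = int(np.prod(shape[2:]))
        g = grad.reshape(shape[:2] + (1,) * (len(shape) - 2))
        return np.broadcast_to(g / n_spatial, shape).copy()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus identity (or 1x1-conv projection) skip."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm(c_out)
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj: Sequential | None = Sequential(
                [Conv2d(c_in, c_out, 1, stride, 0, rng), BatchNorm(c_out)]
            )
        else:
            self.proj = None

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=True):
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train),
                train,
            ),
            train,
        )
        skip = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu_out.forward(main + skip, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g_skip = self.proj.backward(grad) if self.proj is not None else grad
        g = self.bn2.backward(grad)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return g + g_skip


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.ravel()
    y = labels.ravel().astype(np.float64)
    w = np.ones_like(z) if weights is None else weights.ravel()
    # softplus(z) - y*z, numerically stable
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    total_w = w.sum()
    grad = (w * (sigmoid(z) - y) / total_w).reshape(logits.shape)
    return float((w * loss).sum() / total_w), grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def param_checksum(params: list[Param]) -> float:
    """Order-dependent scalar summary of all parameter values (determinism checks)."""
    return float(sum(np.sum(p.value * (i + 1)) for i, p in enumerate(params)))
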