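"""Minimal CPU neural-network primitives (forward + backward) on numpy.

Implements exactly the layer set the restoration networks need: strided 3x3
convolution with reflective padding, 2x2 stride-2 transposed convolution,
batch normalization, ReLU, 2x2 max pooling, dropout, channel concatenation,
plus the Adam optimizer.  Convolutions are lowered to matrix products
(im2col) so the heavy lifting runs in BLAS; everything is float32.

Layers are single-use per forward pass: each caches what its backward pass
needs, and ``backward`` must mirror the most recent ``forward``.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient accumulator.

    ``penalized`` marks parameters subject to the l2 penalty (convolution
    weights); biases and batch-norm scale/offset are not penalized.
    """

    def __init__(self, value: np.ndarray, name: str = "", penalized: bool = False):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.penalized = penalized

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state to persist in checkpoints (e.g. BN running stats)."""
        return {}


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """2D convolution, stride ``s``, symmetric (edge-excluding) padding."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        self.weight = Param(_uniform_init(rng, (c_out, c_in, ksize, ksize), fan_in),
                            name=f"{name}.weight", penalized=True)
        self.bias = Param(_uniform_init(rng, (c_out,), fan_in), name=f"{name}.bias")
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        if p > 0:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
        else:
            xp = x
        b, c, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (b, c, ho, wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * ho * wo, c * k * k)
        wmat = self.weight.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape, (b, ho, wo))
        return np.ascontiguousarray(out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (b, ho, wo) = self._cache
        k, s, p = self.ksize, self.stride, self.pad
        c = self.c_in
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(b * ho * wo, self.c_out)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.weight.value.reshape(self.c_out, -1)).reshape(b, ho, wo, c, k, k)
        hgt, wid = xshape[2], xshape[3]
        dpad = np.zeros((b, c, hgt + 2 * p, wid + 2 * p), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                dpad[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p == 0:
            return dpad
        dx = np.ascontiguousarray(dpad[:, :, p:-p, p:-p])
        # fold reflected borders back: padded row p-1-i mirrors input row i+1
        for i in range(p):
            dx[:, :, i + 1, :] += dpad[:, :, p - 1 - i, p:-p]
            dx[:, :, -(i + 2), :] += dpad[:, :, -(p - i), p:-p]
            dx[:, :, :, i + 1] += dpad[:, :, p:-p, p - 1 - i]
            dx[:, :, :, -(i + 2)] += dpad[:, :, p:-p, -(p - i)]
            # corners mirror on both axes
            dx[:, :, i + 1, i + 1] += dpad[:, :, p - 1 - i, p - 1 - i]
            dx[:, :, i + 1, -(i + 2)] += dpad[:, :, p - 1 - i, -(p - i)]
            dx[:, :, -(i + 2), i + 1] += dpad[:, :, -(p - i), p - 1 - i]
            dx[:, :, -(i + 2), -(i + 2)] += dpad[:, :, -(p - i), -(p - i)]
        return dx


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel size equal to stride (no overlap)."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 2, stride: int = 2,
                 rng: np.random.Generator | None = None, name: str = "upconv"):
        if ksize != stride:
            raise ValueError("only kernel == stride supported")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        self.weight = Param(_uniform_init(rng, (c_in, c_out, ksize, ksize), fan_in),
                            name=f"{name}.weight", penalized=True)
        self.bias = Param(_uniform_init(rng, (c_out,), fan_in), name=f"{name}.bias")
        self.ksize = ksize
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k = self.ksize
        b, c, h, w = x.shape
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(b * h * w, c)
        t = xt @ self.weight.value.reshape(c, -1)          # (bhw, c_out*k*k)
        t = t.reshape(b, h, w, self.c_out, k, k)
        # out[b, o, k*i+ki, k*j+kj] = t[b, i, j, o, ki, kj]
        out = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
            b, self.c_out, h * k, w * k)
        out += self.bias.value[None, :, None, None]
        self._cache = (xt, (b, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xt, (b, c, h, w) = self._cache
        k = self.ksize
        dt = np.ascontiguousarray(
            dout.reshape(b, self.c_out, h, k, w, k).transpose(0, 2, 4, 1, 3, 5)
        ).reshape(b * h * w, self.c_out * k * k)
        self.weight.grad += (xt.T @ dt).reshape(self.weight.value.shape)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        dx = dt @ self.weight.value.reshape(c, -1).T        # (bhw, c)
        return np.ascontiguousarray(
            dx.reshape(b, h, w, c).transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c, dtype=DTYPE), name=f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=DTYPE), name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps, self.c = momentum, eps, c
        self.name = name
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not training:
            return (dout * g).astype(DTYPE)
        n = shape[0] * shape[2] * shape[3]
        return (g * (dout - dbeta[None, :, None, None] / n
                     - xhat * dgamma[None, :, None, None] / n)).astype(DTYPE)


class ReLU(Layer):
    """Rectifier; mutates its (always freshly allocated) input in place."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = np.maximum(x, 0, out=x)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * (self._out > 0)
        return dout.astype(DTYPE, copy=False)


class MaxPool2d(Layer):
    def __init__(self, ksize: int = 2):
        self.ksize = ksize

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k = self.ksize
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // k, k, w // k, k)
        out = xr.max(axis=(3, 5))
        self._cache = (xr, out, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out, xshape = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # split gradient evenly among tied maxima so the pool stays exact
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (dout[:, :, :, None, :, None] / counts)
        return dxr.reshape(xshape).astype(DTYPE)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(DTYPE)


class Adam:
    """Adam with decoupled-from-nothing, classic gradient-coupled l2.

    The l2 penalty ``lam * sum(w^2)`` over penalized parameters contributes
    ``2 lam w`` to the gradient before the moment updates.
    """

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, l2_lambda: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2_lambda = l2_lambda
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2_lambda and p.penalized:
                g = g + 2.0 * self.l2_lambda * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
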