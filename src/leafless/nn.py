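"""Minimal convolutional network engine with manual backpropagation.

This is a deliberately small, dependency-free training engine: strided
convolutions and transposed convolutions via im2col/col2im, leaky ReLU /
ReLU / tanh activations, instance normalisation and an Adam optimiser —
exactly the pieces the encoder–decoder generator and the patch
discriminator need.  Everything runs in float32 on plain numpy arrays of
shape (N, C, H, W) and is fully deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i: i + stride * oh: stride,
                                  j: j + stride * ow: stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`; scatter-adds patches back onto the grid."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i: i + stride * oh: stride,
               j: j + stride * ow: stride] += cols6[:, :, i, j]
    return xp[:, :, pad: pad + h, pad: pad + w]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, rng, k: int = 4, stride: int = 2,
                 pad: int = 1):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.w = Param(_he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,ncp->nop", self.w.value, self._cols, optimize=True)
        n = x.shape[0]
        oh = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        ow = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        return out.reshape(n, self.cout, oh, ow) + self.b.value[None, :, None, None]

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.cout, -1)
        self.b.grad += dflat.sum(axis=(0, 2))
        self.w.grad += np.einsum("nop,ncp->oc", dflat, self._cols, optimize=True)
        dcols = np.einsum("oc,nop->ncp", self.w.value, dflat, optimize=True)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution (the adjoint of :class:`Conv2d`)."""

    def __init__(self, cin: int, cout: int, rng, k: int = 4, stride: int = 2,
                 pad: int = 1):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.w = Param(_he_init(rng, (cin, cout * k * k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def _out_shape(self, n, h, w):
        oh = (h - 1) * self.stride - 2 * self.pad + self.k
        ow = (w - 1) * self.stride - 2 * self.pad + self.k
        return (n, self.cout, oh, ow)

    def forward(self, x):
        n, c, h, w = x.shape
        self._spatial = (h, w)
        self._x = x.reshape(n, c, h * w)
        out_shape = self._out_shape(n, h, w)
        cols = np.einsum("cf,ncp->nfp", self.w.value, self._x, optimize=True)
        out = col2im(cols, out_shape, self.k, self.stride, self.pad)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dcols = im2col(dout, self.k, self.stride, self.pad)
        self.w.grad += np.einsum("ncp,nfp->cf", self._x, dcols, optimize=True)
        dx = np.einsum("cf,nfp->ncp", self.w.value, dcols, optimize=True)
        n_, c_, _ = dx.shape
        return dx.reshape(n_, c_, *self._spatial)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation with learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value[None, :, None, None] * self._xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, dout):
        m = dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        return (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(2, 3), keepdims=True)
                ) / self._std


class Upsample2x(Layer):
    """Parameter-free upsampling; bilinear by default, used by the
    checkerboard-suppressing decoder variant."""

    def __init__(self, mode: str = "bilinear"):
        if mode not in ("nearest", "bilinear"):
            raise ValueError("mode must be 'nearest' or 'bilinear'")
        self.mode = mode

    def _weights(self, h):
        # linear interpolation weights for 2x upsampling, align_corners=False
        src = (np.arange(2 * h) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, h - 1)
        i1 = np.clip(i0 + 1, 0, h - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        return i0, i1, frac.astype(np.float32)

    def forward(self, x):
        self._in_shape = x.shape
        n, c, h, w = x.shape
        if self.mode == "nearest":
            return x.repeat(2, axis=2).repeat(2, axis=3)
        r0, r1, rf = self._weights(h)
        c0, c1, cf = self._weights(w)
        self._cache = (r0, r1, rf, c0, c1, cf)
        top = x[:, :, r0][:, :, :, c0] * (1 - rf)[None, None, :, None] \
            + x[:, :, r1][:, :, :, c0] * rf[None, None, :, None]
        bot = x[:, :, r0][:, :, :, c1] * (1 - rf)[None, None, :, None] \
            + x[:, :, r1][:, :, :, c1] * rf[None, None, :, None]
        return top * (1 - cf)[None, None, None, :] + bot * cf[None, None, None, :]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        if self.mode == "nearest":
            return dout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        r0, r1, rf, c0, c1, cf = self._cache
        for (ri, rw) in ((r0, 1 - rf), (r1, rf)):
            for (ci, cw) in ((c0, 1 - cf), (c1, cf)):
                contrib = dout * rw[None, None, :, None] * cw[None, None, None, :]
                np.add.at(dx, (slice(None), slice(None), ri[:, None], ci[None, :]),
                          contrib)
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Param], lr: float = 4e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def mse_to_label(scores: np.ndarray, label: float) -> float:
    """Mean squared error of a score tensor against a constant 0/1 label."""
    return float(np.mean((scores - label) ** 2))


def mse_to_label_grad(scores: np.ndarray, label: float) -> np.ndarray:
    return (2.0 / scores.size) * (scores - label)


def l1_loss(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference."""
    return float(np.mean(np.abs(a - b)))


def l1_loss_grad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gradient of the mean absolute difference with respect to ``a``."""
    return np.sign(a - b) / a.size
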