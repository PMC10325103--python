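"""Minimal neural-network layers on NumPy with explicit backward passes.

The library covers exactly what the ac-GAN and the evaluation classifiers
need: strided 2-D convolution and transposed convolution, batch
normalization, a fully connected layer, and the usual activations. Forward
passes operate on float32 arrays of shape (N, C, H, W); every layer caches
what its backward pass needs and accumulates parameter gradients into
``Parameter.grad``.

Convolutions are computed as a sum over the k*k kernel offsets, each offset
handled by one vectorized ``einsum`` over the batch — fast enough at the
32-64 pixel scales used here and simple enough to gradient-check.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batchnorm running moments)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    """Spatial size after a convolution: floor((in + 2p - k)/s) + 1."""
    return (size + 2 * padding - kernel) // stride + 1


def deconv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    """Spatial size after a transposed convolution: (in-1)*s - 2p + k."""
    return (size - 1) * stride - 2 * padding + kernel


class Conv2d(Layer):
    """2-D convolution, weight shape (C_out, C_in, k, k), DCGAN init N(0, 0.02)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, bias: bool = True):
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(rng.normal(0.0, 0.02, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        n, _, h, w = x.shape
        ho, wo = conv_out_size(h, k, s, p), conv_out_size(w, k, s, p)
        if ho <= 0 or wo <= 0:
            raise ValueError(
                f"Conv2d produces non-positive output size from input {h}x{w} "
                f"(kernel {k}, stride {s}, padding {p})"
            )
        xp = _pad2d(x, p)
        self._xp_shape = xp.shape
        self._xp = xp
        out = np.zeros((n, self.c_out, ho, wo))
        W = self.weight.data
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + s * ho:s, v:v + s * wo:s]
                out += np.einsum("oc,nchw->nohw", W[:, :, u, v], xs, optimize=True)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        xp = self._xp
        n, _, hp, wp = xp.shape
        ho, wo = dy.shape[2], dy.shape[3]
        W = self.weight.data
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + s * ho:s, v:v + s * wo:s]
                self.weight.grad[:, :, u, v] += np.einsum(
                    "nohw,nchw->oc", dy, xs, optimize=True)
                dxp[:, :, u:u + s * ho:s, v:v + s * wo:s] += np.einsum(
                    "oc,nohw->nchw", W[:, :, u, v], dy, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Layer):
    """2-D transposed convolution, weight shape (C_in, C_out, k, k)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, bias: bool = True):
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(rng.normal(0.0, 0.02, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        n, _, h, w = x.shape
        ho, wo = deconv_out_size(h, k, s, p), deconv_out_size(w, k, s, p)
        if ho <= 0 or wo <= 0:
            raise ValueError(
                f"ConvTranspose2d produces non-positive output size from input "
                f"{h}x{w} (kernel {k}, stride {s}, padding {p})"
            )
        self._x = x
        W = self.weight.data
        yp = np.zeros((n, self.c_out, ho + 2 * p, wo + 2 * p))
        for u in range(k):
            for v in range(k):
                yp[:, :, u:u + s * h:s, v:v + s * w:s] += np.einsum(
                    "co,nchw->nohw", W[:, :, u, v], x, optimize=True)
        y = yp[:, :, p:-p, p:-p] if p else yp
        if self.bias is not None:
            y = y + self.bias.data[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        x = self._x
        n, _, h, w = x.shape
        dyp = _pad2d(dy, p)
        W = self.weight.data
        dx = np.zeros_like(x)
        for u in range(k):
            for v in range(k):
                dys = dyp[:, :, u:u + s * h:s, v:v + s * w:s]
                dx += np.einsum("co,nohw->nchw", W[:, :, u, v], dys, optimize=True)
                self.weight.grad[:, :, u, v] += np.einsum(
                    "nchw,nohw->co", x, dys, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train_n = xhat, inv, x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        g = self.gamma.data
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g[None, :, None, None]
        if not self._train:
            return dxhat * inv[None, :, None, None]
        m = self._train_n
        # standard batchnorm backward through batch mean and variance
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class Linear(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, (f_out, f_in)))
        self.bias = Parameter(np.zeros(f_out))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y ** 2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + \
            [b.copy() for b in self.buffers()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params, bufs = self.parameters(), self.buffers()
        if len(state) != len(params) + len(bufs):
            raise ValueError("state length does not match parameter/buffer count")
        for p, s in zip(params, state):
            p.data[...] = s
        for b, s in zip(bufs, state[len(params):]):
            b[...] = s
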