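"""Minimal convolutional-network framework (numpy).

Layers implement ``forward``/``backward`` with explicit caches, expose their
parameters as :class:`Param` objects, and are composed by :class:`Sequential`.
The framework is deliberately small: exactly the pieces needed for the
twin-subnetwork models in this package (3x3 convolutions, ReLU, residual
blocks, global average pooling, a linear head) plus an Adam optimizer.
There are no stochastic layers, so evaluation is deterministic by
construction once weights are fixed.

All tensors are ``(N, C, H, W)`` float arrays; the dtype is set at
initialization (float32 by default, float64 for gradient checking).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "ResidualBlock",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "im2col",
    "col2im",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold k x k patches of ``x`` (N,C,H,W) into (N, C*k*k, H_out*W_out)."""
    n, c, h, w = x.shape
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h_out, w_out), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride]
    return cols.reshape(n, c * k * k, h_out * w_out)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back to image layout."""
    n, c, h, w = x_shape
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, h_out, w_out)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += cols6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> dict[str, Param]:
        return {}


class Conv2d(Layer):
    """3x3-style convolution via im2col; He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, pad: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Param((rng.standard_normal((c_out, c_in, k, k)) * scale).astype(dtype))
        self.bias = Param(np.zeros(c_out, dtype=dtype))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        cols = im2col(x, self.k, self.stride, self.pad)
        w2 = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = np.einsum("ok,nkl->nol", w2, cols, optimize=True) + self.bias.value[None, :, None]
        h_out = (h + 2 * self.pad - self.k) // self.stride + 1
        w_out = (w + 2 * self.pad - self.k) // self.stride + 1
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h_out, w_out)

    def backward(self, grad):
        cols, x_shape = self._cache
        n = grad.shape[0]
        g2 = grad.reshape(n, grad.shape[1], -1)
        w2 = self.weight.value.reshape(self.weight.value.shape[0], -1)
        self.weight.grad += np.einsum("nol,nkl->ok", g2, cols, optimize=True).reshape(self.weight.value.shape)
        self.bias.grad += g2.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", w2, g2, optimize=True)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def params(self):
        return {"weight": self.weight, "bias": self.bias}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ResidualBlock(Layer):
    """Two 3x3 convolutions with a skip connection (identity shortcut).

    Channel count and spatial size are preserved, so no projection is needed.
    """

    def __init__(self, channels: int, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu2 = ReLU()

    def forward(self, x):
        out = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(out + x)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx + g

    def params(self):
        out = {}
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for pname, p in layer.params().items():
                out[f"{name}.{pname}"] = p
        return out


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Param((rng.standard_normal((n_out, n_in)) * scale).astype(dtype))
        self.bias = Param(np.zeros(n_out, dtype=dtype))

    def forward(self, x):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value

    def params(self):
        return {"weight": self.weight, "bias": self.bias}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def zero_grad(self):
        for p in self.params().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(state) != set(params):
            raise ValueError("state dict does not match model parameters")
        for name, value in state.items():
            p = params[name]
            if p.value.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value[...] = value


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
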