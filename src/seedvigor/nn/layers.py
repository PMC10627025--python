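"""Minimal 1D neural-network layers with explicit forward/backward passes.

All layers consume arrays shaped ``(N, C, L)`` (batch, channels, spectral
length) except the dense tail, which works on ``(N, F)``. Each layer owns its
parameters as :class:`Param` objects and caches whatever its backward pass
needs. Everything is plain float64 NumPy and fully deterministic given the
random generators passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Linear",
]


class Param:
    """A trainable tensor plus its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless a subclass adds parameters/buffers."""

    #: frozen layers are skipped by optimizers and keep buffers fixed
    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # buffers (e.g. BN running stats) that belong in a state dict
    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv1d(Layer):
    """Valid (no padding) 1D convolution, stride 1.

    Weight shape ``(out_channels, in_channels, kernel)``; He-uniform init.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 4,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.kernel = kernel
        self.weight = Param(f"{name}.weight",
                            rng.uniform(-bound, bound, (out_channels, in_channels, kernel)))
        self.bias = Param(f"{name}.bias", np.zeros(out_channels))
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x, training=False, rng=None):
        k = self.kernel
        if x.shape[-1] < k:
            raise ValueError(f"input length {x.shape[-1]} shorter than kernel {k}")
        # windows: (N, C_in, L_out, K)
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)
        out = np.einsum("nclk,ock->nol", windows, self.weight.value, optimize=True)
        out += self.bias.value[None, :, None]
        self._cache = x
        return out

    def backward(self, grad_out):
        x = self._cache
        k = self.kernel
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)
        self.weight.grad += np.einsum("nclk,nol->ock", windows, grad_out, optimize=True)
        self.bias.grad += grad_out.sum(axis=(0, 2))
        grad_in = np.zeros_like(x)
        l_out = grad_out.shape[-1]
        for j in range(k):
            grad_in[:, :, j:j + l_out] += np.einsum(
                "nol,oc->ncl", grad_out, self.weight.value[:, :, j], optimize=True)
        return grad_in


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (batch, length) axes.

    Frozen layers normalise with the stored running statistics even in
    training mode, so a frozen backbone is bit-stable under further training.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self):
        return {self.gamma.name.rsplit(".", 1)[0] + ".running_mean": self.running_mean,
                self.gamma.name.rsplit(".", 1)[0] + ".running_var": self.running_var}

    def forward(self, x, training=False, rng=None):
        use_batch = training and self.trainable
        if use_batch:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, use_batch)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad_out):
        xhat, inv, use_batch = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2))
        self.beta.grad += grad_out.sum(axis=(0, 2))
        g = grad_out * self.gamma.value[None, :, None]
        if not use_batch:
            return g * inv[None, :, None]
        m = xhat.shape[0] * xhat.shape[2]
        sum_g = g.sum(axis=(0, 2), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return inv[None, :, None] / m * (m * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return grad_out * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling, kernel = stride = 2; trailing odd element dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel
        self._cache = None

    def forward(self, x, training=False, rng=None):
        k = self.kernel
        n, c, l = x.shape
        l_out = l // k
        xr = x[:, :, :l_out * k].reshape(n, c, l_out, k)
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, grad_out):
        shape, arg = self._cache
        n, c, l = shape
        k = self.kernel
        l_out = l // k
        grad = np.zeros((n, c, l_out, k))
        np.put_along_axis(grad, arg[..., None], grad_out[..., None], axis=-1)
        out = np.zeros(shape)
        out[:, :, :l_out * k] = grad.reshape(n, c, l_out * k)
        return out


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float = 0.4):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / in_features)
        self.weight = Param(f"{name}.weight",
                            rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Param(f"{name}.bias", np.zeros(out_features))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False, rng=None):
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad_out):
        x = self._cache
        self.weight.grad += grad_out.T @ x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value
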