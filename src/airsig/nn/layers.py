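"""Layers. Sequence tensors are (batch, length, channels); dense tensors (batch, features)."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from airsig.errors import ConfigError


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base layer: forward caches whatever backward needs; backward returns dL/dx."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> Iterator[Parameter]:
        for value in vars(self).values():
            yield from _params_of(value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _params_of(value) -> Iterator[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _params_of(item)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, training=False):
        for mod in self.modules:
            x = mod.forward(x, training=training)
        return x

    def backward(self, grad):
        for mod in reversed(self.modules):
            grad = mod.backward(grad)
        return grad


class Conv1d(Module):
    """1-D convolution over the length axis via im2col.

    padding 'same' keeps the output length equal to the input length;
    'valid' shrinks it by kernel-1 and raises a shape error if it would
    drop below 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: str = "same", bias: bool = True,
                 rng: Optional[np.random.Generator] = None, name: str = "conv"):
        if padding not in ("same", "valid"):
            raise ConfigError(f"{name}: padding must be 'same' or 'valid'")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * in_channels))
        self.w = Parameter(rng.normal(0.0, std, size=(kernel, in_channels, out_channels)))
        self.b = Parameter(np.zeros(out_channels)) if bias else None
        self.kernel = kernel
        self.padding = padding
        self.name = name

    def forward(self, x, training=False):
        n, length, c_in = x.shape
        k = self.kernel
        if self.padding == "same":
            left = (k - 1) // 2
            xp = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
        else:
            xp = x
        l_out = xp.shape[1] - k + 1
        if l_out < 1:
            raise ConfigError(
                f"layer {self.name!r}: input length {length} too short for kernel {k} (valid padding)"
            )
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (n, l_out, c, k)
        cols = windows.transpose(0, 1, 3, 2).reshape(n * l_out, k * c_in)
        y = cols @ self.w.value.reshape(k * c_in, -1)
        if self.b is not None:
            y += self.b.value
        self._cache = (cols, xp.shape, n, l_out, c_in)
        return y.reshape(n, l_out, -1)

    def backward(self, grad):
        cols, xp_shape, n, l_out, c_in = self._cache
        k = self.kernel
        gf = grad.reshape(n * l_out, -1)
        self.w.grad += (cols.T @ gf).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += gf.sum(axis=0)
        dcols = (gf @ self.w.value.reshape(k * c_in, -1).T).reshape(n, l_out, k, c_in)
        dxp = np.zeros(xp_shape)
        for t in range(k):
            dxp[:, t:t + l_out, :] += dcols[:, :, t, :]
        if self.padding == "same":
            left = (k - 1) // 2
            length = xp_shape[1] - (k - 1)
            return dxp[:, left:left + length, :]
        return dxp


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.b = Parameter(np.zeros(out_features))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class PReLU(Module):
    """Parametric rectifier with one learnable slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        self.a = Parameter(np.full(channels, init))

    def forward(self, x, training=False):
        self._x = x
        return np.where(x > 0, x, self.a.value * x)

    def backward(self, grad):
        x = self._x
        neg = x <= 0
        axes = tuple(range(x.ndim - 1))
        self.a.grad += (grad * x * neg).sum(axis=axes)
        return grad * np.where(neg, self.a.value, 1.0)


class BatchNorm1d(Module):
    """Normalizes each channel over (batch, length); running stats for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, training = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not training:
            return g * inv
        m = np.prod([xhat.shape[a] for a in axes])
        return (inv / m) * (m * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes))


class InstanceNorm1d(Module):
    """Normalizes each (sample, channel) over the length axis; affine per channel."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x, training=False):
        mean = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        g = grad * self.gamma.value
        length = xhat.shape[1]
        return (inv / length) * (
            length * g
            - g.sum(axis=1, keepdims=True)
            - xhat * (g * xhat).sum(axis=1, keepdims=True)
        )


class MaxPool1d(Module):
    """Max pooling; padding 'same' (with -inf fill) keeps ceil(L/stride) outputs."""

    def __init__(self, kernel: int, stride: int, padding: str = "valid", name: str = "maxpool"):
        self.kernel, self.stride, self.padding, self.name = kernel, stride, padding, name

    def forward(self, x, training=False):
        n, length, c = x.shape
        k, s = self.kernel, self.stride
        if self.padding == "same":
            l_out = int(np.ceil(length / s))
            needed = (l_out - 1) * s + k
            left = (needed - length) // 2
            xp = np.pad(x, ((0, 0), (left, needed - length - left), (0, 0)),
                        constant_values=-np.inf)
        else:
            left = 0
            xp = x
            if length < k:
                raise ConfigError(f"layer {self.name!r}: input length {length} < kernel {k}")
            l_out = (length - k) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)[:, ::s]  # (n,l_out,c,k)
        idx = windows.argmax(axis=3)
        y = np.take_along_axis(windows, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, xp.shape, left, length, l_out)
        return y

    def backward(self, grad):
        idx, xp_shape, left, length, l_out = self._cache
        n, _, c = xp_shape
        dxp = np.zeros(xp_shape)
        ni, wi, ci = np.ogrid[:n, :l_out, :c]
        np.add.at(dxp, (ni, wi * self.stride + idx, ci), grad)
        return dxp[:, left:left + length, :]


class AvgPool1d(Module):
    def __init__(self, kernel: int, stride: int, name: str = "avgpool"):
        self.kernel, self.stride, self.name = kernel, stride, name

    def forward(self, x, training=False):
        n, length, c = x.shape
        k, s = self.kernel, self.stride
        if length < k:
            raise ConfigError(f"layer {self.name!r}: input length {length} < kernel {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)[:, ::s]
        self._cache = (x.shape, windows.shape[1])
        return windows.mean(axis=3)

    def backward(self, grad):
        x_shape, l_out = self._cache
        k, s = self.kernel, self.stride
        dx = np.zeros(x_shape)
        for t in range(k):
            np.add.at(dx, (slice(None), np.arange(l_out) * s + t, slice(None)), grad / k)
        return dx


class GlobalAvgPool(Module):
    """(batch, length, channels) -> (batch, channels)."""

    def forward(self, x, training=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class TimeSoftmaxAttention(Module):
    """Split channels in half; softmax the first half over time and use it to
    weight-and-sum the second half: (batch, L, 2C) -> (batch, C)."""

    def forward(self, x, training=False):
        half = x.shape[2] // 2
        h1, h2 = x[:, :, :half], x[:, :, half:]
        z = h1 - h1.max(axis=1, keepdims=True)
        e = np.exp(z)
        a = e / e.sum(axis=1, keepdims=True)
        self._cache = (a, h2, half)
        return (a * h2).sum(axis=1)

    def backward(self, grad):
        a, h2, half = self._cache
        g = grad[:, None, :]
        dh2 = a * g
        da = g * h2
        dh1 = a * (da - (a * da).sum(axis=1, keepdims=True))
        return np.concatenate([dh1, dh2], axis=2)
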