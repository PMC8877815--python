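"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the screening classifier needs: depthwise-separable 1-D
convolution (optionally strided for downsampling), dense layers, PReLU /
ReLU / sigmoid activations, flattening, an Adam optimizer and binary
cross-entropy.  Every layer is either linear in its input or a pure
elementwise nonlinearity, which the attribution module exploits to
propagate exact relevance multipliers.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    is_linear = False        # linear map of the input (weights may still exist)
    is_elementwise = False   # pure elementwise nonlinearity

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backprop_input(self, grad: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. input for *linear* layers; independent of cache."""
        raise NotImplementedError


def prelu(x: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Parametric rectifier: x for x > 0, alpha*x otherwise (elementwise)."""
    return np.maximum(0, x) + alpha * np.minimum(0, x)


class PReLU(Layer):
    """PReLU with a fixed or learnable slope alpha on the negative half-line."""

    is_elementwise = True

    def __init__(self, alpha: float = 0.25, learnable: bool = False):
        self.alpha_param = Parameter(np.array(alpha)) if learnable else None
        self._alpha_fixed = float(alpha)
        self._x: np.ndarray | None = None

    @property
    def alpha(self) -> float:
        return float(self.alpha_param.value) if self.alpha_param is not None \
            else self._alpha_fixed

    def params(self) -> list[Parameter]:
        return [self.alpha_param] if self.alpha_param is not None else []

    def f(self, x: np.ndarray) -> np.ndarray:
        return prelu(x, self.alpha)

    def f_prime(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, 1.0, self.alpha)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return self.f(x)

    def backward(self, grad):
        x = self._x
        if self.alpha_param is not None:
            self.alpha_param.grad += np.sum(grad * np.minimum(0, x))
        return grad * self.f_prime(x)


class ReLU(Layer):
    is_elementwise = True

    def f(self, x):
        return np.maximum(0, x)

    def f_prime(self, x):
        return (x > 0).astype(x.dtype)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return self.f(x)

    def backward(self, grad):
        return grad * self.f_prime(self._x)


class Sigmoid(Layer):
    is_elementwise = True

    def f(self, x):
        out = np.empty_like(x, dtype=np.float64)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def f_prime(self, x):
        s = self.f(x)
        return s * (1.0 - s)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return self.f(x)

    def backward(self, grad):
        return grad * self.f_prime(self._x)


class Flatten(Layer):
    is_linear = True

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def backprop_input(self, grad):
        return self.backward(grad)


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """'same' zero padding: output length ceil(L/stride)."""
    out_len = -(-length // stride)
    pad_total = max((out_len - 1) * stride + kernel - length, 0)
    left = pad_total // 2
    return out_len, left, pad_total - left


class SeparableConv1D(Layer):
    """Depthwise-separable 1-D convolution with 'same' zero padding.

    Each of the ``in_channels`` input channels is convolved with its own
    spatial kernel of size ``kernel`` (the depthwise stage, no bias), then a
    1x1 kernel of depth ``in_channels`` mixes channels into ``out_channels``
    outputs (the pointwise stage, one bias per output filter).  ``stride``
    applies to the depthwise stage and downsamples the spatial axis.
    """

    is_linear = True

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 pointwise_bias: bool = True):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        # He-style fan-in scaling for the two stages
        self.w_dw = Parameter(rng.normal(0.0, np.sqrt(2.0 / kernel),
                                         size=(in_channels, kernel)))
        self.w_pw = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_channels),
                                         size=(in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels)) if pointwise_bias else None

    def params(self):
        ps = [self.w_dw, self.w_pw]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def n_parameters(self) -> int:
        n = self.w_dw.value.size + self.w_pw.value.size
        if self.bias is not None:
            n += self.bias.value.size
        return n

    def _depthwise(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        out_len, left, right = _same_padding(L, self.kernel, self.stride)
        xpad = np.pad(x, ((0, 0), (0, 0), (left, right)))
        y = np.zeros((n, c, out_len), dtype=np.float64)
        w = self.w_dw.value
        for k in range(self.kernel):
            seg = xpad[:, :, k: k + (out_len - 1) * self.stride + 1: self.stride]
            y += w[None, :, k, None] * seg
        return y

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        self._in_shape = x.shape
        y1 = self._depthwise(x)
        if train:
            self._x = x
            self._y1 = y1
        out = np.einsum("ncl,cf->nfl", y1, self.w_pw.value)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        return out

    def backward(self, grad):
        # pointwise stage
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        self.w_pw.grad += np.einsum("ncl,nfl->cf", self._y1, grad)
        g_y1 = np.einsum("nfl,cf->ncl", grad, self.w_pw.value)
        # depthwise stage
        n, c, L = self._in_shape
        out_len, left, right = _same_padding(L, self.kernel, self.stride)
        xpad = np.pad(self._x, ((0, 0), (0, 0), (left, right)))
        g_xpad = np.zeros_like(xpad)
        w = self.w_dw.value
        span = (out_len - 1) * self.stride + 1
        for k in range(self.kernel):
            seg = xpad[:, :, k: k + span: self.stride]
            self.w_dw.grad[:, k] += np.einsum("ncl,ncl->c", g_y1, seg)
            g_xpad[:, :, k: k + span: self.stride] += w[None, :, k, None] * g_y1
        return g_xpad[:, :, left: left + L]

    def transpose_to_input(self, grad: np.ndarray, in_length: int) -> np.ndarray:
        """Apply the transpose of the conv linear map to ``grad``."""
        g_y1 = np.einsum("nfl,cf->ncl", grad, self.w_pw.value)
        n, c, out_len = g_y1.shape
        _, left, right = _same_padding(in_length, self.kernel, self.stride)
        g_xpad = np.zeros((n, c, in_length + left + right), dtype=np.float64)
        w = self.w_dw.value
        span = (out_len - 1) * self.stride + 1
        for k in range(self.kernel):
            g_xpad[:, :, k: k + span: self.stride] += w[None, :, k, None] * g_y1
        return g_xpad[:, :, left: left + in_length]


class Dense(Layer):
    is_linear = True

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      size=(in_features, out_features)))
        self.b = Parameter(np.zeros(out_features)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def n_parameters(self) -> int:
        return self.w.value.size + (self.b.value.size if self.b is not None else 0)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if train:
            self._x = x
        out = x @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, grad):
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        self.w.grad += self._x.T @ grad
        return grad @ self.w.value.T

    def backprop_input(self, grad):
        return grad @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_cached(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning the input of every layer plus the output."""
        acts = [x]
        for layer in self.layers:
            x = layer.forward(x, train=False)
            acts.append(x)
        return acts

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean BCE over all entries of a probability matrix."""
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
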