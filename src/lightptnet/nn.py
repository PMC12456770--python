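"""Minimal NumPy neural-network layers with hand-written backpropagation.

Everything operates on float32 arrays shaped ``[batch, time, channels]``
(dense layers take ``[batch, features]``).  Each layer caches whatever its
backward pass needs during ``forward`` and exposes its trainable tensors as
:class:`Parameter` objects, so a plain list of parameters is enough for the
optimiser.  Only the pieces the architecture needs are implemented: dilated
depthwise / pointwise / standard 1D convolutions, batch normalisation, ReLU,
dropout, average pooling, global average pooling and a dense layer.

Convolutions never carry a bias term: every convolution in the network is
either immediately followed by batch normalisation (whose shift subsumes a
bias) or is a 1x1 projection merged into a residual sum, and the analytic
parameter accounting in :mod:`lightptnet.complexity` relies on this
convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "depthwise_conv1d",
    "pointwise_conv1d",
    "conv1d",
    "pad_amounts",
    "DepthwiseConv1d",
    "PointwiseConv1d",
    "StandardConv1d",
    "SeparableConv1d",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "AvgPool1d",
    "GlobalAvgPool",
    "Dense",
    "Adam",
    "glorot_uniform",
]


class Parameter:
    """A trainable tensor together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def pad_amounts(kernel: int, dilation: int, padding: str) -> tuple[int, int]:
    """Left/right zero-padding for a dilated conv of effective extent
    ``(kernel-1)*dilation + 1``.

    ``same`` splits the padding so output length equals input length (extra
    sample on the right for even extents, as in Keras); ``causal`` pads only
    on the left so output ``t`` depends on inputs at times ``<= t``.
    """
    total = (kernel - 1) * dilation
    if padding == "same":
        left = total // 2
        return left, total - left
    if padding == "causal":
        return total, 0
    raise ValueError(f"padding must be 'same' or 'causal', got {padding!r}")


# ---------------------------------------------------------------------------
# Functional convolutions (shared by the layers and usable as test oracles)
# ---------------------------------------------------------------------------

def depthwise_conv1d(x, w, dilation=1, padding="same"):
    """Per-channel dilated convolution.

    x: [N, T, C]; w: [k, C].  Returns [N, T, C].
    """
    x = np.asarray(x)
    k = w.shape[0]
    left, right = pad_amounts(k, dilation, padding)
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    T = x.shape[1]
    out = np.zeros_like(x, dtype=np.result_type(x, w))
    for j in range(k):
        out += w[j] * xp[:, j * dilation : j * dilation + T, :]
    return out


def pointwise_conv1d(x, w):
    """1x1 channel-mixing convolution.  x: [N, T, Cin]; w: [Cin, Cout]."""
    return np.asarray(x) @ w


def conv1d(x, w, dilation=1, padding="same"):
    """Standard (unfactored) dilated convolution.

    x: [N, T, Cin]; w: [k, Cin, Cout].  Returns [N, T, Cout].
    """
    x = np.asarray(x)
    k, cin, cout = w.shape
    left, right = pad_amounts(k, dilation, padding)
    xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
    T = x.shape[1]
    out = np.zeros((x.shape[0], T, cout), dtype=np.result_type(x, w))
    for j in range(k):
        out += xp[:, j * dilation : j * dilation + T, :] @ w[j]
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class: stateless unless a subclass stores parameters/caches."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x, training: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class DepthwiseConv1d(Layer):
    def __init__(self, channels: int, kernel: int, dilation: int, padding: str,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.dilation = dilation
        self.padding = padding
        self.w = Parameter(glorot_uniform(rng, (kernel, channels), kernel, kernel),
                           name=f"dwconv{kernel}d{dilation}")

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        self._x = x
        return depthwise_conv1d(x, self.w.value, self.dilation, self.padding)

    def backward(self, grad):
        x = self._x
        k, d = self.kernel, self.dilation
        left, right = pad_amounts(k, d, self.padding)
        T = x.shape[1]
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        gxp = np.zeros_like(xp)
        w = self.w.value
        for j in range(k):
            sl = slice(j * d, j * d + T)
            self.w.grad[j] += np.einsum("ntc,ntc->c", grad, xp[:, sl, :])
            gxp[:, sl, :] += grad * w[j]
        return gxp[:, left : left + T, :]


class PointwiseConv1d(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Parameter(glorot_uniform(rng, (cin, cout), cin, cout),
                           name=f"pwconv{cin}x{cout}")

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value

    def backward(self, grad):
        x = self._x
        cin = x.shape[-1]
        self.w.grad += x.reshape(-1, cin).T @ grad.reshape(-1, grad.shape[-1])
        return grad @ self.w.value.T


class StandardConv1d(Layer):
    """Unfactored dilated conv; the ablation alternative to separable."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int,
                 padding: str, rng: np.random.Generator):
        self.kernel = kernel
        self.dilation = dilation
        self.padding = padding
        self.w = Parameter(
            glorot_uniform(rng, (kernel, cin, cout), kernel * cin, kernel * cout),
            name=f"conv{kernel}d{dilation}")

    def params(self):
        return [self.w]

    def forward(self, x, training=False):
        self._x = x
        return conv1d(x, self.w.value, self.dilation, self.padding)

    def backward(self, grad):
        x = self._x
        k, d = self.kernel, self.dilation
        left, right = pad_amounts(k, d, self.padding)
        T = x.shape[1]
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        gxp = np.zeros_like(xp)
        w = self.w.value
        cin, cout = w.shape[1], w.shape[2]
        for j in range(k):
            sl = slice(j * d, j * d + T)
            self.w.grad[j] += (xp[:, sl, :].reshape(-1, cin).T
                               @ grad.reshape(-1, cout))
            gxp[:, sl, :] += grad @ w[j].T
        return gxp[:, left : left + T, :]


class SeparableConv1d(Layer):
    """Depthwise dilated conv followed by a 1x1 pointwise conv."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int,
                 padding: str, rng: np.random.Generator):
        self.depthwise = DepthwiseConv1d(cin, kernel, dilation, padding, rng)
        self.pointwise = PointwiseConv1d(cin, cout, rng)

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x, training=False):
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))


class BatchNorm(Layer):
    """Per-channel batch normalisation over batch and (if present) time.

    Trainable scale ``gamma`` and shift ``beta`` (2 parameters per channel);
    running statistics updated with momentum in training mode and used
    verbatim in eval mode.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), "bn_gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), "bn_beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, training, axes = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        if not training:
            return dxhat * inv
        m = np.prod([xhat.shape[a] for a in axes])
        return (inv / m) * (m * dxhat
                            - dxhat.sum(axis=axes)
                            - xhat * (dxhat * xhat).sum(axis=axes))


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  Draws masks from ``rng``."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class AvgPool1d(Layer):
    """Average pooling, size == stride; a trailing partial window is dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        n, T, c = x.shape
        T2 = T // s
        self._in_T = T
        return x[:, : T2 * s, :].reshape(n, T2, s, c).mean(axis=2)

    def backward(self, grad):
        s = self.size
        n, T2, c = grad.shape
        g = np.repeat(grad / s, s, axis=1)
        if T2 * s < self._in_T:
            pad = self._in_T - T2 * s
            g = np.pad(g, ((0, 0), (0, pad), (0, 0)))
        return g


class GlobalAvgPool(Layer):
    """Averages each channel over time: [N, T, C] -> [N, C]."""

    def forward(self, x, training=False):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :] / self._T, self._T, axis=1)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with bias: [N, Cin] -> [N, Cout]."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Parameter(glorot_uniform(rng, (cin, cout), cin, cout), "dense_w")
        self.b = Parameter(np.zeros(cout, dtype=np.float32), "dense_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Adam:
    """Adam optimiser; the learning rate may change between steps."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
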