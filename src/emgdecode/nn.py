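"""Minimal sequence-network engine: layers with explicit forward/backward.

Everything operates on batched sequences of shape ``(B, T, C)`` in float64.
Each layer caches what its backward pass needs; ``backward`` consumes the
gradient of the loss with respect to the layer output and returns the
gradient with respect to the input, accumulating parameter gradients on the
:class:`Param` objects.  Gradients are exact (verified against central
finite differences in the test suite), which keeps training behaviour easy
to reason about on small CPUs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "CausalConv1d",
    "ReLU",
    "Dropout",
    "Linear",
    "TemporalBlock",
    "LSTMLayer",
    "Sequential",
    "Adam",
    "SGD",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class CausalConv1d(Layer):
    """Dilated causal 1-D convolution over the time axis.

    ``y[:, t] = b + sum_k x_pad[:, t + k*d] @ W[k]`` with ``d*(K-1)`` zeros
    padded on the left, so ``y[:, t]`` depends on ``x[:, max(0, t-(K-1)d) .. t]``
    only: no future sample can influence a past output.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, rng: np.random.Generator | None = None) -> None:
        if kernel_size < 1 or dilation < 1:
            raise ValueError("kernel_size and dilation must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = Param(
            rng.uniform(-bound, bound, size=(kernel_size, in_channels, out_channels)),
            "conv.weight",
        )
        self.bias = Param(rng.uniform(-bound, bound, size=out_channels), "conv.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ValueError(
                f"expected input (B, T, {self.in_channels}), got shape {x.shape}"
            )
        b, t, _ = x.shape
        pad = self.dilation * (self.kernel_size - 1)
        xp = np.concatenate([np.zeros((b, pad, self.in_channels)), x], axis=1)
        y = np.broadcast_to(self.bias.value, (b, t, self.out_channels)).copy()
        for k in range(self.kernel_size):
            y += xp[:, k * self.dilation : k * self.dilation + t] @ self.weight.value[k]
        self._cache = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache
        b, t = dy.shape[:2]
        pad = self.dilation * (self.kernel_size - 1)
        dxp = np.zeros_like(xp)
        self.bias.grad += dy.sum(axis=(0, 1))
        for k in range(self.kernel_size):
            sl = slice(k * self.dilation, k * self.dilation + t)
            self.weight.grad[k] += np.einsum("bti,bto->io", xp[:, sl], dy)
            dxp[:, sl] += dy @ self.weight.value[k].T
        return dxp[:, pad:]


class ReLU(Layer):
    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float = 0.0, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    """Affine map applied independently at every time step."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(
            rng.uniform(-bound, bound, size=(in_features, out_features)), "linear.weight"
        )
        self.bias = Param(rng.uniform(-bound, bound, size=out_features), "linear.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got shape {x.shape}"
            )
        self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        self.bias.grad += dy.sum(axis=(0, 1))
        return dy @ self.weight.value.T


class TemporalBlock(Layer):
    """Residual block of a temporal convolutional network.

    ``convs_per_block`` dilated causal convolutions (same dilation), each
    followed by a rectifier and optional dropout; the block output is the
    activation path plus a shortcut — the identity when channel widths match,
    a width-1 linear projection otherwise.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, dropout: float = 0.0, convs_per_block: int = 2,
                 rng: np.random.Generator | None = None) -> None:
        if convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.path: list[Layer] = []
        cin = in_channels
        for _ in range(convs_per_block):
            self.path += [
                CausalConv1d(cin, out_channels, kernel_size, dilation, rng=rng),
                ReLU(),
                Dropout(dropout, rng=rng),
            ]
            cin = out_channels
        self.shortcut = (
            None if in_channels == out_channels else Linear(in_channels, out_channels, rng=rng)
        )

    def params(self) -> list[Param]:
        ps = [p for layer in self.path for p in layer.params()]
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.path:
            h = layer.forward(h, train=train)
        res = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return h + res

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = dy
        for layer in reversed(self.path):
            dh = layer.backward(dh)
        dres = dy if self.shortcut is None else self.shortcut.backward(dy)
        return dh + dres


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer(Layer):
    """One LSTM layer unrolled over time with zero initial states.

    Gate pre-activations are ``[h_{t-1}, x_t] @ W + b`` with the packed gate
    order (input, forget, candidate, output):

        i = sigmoid(a_i); f = sigmoid(a_f); g = tanh(a_g); o = sigmoid(a_o)
        c_t = f * c_{t-1} + i * g;  h_t = o * tanh(c_t)

    Backward is full backpropagation through time.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None) -> None:
        self.input_size = input_size
        self.hidden_size = hidden_size
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(hidden_size)
        self.weight = Param(
            rng.uniform(-bound, bound, size=(hidden_size + input_size, 4 * hidden_size)),
            "lstm.weight",
        )
        self.bias = Param(rng.uniform(-bound, bound, size=4 * hidden_size), "lstm.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected input (B, T, {self.input_size}), got shape {x.shape}"
            )
        b, t, _ = x.shape
        hs = self.hidden_size
        h = np.zeros((b, hs))
        c = np.zeros((b, hs))
        y = np.empty((b, t, hs))
        cache = []
        for j in range(t):
            z = np.concatenate([h, x[:, j]], axis=1)
            a = z @ self.weight.value + self.bias.value
            i = _sigmoid(a[:, :hs])
            f = _sigmoid(a[:, hs : 2 * hs])
            g = np.tanh(a[:, 2 * hs : 3 * hs])
            o = _sigmoid(a[:, 3 * hs :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h = o * tc
            y[:, j] = h
            cache.append((z, i, f, g, o, c, c_new, tc))
            c = c_new
        self._cache = cache
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache = self._cache
        b, t, hs = dy.shape
        dx = np.empty((b, t, self.input_size))
        dh_next = np.zeros((b, hs))
        dc_next = np.zeros((b, hs))
        for j in range(t - 1, -1, -1):
            z, i, f, g, o, c_prev, _c, tc = cache[j]
            dh = dy[:, j] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.weight.grad += z.T @ da
            self.bias.grad += da.sum(axis=0)
            dz = da @ self.weight.value.T
            dh_next = dz[:, :hs]
            dx[:, j] = dz[:, hs:]
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the usual bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params: list[Param], lr: float = 0.01) -> None:
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
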