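"""Minimal float32 neural-network layers with explicit backward passes.

Convolutions are im2col + GEMM; the data gradient is computed as a
convolution of the output gradient with the flipped, transposed kernels, so
no scatter-add is needed.  Everything is deterministic given the generators
handed in.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Dense",
    "Dropout",
    "LSTM",
    "softmax",
    "softmax_cross_entropy",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, N, H, W) -> (C*k*k, N*H*W) patch matrix for stride-1 convolution.

    Feature maps use a channels-outermost layout so patch extraction is a set
    of plain strided copies (no transposes of large buffers).
    """
    c, n, h, w = x.shape
    xp = np.zeros((c, n, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    xp[:, :, pad : pad + h, pad : pad + w] = x
    cols = np.empty((c, k, k, n, h, w), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, ki, kj] = xp[:, :, ki : ki + h, kj : kj + w]
    return cols.reshape(c * k * k, n * h * w)


class Layer:
    def params(self) -> List[Param]:
        return []


class Conv2D(Layer):
    """3x3, stride 1, padding 1 convolution (spatial size preserved).

    Operates on (C, N, H, W) feature maps; kernels are stored as
    (c_out, c_in, k, k).
    """

    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3, input_grad: bool = True
    ) -> None:
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.input_grad = input_grad  # first layer can skip the data gradient
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.standard_normal((c_out, c_in, k, k)) * scale)
        self.b = Param(np.zeros(c_out))
        self._cols: Optional[np.ndarray] = None
        self._shape = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, n, h, w = x.shape
        self._shape = x.shape
        cols = _im2col(x, self.k, (self.k - 1) // 2)
        self._cols = cols if train else None
        out = self.W.value.reshape(self.c_out, -1) @ cols
        out += self.b.value[:, None]
        return out.reshape(self.c_out, n, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, n, h, w = self._shape
        dmat = dout.reshape(self.c_out, -1)
        self.W.grad += (dmat @ self._cols.T).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=1)
        self._cols = None
        if not self.input_grad:
            return None
        # data gradient = convolution of dout with flipped, transposed kernels
        w_back = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols = _im2col(dout, self.k, (self.k - 1) // 2)
        dx = np.ascontiguousarray(w_back.reshape(self.c_in, -1)) @ cols
        return dx.reshape(self.c_in, n, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 on (C, N, H, W) maps.

    Implemented as an elementwise max of the four strided quadrant views;
    on ties the gradient is routed to the first quadrant in scan order.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        quads = (
            x[..., 0::2, 0::2],
            x[..., 0::2, 1::2],
            x[..., 1::2, 0::2],
            x[..., 1::2, 1::2],
        )
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        if train:
            self._x = x
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        dx = np.zeros_like(x)
        remaining = np.ones_like(out, dtype=bool)
        for oi, oj in ((0, 0), (0, 1), (1, 0), (1, 1)):
            quad = x[..., oi::2, oj::2]
            hit = (quad == out) & remaining
            dx[..., oi::2, oj::2] = dout * hit
            remaining &= ~hit
        self._x = self._out = None
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / DTYPE(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single-layer LSTM over a (batch, time, features) sequence.

    Gates: f_t = sigma(W_f.[h_{t-1}, x_t] + b_f), likewise i_t and o_t;
    candidate C~_t = tanh(W_c.[h_{t-1}, x_t] + b_c);
    cell C_t = C_{t-1} * f_t + C~_t * i_t; output h_t = tanh(C_t) * o_t.
    Weights are stored fused as (input, 4*hidden) in gate order (i, f, c, o);
    the forget-gate bias starts at 1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.n_in, self.hidden = n_in, hidden
        scale = np.sqrt(1.0 / (n_in + hidden))
        self.Wx = Param(rng.standard_normal((n_in, 4 * hidden)) * scale)
        self.Wh = Param(rng.standard_normal((hidden, 4 * hidden)) * scale)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(b)

    def params(self) -> List[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Returns the final hidden state h_T, shape (batch, hidden)."""
        batch, steps, _ = x.shape
        hd = self.hidden
        h = np.zeros((batch, hd), dtype=DTYPE)
        c = np.zeros((batch, hd), dtype=DTYPE)
        self._cache = [] if train else None
        self._x_shape = x.shape
        for t in range(steps):
            xt = x[:, t, :]
            z = xt @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :hd])
            f = _sigmoid(z[:, hd : 2 * hd])
            g = np.tanh(z[:, 2 * hd : 3 * hd])
            o = _sigmoid(z[:, 3 * hd :])
            c_prev, h_prev = c, h
            c = c_prev * f + g * i
            tc = np.tanh(c)
            h = tc * o
            if train:
                self._cache.append((xt, h_prev, c_prev, i, f, g, o, tc))
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        batch, steps, _ = self._x_shape
        hd = self.hidden
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        dc = np.zeros_like(dh)
        for t in reversed(range(steps)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh = dz @ self.Wh.value.T
            dc = dc * f
        self._cache = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Returns (mean loss, probabilities, gradient w.r.t. logits)."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, probs, (grad / n).astype(DTYPE)
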