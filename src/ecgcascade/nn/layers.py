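"""Differentiable layers on float32 numpy arrays.

Activations follow the sequence convention ``(batch, length, channels)``.
Convolutions use "same" padding and stride 1; pooling uses "valid" windows.
Each layer caches what its backward pass needs, so forward(training=True)
must precede backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ParameterError


class Layer:
    """Base layer: parameter-free, shape-preserving by default."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, ReLU activation, Glorot-uniform init."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1):
        if stride != 1:
            raise ParameterError("Conv1D supports stride 1 only")
        if kernel_size < 1 or filters < 1 or in_channels < 1:
            raise ParameterError("Conv1D sizes must be positive")
        limit = np.sqrt(6.0 / (kernel_size * in_channels + filters))
        self.W = rng.uniform(-limit, limit,
                             (kernel_size, in_channels, filters)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size = kernel_size
        self.stride = stride
        self.filters = filters
        self.in_channels = in_channels

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _w_mat(self):
        # (k, C, F) -> (k*C, F), matching the im2col column layout
        return self.W.reshape(self.kernel_size * self.in_channels, self.filters)

    def forward(self, x, training=False, rng=None):
        k = self.kernel_size
        left = (k - 1) // 2
        xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (left, k - 1 - left), (0, 0)))
        win = sliding_window_view(xp, (k, xp.shape[2]), axis=(1, 2))[:, :, 0]
        B, L = win.shape[:2]
        cols = np.ascontiguousarray(win).reshape(B * L, k * self.in_channels)
        z = (cols @ self._w_mat()).reshape(B, L, self.filters) + self.b
        y = np.maximum(z, 0.0)
        if training:
            self._cols, self._mask, self._pad_left = cols, z > 0, left
        return y

    def backward(self, dy):
        dz = (dy * self._mask).astype(np.float32)
        B, L, _ = dz.shape
        k, left = self.kernel_size, self._pad_left
        dz_flat = dz.reshape(B * L, self.filters)
        self.dW[...] = (self._cols.T @ dz_flat).reshape(self.W.shape)
        self.db[...] = dz_flat.sum(axis=0)
        dcols = (dz_flat @ self._w_mat().T).reshape(B, L, k, self.in_channels)
        dxp = np.zeros((B, L + k - 1, self.in_channels), dtype=np.float32)
        for i in range(k):
            dxp[:, i : i + L, :] += dcols[:, :, i, :]
        self._cols = self._mask = None
        return dxp[:, left : left + L, :]

    def describe(self):
        return {"type": "conv1d", "kernel_size": self.kernel_size,
                "stride": self.stride, "filters": self.filters}


class MaxPool1D(Layer):
    """Valid max pooling over the time axis."""

    def __init__(self, size: int = 2, stride: int = 1):
        if size < 1 or stride < 1:
            raise ParameterError("pool size and stride must be positive")
        self.size = size
        self.stride = stride

    def forward(self, x, training=False, rng=None):
        win = sliding_window_view(x, self.size, axis=1)[:, :: self.stride]
        y = win.max(axis=-1)
        if training:
            self._arg = win.argmax(axis=-1)
            self._in_shape = x.shape
        return y

    def backward(self, dy):
        B, L_out, C = dy.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        if self.size == 2:
            # windows start at i*stride and cover two samples; scatter by argmax
            lo = dy * (self._arg == 0)
            hi = dy * (self._arg == 1)
            if self.stride == 1:
                dx[:, :L_out, :] += lo
                dx[:, 1 : L_out + 1, :] += hi
            else:
                s = self.stride
                dx[:, 0 : s * L_out : s, :] += lo
                dx[:, 1 : s * L_out + 1 : s, :] += hi
        else:
            pos = np.arange(L_out)[None, :, None] * self.stride + self._arg
            b_idx = np.broadcast_to(np.arange(B)[:, None, None], dy.shape)
            c_idx = np.broadcast_to(np.arange(C)[None, None, :], dy.shape)
            np.add.at(dx, (b_idx, pos, c_idx), dy)
        self._arg = None
        return dx

    def describe(self):
        return {"type": "maxpool", "size": self.size, "stride": self.stride}


class GlobalMaxPool1D(Layer):
    """Per-filter maximum over the whole time axis: (B, L, C) -> (B, C)."""

    def forward(self, x, training=False, rng=None):
        if training:
            self._arg = x.argmax(axis=1)
            self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, dy):
        B, _, C = self._in_shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        b_idx = np.arange(B)[:, None]
        c_idx = np.arange(C)[None, :]
        dx[b_idx, self._arg, c_idx] = dy
        self._arg = None
        return dx

    def describe(self):
        return {"type": "global_maxpool"}


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ParameterError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ParameterError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def describe(self):
        return {"type": "dropout", "rate": self.rate}


class Dense(Layer):
    """Fully connected layer on (B, n_in); optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = "relu"):
        if activation not in ("relu", None):
            raise ParameterError(f"unsupported activation {activation!r}")
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self.units = n_out

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        z = x @ self.W + self.b
        y = np.maximum(z, 0.0) if self.activation == "relu" else z
        if training:
            self._x = x
            self._mask = z > 0 if self.activation == "relu" else None
        return y

    def backward(self, dy):
        dz = dy * self._mask if self._mask is not None else dy
        dz = dz.astype(np.float32)
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        dx = dz @ self.W.T
        self._x = self._mask = None
        return dx

    def describe(self):
        return {"type": "dense", "units": self.units, "activation": self.activation}
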