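"""Minimal reverse-mode neural-network layers on numpy.

Just enough machinery for the two window classifiers: 1-D convolutions
(valid or same padding, arbitrary stride) via im2col, dense layers, ReLU,
inverted dropout, batch normalization over (batch, time) per channel,
same-length max pooling, global average pooling over time, and a fused
softmax/cross-entropy loss.  Tensors are ``(N, L, C)`` — batch, time,
channels.  Every layer caches what its backward pass needs; gradients are
verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Default parameter/activation dtype.  float32 roughly halves training
#: time on BLAS; gradient-checking tests switch to float64 for precision.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used by layers built afterwards (float32/float64)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Layer:
    """Base layer: forward/backward plus named parameter and grad dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return [self]


def conv_out_len(L: int, kernel: int, stride: int) -> int:
    """Temporal length after a valid convolution: floor((L - K) / S) + 1."""
    return (L - kernel) // stride + 1


class Conv1D(Layer):
    """Temporal convolution. ``padding`` is 'valid' or 'same' (stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: str = "valid", bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if padding == "same" and stride != 1:
            raise ValueError("'same' padding supports stride 1 only")
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * in_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_ch, self.out_ch, self.use_bias = in_ch, out_ch, bias
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch)
        ).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=DTYPE)

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        if self.padding == "valid":
            return x, 0, 0
        left = (self.kernel - 1) // 2
        right = self.kernel // 2
        return np.pad(x, ((0, 0), (left, right), (0, 0))), left, right

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=self.params["W"].dtype)
        xp, left, _ = self._pad(x)
        K, S = self.kernel, self.stride
        # (N, L_out, C, K) view -> (N, L_out, K*C) patches
        win = sliding_window_view(xp, K, axis=1)[:, ::S]
        patches = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, K * self.in_ch
        )
        self._patches = patches
        self._x_shape, self._pad_left = x.shape, left
        y = patches @ self.params["W"]
        if self.use_bias:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        K, S = self.kernel, self.stride
        N, L_out, _ = dy.shape
        flat_p = self._patches.reshape(-1, K * self.in_ch)
        self.grads["W"] = flat_p.T @ dy.reshape(-1, self.out_ch)
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 1))
        dpatch = (dy @ self.params["W"].T).reshape(N, L_out, K, self.in_ch)
        L_pad = self._x_shape[1] + (0 if self.padding == "valid" else K - 1)
        dxp = np.zeros((N, L_pad, self.in_ch), dtype=dpatch.dtype)
        for k in range(K):
            dxp[:, k : k + S * (L_out - 1) + 1 : S] += dpatch[:, :, k]
        if self.padding == "same":
            left = self._pad_left
            return dxp[:, left : left + self._x_shape[1]]
        return dxp


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)
        ).astype(DTYPE)
        self.params["b"] = np.zeros(out_dim, dtype=DTYPE)

    def reinit(self, rng: np.random.Generator) -> None:
        """Fresh random parameters (used for transfer-learning head resets)."""
        dt = self.params["W"].dtype
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / self.in_dim), size=(self.in_dim, self.out_dim)
        ).astype(dt)
        self.params["b"] = np.zeros(self.out_dim, dtype=dt)

    def forward(self, x, train=False, rng=None):
        self._x = np.asarray(x, dtype=self.params["W"].dtype)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        self._mask = (u >= self.p).astype(x.dtype)
        self._mask /= x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class BatchNorm(Layer):
    """Per-channel normalization over (batch, time) with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(n_ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_ch, dtype=DTYPE)
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        x = np.asarray(x, dtype=self.params["gamma"].dtype)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train, self._axes = train, axes
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        if not self._train:
            return dxhat / self._std
        m = np.prod([self._xhat.shape[a] for a in axes])
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class MaxPoolSame(Layer):
    """Max pooling along time, stride 1, same length (pad with -inf)."""

    def __init__(self, kernel: int = 3) -> None:
        super().__init__()
        self.kernel = kernel

    def forward(self, x, train=False, rng=None):
        K = self.kernel
        left, right = (K - 1) // 2, K // 2
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, K, axis=1)  # (N, L, C, K)
        self._argmax = win.argmax(axis=-1)  # offset within window
        self._x_shape, self._left = x.shape, left
        return win.max(axis=-1)

    def backward(self, dy):
        N, L, C = self._x_shape
        dxp = np.zeros((N, L + self.kernel - 1, C), dtype=dy.dtype)
        t_idx = np.arange(L)[None, :, None] + self._argmax  # position in padded axis
        n_idx = np.arange(N)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(dxp, (n_idx, t_idx, c_idx), dy)
        return dxp[:, self._left : self._left + L]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def sublayers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.sublayers())
        return out


def parameters(layer: Layer) -> list[tuple[Layer, str]]:
    """All (layer, parameter-name) pairs below ``layer``, in stable order."""
    return [(sub, name) for sub in layer.sublayers() for name in sub.params]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy, gradient w.r.t. logits, and the probabilities."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n, probs
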