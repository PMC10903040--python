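"""NumPy layers with reverse-mode gradients, losses, and RMSprop.

Tensors flow as (batch, length, channels) for convolutional layers and
(batch, features) for dense layers.  Every layer implements
``forward(x, training)`` and ``backward(grad)``; trainable layers
expose aligned ``params`` / ``grads`` lists consumed by the optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relu", "sigmoid", "softmax", "conv1d_valid", "bce_loss", "cce_loss",
    "Conv1D", "MaxPool1D", "BatchNorm1D", "GlobalAveragePool1D",
    "Dense", "Dropout", "ReLULayer", "Flatten", "LSTMLayer", "RMSprop",
]


# ---------------------------------------------------------------- activations

def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit: max(x, 0), elementwise."""
    return np.maximum(np.asarray(x), 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1 / (1 + e^-x), numerically stabilized."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax along ``axis``; rows sum to one."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=axis, keepdims=True)


def conv1d_valid(signal: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid (no zero-padding) 1D convolution of a single channel.

    Output length is ``len(signal) - len(kernel) + 1``; element t is
    ``sum_k signal[t + k] * kernel[k] + bias`` (the sliding-dot-product
    convention used by convolutional networks).
    """
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or signal.ndim != 1:
        raise ValueError("conv1d_valid expects 1-D signal and kernel")
    if len(kernel) > len(signal):
        raise ValueError(
            f"kernel length {len(kernel)} exceeds signal length {len(signal)}"
        )
    n_out = len(signal) - len(kernel) + 1
    windows = np.lib.stride_tricks.sliding_window_view(signal, len(kernel))
    return windows[:n_out] @ kernel + bias


# --------------------------------------------------------------------- losses

def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of predicted probabilities ``p``."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cce_loss(p: np.ndarray, y_onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy; zero for a perfect one-hot match."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0)
    y_onehot = np.asarray(y_onehot, dtype=float)
    return float(-np.mean(np.sum(y_onehot * np.log(p), axis=-1)))


# --------------------------------------------------------------------- layers

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid multi-channel 1D convolution, optional fused ReLU.

    Weights (kernel, in_ch, out_ch) are He-initialized.  Forward uses an
    im2col sliding-window view so the convolution is one matmul.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 activation: str | None = "relu") -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.w = rng.normal(0.0, scale, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.activation = activation
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        if k > L:
            raise ValueError(f"kernel {k} exceeds input length {L}")
        # (B, L_out, k, C)
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols
        self._in_shape = x.shape
        z = np.tensordot(cols, self.w, axes=([2, 3], [0, 1])) + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * self._mask
        B, L, C = self._in_shape
        k = self.kernel
        self.grads[0][...] = np.tensordot(self._cols, grad, axes=([0, 1], [0, 1]))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        # scatter-add each kernel tap's contribution back to the input
        L_out = grad.shape[1]
        for t in range(k):
            dx[:, t : t + L_out, :] += grad @ self.w[t].T
        return dx


class MaxPool1D(Layer):
    def __init__(self, window: int = 2, stride: int | None = None) -> None:
        super().__init__()
        self.window = window
        self.stride = stride if stride is not None else window

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        n_out = (L - self.window) // self.stride + 1
        if n_out < 1:
            raise ValueError(f"pooling window {self.window} exceeds length {L}")
        idx = np.arange(n_out)[:, None] * self.stride + np.arange(self.window)[None, :]
        windows = x[:, idx, :]  # (B, n_out, window, C)
        self._argmax = windows.argmax(axis=2)
        self._idx = idx
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, n_out, C = grad.shape
        dx = np.zeros(self._in_shape)
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        # absolute input position of each window's max: window start + offset
        pos = self._argmax + (np.arange(n_out) * self.stride)[None, :, None]
        np.add.at(dx, (b_idx, pos, c_idx), grad)
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = self._axes
        m = np.prod([grad.shape[a] for a in axes])
        self.grads[0][...] = np.sum(grad * self._xhat, axis=axes)
        self.grads[1][...] = np.sum(grad, axis=axes)
        dxhat = grad * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * np.mean(dxhat * self._xhat, axis=axes)
        ) / self._std


class GlobalAveragePool1D(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class ReLULayer(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class LSTMLayer(Layer):
    """Single LSTM layer returning the final hidden state.

    Input (B, L, C); output (B, units).  Full backpropagation through
    time; gate order in the stacked weight matrices is i, f, g, o.
    """

    def __init__(self, in_ch: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = 1.0 / np.sqrt(in_ch + units)
        self.w = rng.normal(0.0, scale, size=(in_ch + units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias init
        self.units = units
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        self._x = x
        for t in range(L):
            z = np.hstack([x[:, t, :], h]) @ self.w + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, L, C = self._x.shape
        u = self.units
        dw = np.zeros_like(self.w)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(self._x)
        dh = grad
        dc = np.zeros((B, u))
        for t in reversed(range(L)):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.hstack([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ])
            concat = np.hstack([self._x[:, t, :], h_prev])
            dw += concat.T @ dz
            db += dz.sum(axis=0)
            dconcat = dz @ self.w.T
            dx[:, t, :] = dconcat[:, :C]
            dh = dconcat[:, C:]
            dc = dc * f
        self.grads[0][...] = dw
        self.grads[1][...] = db
        return dx


# ------------------------------------------------------------------ optimizer

class RMSprop:
    """RMSprop: v <- rho v + (1 - rho) g^2; p <- p - lr g / (sqrt(v) + eps)."""

    def __init__(self, lr: float = 0.00025, rho: float = 0.9, eps: float = 1e-8) -> None:
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g in zip(params, grads):
            key = id(p)
            v = self._cache.setdefault(key, np.zeros_like(p))
            v *= self.rho
            v += (1 - self.rho) * g**2
            p -= self.lr * g / (np.sqrt(v) + self.eps)
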