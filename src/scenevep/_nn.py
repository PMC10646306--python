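"""Minimal NumPy neural-network layers for the compact VEP classifier.

Only what the architecture needs is implemented: temporal (1, k)
convolutions, batch normalization, ELU, temporal average pooling, dropout,
and a fully connected head, each with an explicit backward pass, plus Adam.
All arrays are float32; activations are shaped (batch, filters, channels,
time) so convolutions and pools act on the last (time) axis only.

Keeping the framework in plain NumPy makes the gradients available to the
attribution stage (Grad-CAM needs d score / d feature-map) without any
autodiff dependency, and makes every arithmetic choice (padding mode,
floor-division pooling) explicit and testable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def out_time(self, t: int) -> int:
        """Time-axis length after this layer (identity unless overridden)."""
        return t


class ReplicatePad(Layer):
    """Edge-replicate padding on the time axis, ``pad`` samples per side."""

    def __init__(self, pad: int):
        super().__init__()
        self.pad = int(pad)

    def forward(self, x, training=False, rng=None):
        p = self.pad
        return np.pad(x, ((0, 0), (0, 0), (0, 0), (p, p)), mode="edge")

    def backward(self, gy):
        p = self.pad
        gx = gy[..., p:-p].copy()
        # replicated edge samples accumulate their pad gradients
        gx[..., 0] += gy[..., :p].sum(axis=-1)
        gx[..., -1] += gy[..., -p:].sum(axis=-1)
        return gx

    def out_time(self, t):
        return t + 2 * self.pad


def _freq_matmul(Ah: np.ndarray, Bh: np.ndarray) -> np.ndarray:
    """Per-frequency contraction  (B, Ci, E, F) x (Co, Ci, F) -> (B, Co, E, F)
    via batched complex matmuls (one cgemm per frequency bin)."""
    B, Ci, E, F = Ah.shape
    Co = Bh.shape[0]
    Am = np.ascontiguousarray(Ah.transpose(3, 0, 2, 1)).reshape(F, B * E, Ci)
    Bm = np.ascontiguousarray(Bh.transpose(2, 1, 0))                # (F, Ci, Co)
    Ym = Am @ Bm                                                     # (F, B*E, Co)
    return np.ascontiguousarray(
        Ym.reshape(F, B, E, Co).transpose(1, 3, 2, 0))


class ConvTime(Layer):
    """2-D convolution with kernel (1, k): a 1-D temporal correlation
    applied independently at every electrode, mixing input filters.

    For k > 1 the forward and backward passes run in the frequency domain
    (circular correlation with zero-padded kernels; the valid region is
    wrap-free), which is far cheaper than im2col at these signal lengths.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k))
        self.params["W"] = (rng.standard_normal((c_out, c_in, k)) * scale).astype(_F32)
        self.params["b"] = np.zeros(c_out, dtype=_F32)

    def _wh(self, T: int) -> np.ndarray:
        from scipy import fft as sfft
        return sfft.rfft(self.params["W"], n=T, axis=-1)   # (O, C, F)

    def forward(self, x, training=False, rng=None):
        B, C, E, T = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input filters, got {C}")
        k, O = self.k, self.c_out
        To = T - k + 1
        if k == 1:
            xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(B * E * T, C)
            y = xt @ self.params["W"][:, :, 0].T + self.params["b"]
            self._cache = (xt, None, (B, C, E, T))
            return np.ascontiguousarray(
                y.reshape(B, E, T, O).transpose(0, 3, 1, 2))
        from scipy import fft as sfft
        Xh = sfft.rfft(x, axis=-1)                          # (B, C, E, F)
        Yh = _freq_matmul(Xh, np.conj(self._wh(T)))
        y = sfft.irfft(Yh, n=T, axis=-1)[..., :To]
        self._cache = (None, Xh, (B, C, E, T))
        return (y + self.params["b"][:, None, None]).astype(_F32)

    def backward(self, gy):
        xt, Xh, (B, C, E, T) = self._cache
        k, O = self.k, self.c_out
        To = T - k + 1
        if k == 1:
            g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(B * E * T, O)
            self.grads["W"] = (g.T @ xt)[:, :, None]
            self.grads["b"] = g.sum(axis=0)
            gx = (g @ self.params["W"][:, :, 0]).reshape(B, E, T, C)
            self._cache = None
            return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        from scipy import fft as sfft
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        Gh = sfft.rfft(gy, n=T, axis=-1)                    # (B, O, E, F)
        Wh = self._wh(T)
        # dx[t] = sum_j gy[t - j] w[j]  (plain convolution)
        gx = sfft.irfft(_freq_matmul(Gh, Wh.transpose(1, 0, 2)), n=T, axis=-1)
        # dW[o, c, j] = sum_t x[t + j] gy[t]  (cross-correlation, lags 0..k-1)
        P = np.einsum("bcef,boef->ocf", Xh, np.conj(Gh))
        self.grads["W"] = sfft.irfft(P, n=T, axis=-1)[:, :, :k].astype(_F32)
        self._cache = None
        return gx.astype(_F32)

    def out_time(self, t):
        return t - self.k + 1


class BatchNorm(Layer):
    """Batch normalization per filter over (batch, electrode, time)."""

    def __init__(self, n_filters: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_filters, dtype=_F32)
        self.params["beta"] = np.zeros(n_filters, dtype=_F32)
        self.running_mean = np.zeros(n_filters, dtype=_F32)
        self.running_var = np.ones(n_filters, dtype=_F32)

    def forward(self, x, training=False, rng=None):
        ax = (0, 2, 3)
        if training:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(_F32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = np.subtract(x, mu[:, None, None].astype(_F32))
        xhat *= inv[:, None, None]
        self._cache = (xhat, inv, x.shape, training)
        y = xhat * self.params["gamma"][:, None, None]
        y += self.params["beta"][:, None, None]
        return y

    def backward(self, gy):
        xhat, inv, shape, training = self._cache
        ax = (0, 2, 3)
        self.grads["gamma"] = (gy * xhat).sum(axis=ax)
        self.grads["beta"] = gy.sum(axis=ax)
        gscale = self.params["gamma"][:, None, None] * inv[:, None, None]
        if not training:
            return (gy * gscale).astype(_F32)
        n = shape[0] * shape[2] * shape[3]
        gmean = gy.mean(axis=ax)[:, None, None]
        gdot = (gy * xhat).mean(axis=ax)[:, None, None]
        self._cache = None
        return (gscale * (gy - gmean - xhat * gdot)).astype(_F32)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        neg = x <= 0
        y = x.astype(_F32, copy=True)
        np.expm1(y, out=y, where=neg)
        if self.alpha != 1.0:
            np.multiply(y, _F32(self.alpha), out=y, where=neg)
        self._cache = (neg, y)
        return y

    def backward(self, gy):
        neg, y = self._cache
        gx = gy.astype(_F32, copy=True)
        d = y + _F32(self.alpha)
        np.multiply(gx, d, out=gx, where=neg)
        self._cache = None
        return gx


class AvgPoolTime(Layer):
    """Temporal average pooling, stride = width, floor division (no pad)."""

    def __init__(self, p: int):
        super().__init__()
        self.p = int(p)

    def forward(self, x, training=False, rng=None):
        p = self.p
        To = x.shape[-1] // p
        self._t_in = x.shape[-1]
        y = x[..., : To * p].reshape(*x.shape[:-1], To, p).mean(axis=-1)
        return y.astype(_F32)

    def backward(self, gy):
        p = self.p
        gx = np.zeros(gy.shape[:-1] + (self._t_in,), dtype=_F32)
        gx[..., : gy.shape[-1] * p] = np.repeat(gy / p, p, axis=-1)
        return gx

    def out_time(self, t):
        return t // self.p


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape, dtype=np.float32) >= self.p)
                      .astype(_F32) / (1.0 - self.p))
        return (x * self._mask).astype(_F32)

    def backward(self, gy):
        if self._mask is None:
            return gy
        return (gy * self._mask).astype(_F32)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.params["b"] = np.zeros(n_out, dtype=_F32)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        gx = gy @ self.params["W"].T
        self._x = None
        return gx.astype(_F32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None, capture: int | None = None):
        """Run the stack; if ``capture`` is a layer index, also return that
        layer's output (the Grad-CAM feature-map tap)."""
        captured = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training=training, rng=rng)
            if capture is not None and i == capture:
                captured = x
        return (x, captured) if capture is not None else x

    def backward(self, gy, capture: int | None = None, stop_at: int | None = None):
        """Backpropagate; if ``capture`` is given, return the gradient with
        respect to that layer's *output*. ``stop_at`` truncates the pass."""
        captured = None
        for i in range(len(self.layers) - 1, -1, -1):
            if capture is not None and i == capture:
                captured = gy  # gradient w.r.t. layers[i]'s output
            if stop_at is not None and i <= stop_at:
                break
            gy = self.layers[i].backward(gy)
        return (gy, captured) if capture is not None else gy

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def out_time(self, t: int) -> list[int]:
        """Time-axis length after each layer, by pure integer arithmetic."""
        out = []
        for layer in self.layers:
            t = layer.out_time(t)
            out.append(t)
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p
    g[np.arange(n), labels] -= 1.0
    return float(loss), (g / n).astype(_F32)


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style; decay is
    not applied to biases or batch-norm affine parameters)."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for layer, name, p in self.net.parameters():
            g = layer.grads[name].astype(np.float32)
            key = (id(layer), name)
            if key not in self.state:
                self.state[key] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[key]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and name == "W":
                p -= self.lr * self.weight_decay * p
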