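"""Minimal feed-forward layers with hand-written gradients.

Supports exactly what the two models need: Chebyshev graph convolutions with
per-sample operators, batch normalization, pairwise node max-pooling,
dropout, dense layers, stride-2 SAME 2-D convolutions and their transposes,
and an Adam optimizer. Shapes follow the channels-last convention
(B, H, W, C) for images and (B, N, F) for graph signals.

Every layer exposes ``params`` / ``grads`` (parallel lists of arrays),
``forward(x, training)`` and ``backward(dout)``; gradient correctness is
pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, training=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# graph layers
# ---------------------------------------------------------------------------

def cheb_tensor(scaled_laplacians: np.ndarray, order: int) -> np.ndarray:
    """Stack [T_0(L~), ..., T_K(L~)] per sample: (B, K+1, N, N)."""
    lt = np.asarray(scaled_laplacians, dtype=float)
    if lt.ndim == 2:
        lt = lt[None]
    b, n, _ = lt.shape
    out = np.empty((b, order + 1, n, n))
    out[:, 0] = np.eye(n)
    out[:, 1] = lt
    for k in range(2, order + 1):
        out[:, k] = 2.0 * lt @ out[:, k - 1] - out[:, k - 2]
    return out


class ChebConv(Layer):
    """Graph convolution y = sum_k T_k(L~) x W_k + b with per-node bias.

    ``forward`` takes (cheb, x) where cheb is the precomputed (B, K+1, N, N)
    Chebyshev stack of each sample's scaled Laplacian and x is (B, N, F_in).
    """

    def __init__(self, order: int, f_in: int, f_out: int, n_nodes: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (f_in * (order + 1) + f_out))
        self.weight = rng.standard_normal((order + 1, f_in, f_out)) * scale
        self.bias = np.zeros((n_nodes, f_out))
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, inputs, training=True):
        cheb, x = inputs
        self._cheb = cheb
        self._s = cheb @ x[:, None]  # (B, K+1, N, F)
        b, k1, n, f = self._s.shape
        w = self.weight.reshape(k1 * f, -1)
        return (self._s.transpose(0, 2, 1, 3).reshape(b, n, k1 * f) @ w) + self.bias

    def backward(self, dout):
        b, k1, n, f = self._s.shape
        self.grads[0][...] = np.tensordot(self._s, dout, axes=([0, 2], [0, 1]))
        self.grads[1][...] = dout.sum(axis=0)
        w = self.weight.reshape(k1 * f, -1)
        ds = (dout @ w.T).reshape(b, n, k1, f).transpose(0, 2, 1, 3)
        # T_k symmetric, so the adjoint reuses the same stack transposed
        return (self._cheb.swapaxes(2, 3) @ ds).sum(axis=1)


class NodeMaxPool(Layer):
    """Max over fixed node pairs (2i, 2i+1); an odd trailing node passes through."""

    def forward(self, x, training=True):
        b, n, c = x.shape
        self._in_shape = x.shape
        n_even = n - (n % 2)
        pairs = x[:, :n_even].reshape(b, n_even // 2, 2, c)
        self._arg = pairs.argmax(axis=2)
        out = pairs.max(axis=2)
        if n % 2:
            out = np.concatenate([out, x[:, -1:]], axis=1)
        return out

    def backward(self, dout):
        b, n, c = self._in_shape
        dx = np.zeros(self._in_shape)
        n_pairs = n // 2
        d_pairs = dout[:, :n_pairs]
        bi, pi, ci = np.meshgrid(np.arange(b), np.arange(n_pairs), np.arange(c),
                                 indexing="ij")
        dx_pairs = np.zeros((b, n_pairs, 2, c))
        dx_pairs[bi, pi, self._arg, ci] = d_pairs
        dx[:, :n_pairs * 2] = dx_pairs.reshape(b, n_pairs * 2, c)
        if n % 2:
            dx[:, -1] = dout[:, -1]
        return dx


# ---------------------------------------------------------------------------
# generic layers
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=True):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes, m = self._axes, self._m
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout with an externally seeded generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=True):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = rng.standard_normal((f_in, f_out)) * np.sqrt(2.0 / (f_in + f_out))
        self.bias = np.zeros(f_out)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x, training=True):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.weight.T


# ---------------------------------------------------------------------------
# 2-D convolutions, stride-2 SAME (TensorFlow padding convention)
# ---------------------------------------------------------------------------

def same_pads(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_begin, pad_end) for SAME padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


def _conv_fwd(x, w, stride, pads_h, pads_w, out_h, out_w):
    b, h, wd, cin = x.shape
    k = w.shape[0]
    xp = np.pad(x, ((0, 0), pads_h, pads_w, (0, 0)))
    y = np.zeros((b, out_h, out_w, w.shape[3]))
    for di in range(k):
        for dj in range(k):
            xs = xp[:, di:di + out_h * stride:stride, dj:dj + out_w * stride:stride]
            y += (xs.reshape(-1, cin) @ w[di, dj]).reshape(y.shape)
    return y


def _conv_bwd_data(dy, w, x_shape, stride, pads_h, pads_w):
    b, h, wd, cin = x_shape
    k = w.shape[0]
    out_h, out_w = dy.shape[1], dy.shape[2]
    cout = dy.shape[3]
    dxp = np.zeros((b, h + sum(pads_h), wd + sum(pads_w), cin))
    dyf = dy.reshape(-1, cout)
    for di in range(k):
        for dj in range(k):
            contrib = (dyf @ w[di, dj].T).reshape(b, out_h, out_w, cin)
            dxp[:, di:di + out_h * stride:stride,
                dj:dj + out_w * stride:stride] += contrib
    return dxp[:, pads_h[0]:pads_h[0] + h, pads_w[0]:pads_w[0] + wd]


def _conv_bwd_weights(x, dy, kernel, stride, pads_h, pads_w):
    k = kernel
    out_h, out_w = dy.shape[1], dy.shape[2]
    cin, cout = x.shape[3], dy.shape[3]
    xp = np.pad(x, ((0, 0), pads_h, pads_w, (0, 0)))
    dyf = dy.reshape(-1, cout)
    dw = np.zeros((k, k, cin, cout))
    for di in range(k):
        for dj in range(k):
            xs = xp[:, di:di + out_h * stride:stride, dj:dj + out_w * stride:stride]
            dw[di, dj] = xs.reshape(-1, cin).T @ dyf
    return dw


class Conv2D(Layer):
    """k x k, stride-s, SAME-padded convolution; kernel (k, k, C_in, C_out)."""

    def __init__(self, in_size: tuple[int, int], c_in: int, c_out: int,
                 rng: np.random.Generator, kernel: int = 3, stride: int = 2):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.out_h, *ph = same_pads(in_size[0], kernel, stride)
        self.out_w, *pw = same_pads(in_size[1], kernel, stride)
        self.pads_h, self.pads_w = tuple(ph), tuple(pw)
        self.in_size, self.c_in, self.c_out = in_size, c_in, c_out
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.weight = rng.standard_normal((kernel, kernel, c_in, c_out)) * scale
        self.bias = np.zeros(c_out)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x, training=True):
        self._x = x
        return _conv_fwd(x, self.weight, self.stride, self.pads_h, self.pads_w,
                         self.out_h, self.out_w) + self.bias

    def backward(self, dout):
        self.grads[0][...] = _conv_bwd_weights(self._x, dout, self.kernel,
                                               self.stride, self.pads_h, self.pads_w)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        return _conv_bwd_data(dout, self.weight, self._x.shape, self.stride,
                              self.pads_h, self.pads_w)


class ConvTranspose2D(Layer):
    """Adjoint of a stride-s SAME convolution ``out_size -> in_size``.

    Maps (B, in_h, in_w, C_in) -> (B, out_h, out_w, C_out); the kernel has
    shape (k, k, C_out, C_in) so parameter counts follow the
    k*k*C_out*C_in + C_out convention of transposed convolutions.
    """

    def __init__(self, in_size: tuple[int, int], out_size: tuple[int, int],
                 c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        # pads of the underlying forward conv out_size -> in_size
        oh, *ph = same_pads(out_size[0], kernel, stride)
        ow, *pw = same_pads(out_size[1], kernel, stride)
        if (oh, ow) != tuple(in_size):
            raise ValueError(f"incompatible transpose geometry {in_size} -> {out_size}")
        self.pads_h, self.pads_w = tuple(ph), tuple(pw)
        self.in_size, self.out_size = tuple(in_size), tuple(out_size)
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.weight = rng.standard_normal((kernel, kernel, c_out, c_in)) * scale
        self.bias = np.zeros(c_out)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x, training=True):
        self._x = x
        b = x.shape[0]
        y = _conv_bwd_data(x, self.weight,
                           (b, *self.out_size, self.c_out),
                           self.stride, self.pads_h, self.pads_w)
        return y + self.bias

    def backward(self, dout):
        self.grads[0][...] = _conv_bwd_weights(dout, self._x, self.kernel,
                                               self.stride, self.pads_h, self.pads_w)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        return _conv_fwd(dout, self.weight, self.stride, self.pads_h, self.pads_w,
                         *self._x.shape[1:3])


# ---------------------------------------------------------------------------
# losses and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  weights_sq_sum: float = 0.0, rho: float = 0.0,
                  n_params: int = 1, eps: float = 1e-12) -> float:
    """Mean -sum y log(p) plus the (rho / 2 N_P) ||W||^2 decay term."""
    ce = -np.sum(onehot * np.log(np.clip(probs, eps, 1.0))) / probs.shape[0]
    return float(ce + rho / (2.0 * max(n_params, 1)) * weights_sq_sum)


def binary_cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                         eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(onehot * np.log(p) + (1 - onehot) * np.log(1 - p)))


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.n_params = sum(p.size for l in self.layers for p in l.params)

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                if self.weight_decay and p.ndim > 1:
                    g = g + (self.weight_decay / self.n_params) * p
                m = self.m[li][pi] = self.b1 * self.m[li][pi] + (1 - self.b1) * g
                v = self.v[li][pi] = self.b2 * self.v[li][pi] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def weights_sq_sum(self) -> float:
        return float(sum((p ** 2).sum() for l in self.layers for p in l.params
                         if p.ndim > 1))
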