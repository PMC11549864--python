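"""Minimal numpy neural-network core: 1-D convolutions, dense layers,
dropout, Adam, and input-gradient backprop.

Only what the MRL regressor needs.  All math is float32; convolutions are
implemented as im2col + BLAS matmul, which on one CPU core is the fastest
route available here.  Every source of randomness (init, shuffling,
dropout) flows through a caller-supplied ``numpy.random.Generator`` so
training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

F32 = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv1DSame:
    """1-D convolution with length-preserving (zero) padding and ReLU option.

    Weights are stored flattened as ``(kernel * in_channels, filters)`` so the
    forward pass is a single matmul on im2col patches.  For an even kernel the
    extra pad column goes on the right.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, relu: bool,
                 rng: np.random.Generator):
        self.cin, self.f, self.k, self.relu = in_channels, filters, kernel, relu
        self.W = _glorot(rng, (kernel * in_channels, filters),
                         fan_in=kernel * in_channels, fan_out=kernel * filters)
        self.b = np.zeros(filters, dtype=F32)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (B, L, cin, k) -> (B, L, k, cin) -> (B*L, k*cin)
        patches = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        z = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(B * L, self.k * self.cin)
        y = (z @ self.W + self.b).reshape(B, L, self.f)
        mask = None
        if self.relu:
            mask = y > 0
            y *= mask
        return y, (z, mask, B, L)

    def backward(self, dy, cache, need_param_grads=True):
        z, mask, B, L = cache
        if self.relu:
            dy = dy * mask
        dyf = dy.reshape(B * L, self.f)
        if need_param_grads:
            dW = z.T @ dyf
            db = dyf.sum(axis=0)
        dz = (dyf @ self.W.T).reshape(B, L, self.k, self.cin)
        dxp = np.zeros((B, L + self.k - 1, self.cin), dtype=F32)
        for k in range(self.k):
            dxp[:, k : k + L, :] += dz[:, :, k, :]
        dx = dxp[:, self.pad_left : self.pad_left + L, :]
        return dx, [dW, db] if need_param_grads else []


class Flatten:
    params: list = []

    def forward(self, x, train, rng):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache, need_param_grads=True):
        return dy.reshape(cache), []


class Dense:
    def __init__(self, in_dim: int, out_dim: int, relu: bool, rng: np.random.Generator):
        self.relu = relu
        self.W = _glorot(rng, (in_dim, out_dim), fan_in=in_dim, fan_out=out_dim)
        self.b = np.zeros(out_dim, dtype=F32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        y = x @ self.W + self.b
        mask = None
        if self.relu:
            mask = y > 0
            y *= mask
        return y, (x, mask)

    def backward(self, dy, cache, need_param_grads=True):
        x, mask = cache
        if self.relu:
            dy = dy * mask
        dx = dy @ self.W.T
        return dx, [x.T @ dy, dy.sum(axis=0)] if need_param_grads else []


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    params: list = []

    def __init__(self, rate: float):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            return x, None
        mask = (rng.random(x.shape) >= self.rate).astype(F32) / F32(1 - self.rate)
        return x * mask, mask

    def backward(self, dy, cache, need_param_grads=True):
        if cache is None:
            return dy, []
        return dy * cache, []


class Network:
    """A plain sequential stack with scalar output."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        flat = self.params
        if len(flat) != len(values):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(flat, values):
            dst[...] = src

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def copy(self) -> "Network":
        return copy.deepcopy(self)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        caches = []
        h = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            h, cache = layer.forward(h, train, rng)
            caches.append(cache)
        return h[:, 0], caches

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = np.empty(len(x), dtype=F32)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = self.forward(x[i : i + batch_size])[0]
        return out

    def backward(self, dout: np.ndarray, caches, need_param_grads: bool = True):
        """Backprop ``d(output)`` to input and parameter gradients."""
        dy = np.ascontiguousarray(dout, dtype=F32)[:, None]
        grads: list[np.ndarray] = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy, layer_grads = layer.backward(dy, cache, need_param_grads)
            grads = layer_grads + grads
        return dy, grads

    def input_gradients(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Gradient of the scalar output w.r.t. each input, eval mode."""
        out = np.empty_like(np.ascontiguousarray(x, dtype=F32))
        ones = np.ones(batch_size, dtype=F32)
        for i in range(0, len(x), batch_size):
            xb = x[i : i + batch_size]
            _, caches = self.forward(xb)
            dx, _ = self.backward(ones[: len(xb)], caches, need_param_grads=False)
            out[i : i + batch_size] = dx
        return out


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bias1 = 1 - self.b1 ** self.t
        bias2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def fit(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    epoch_callback=None,
) -> list[dict]:
    """Mini-batch Adam on squared-error loss; returns per-epoch history.

    ``epoch_callback(epoch_1based, net)`` runs after each epoch (used for
    checkpointing during the fine-tuning epoch search).
    """
    x = np.ascontiguousarray(x, dtype=F32)
    y = np.ascontiguousarray(y, dtype=F32)
    opt = Adam(net.params, lr=lr)
    history = []
    n = len(x)
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for i in range(0, n, batch_size):
            idx = perm[i : i + batch_size]
            xb, yb = x[idx], y[idx]
            pred, caches = net.forward(xb, train=True, rng=rng)
            err = pred - yb
            total += float(err @ err)
            seen += len(idx)
            _, grads = net.backward(2.0 * err / len(idx), caches)
            opt.step(grads)
        rec = {"epoch": epoch, "train_loss": total / seen}
        if x_val is not None and len(x_val):
            val_pred = net.predict(x_val)
            rec["val_loss"] = float(np.mean((val_pred - y_val) ** 2))
        history.append(rec)
        if epoch_callback is not None:
            epoch_callback(epoch, net)
    return history
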