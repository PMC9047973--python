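"""Minimal NumPy neural-network layers used by the detector and embedder.

Only what the two small CNNs need: 2-D convolution (stride, groups,
"same" padding with ceil output sizes), batch normalization, ReLU,
channel shuffle, global average pooling, a linear layer, L2
normalization, and SGD with momentum.  Forward/backward passes are
explicit; gradients are verified against numeric differentiation in the
test suite.

All layers consume and produce float32 arrays of shape (N, C, H, W)
unless stated otherwise.  Randomness (weight init) comes exclusively
from the numpy Generator handed to each layer, so a model built twice
from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "ChannelShuffle",
    "GlobalAvgPool",
    "Linear",
    "L2Normalize",
    "Sequential",
    "SGD",
    "same_pad",
]


def same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Padding so that the output length is ceil(size / stride).

    Returns (out_size, pad_before, pad_after).  The total pad is split
    as evenly as possible with the extra pixel at the end, matching the
    usual "SAME" convention.
    """
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


class Layer:
    """Base class: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs updated by the optimizer."""
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Arrays to persist in a checkpoint (params + running stats)."""
        return {}


class Conv2d(Layer):
    """Grouped 2-D convolution with SAME padding and arbitrary stride."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 groups=1, rng: np.random.Generator | None = None):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.cin, self.cout, self.k, self.s, self.g = (
            in_channels, out_channels, kernel_size, stride, groups)
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = rng.normal(0.0, scale,
                            (out_channels, in_channels // groups,
                             kernel_size, kernel_size)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s = self.k, self.s
        ho, pt, pb = same_pad(h, k, s)
        wo, pl, pr = same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        # windows: (n, c, ho, wo, k, k), a strided view until copied
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]
        out = np.empty((n, self.cout, ho, wo), dtype=np.float32)
        cg_in = self.cin // self.g
        cg_out = self.cout // self.g
        cols_per_group = []
        for g in range(self.g):
            cols = win[:, g * cg_in:(g + 1) * cg_in]
            cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, -1)
            cols_per_group.append(cols)
            wg = self.W[g * cg_out:(g + 1) * cg_out].reshape(cg_out, -1)
            out[:, g * cg_out:(g + 1) * cg_out] = (
                cols @ wg.T).transpose(0, 3, 1, 2)
        out += self.b[None, :, None, None]
        if train:
            self._cache = (x.shape, (pt, pl), cols_per_group, (ho, wo))
        return out

    def backward(self, grad):
        (n, c, h, w), (pt, pl), cols_per_group, (ho, wo) = self._cache
        k, s = self.k, self.s
        cg_in = self.cin // self.g
        cg_out = self.cout // self.g
        hp = h + pt + same_pad(h, k, s)[2]
        wp = w + pl + same_pad(w, k, s)[2]
        dxp = np.zeros((n, self.cin, hp, wp), dtype=np.float32)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        for g in range(self.g):
            go = grad[:, g * cg_out:(g + 1) * cg_out]
            go_f = go.transpose(0, 2, 3, 1).reshape(-1, cg_out)  # (nhw, cg_out)
            cols = cols_per_group[g].reshape(-1, cg_in * k * k)
            dwg = go_f.T @ cols  # (cg_out, cg_in*k*k)
            self.dW[g * cg_out:(g + 1) * cg_out] = dwg.reshape(
                cg_out, cg_in, k, k)
            wg = self.W[g * cg_out:(g + 1) * cg_out].reshape(cg_out, -1)
            dcols = (go_f @ wg).reshape(n, ho, wo, cg_in, k, k)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, cg_in, ho, wo, k, k)
            sl = slice(g * cg_in, (g + 1) * cg_in)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, sl, ki:ki + ho * s:s, kj:kj + wo * s:s] += \
                        dcols[:, :, :, :, ki, kj]
        return dxp[:, :, pt:pt + h, pl:pl + w]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state_arrays(self):
        return {"W": self.W, "b": self.b}


class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, inv = self._cache
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        term = (g - g.mean(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None])
        return (term * inv[None, :, None, None]).astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_arrays(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean,
                "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Channel order after the reshape-transpose shuffle.

    Channels laid out as `groups` contiguous blocks are re-ordered so
    that each output block takes one channel from every input block
    (reshape to (groups, C/groups), transpose, flatten).
    """
    if channels % groups:
        raise ValueError(f"channels={channels} not divisible by groups={groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


class ChannelShuffle(Layer):
    def __init__(self, groups):
        self.groups = groups
        self._perm = None

    def forward(self, x, train=False):
        if self._perm is None or len(self._perm) != x.shape[1]:
            self._perm = shuffle_permutation(x.shape[1], self.groups)
            self._inv = np.argsort(self._perm)
        return x[:, self._perm]

    def backward(self, grad):
        return grad[:, self._inv]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0, scale, (out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state_arrays(self):
        return {"W": self.W, "b": self.b}


class L2Normalize(Layer):
    """Project vectors onto the unit sphere (rows of an (N, D) array)."""

    def __init__(self, eps=1e-12):
        self.eps = eps

    def forward(self, x, train=False):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        y = x / norm
        if train:
            self._y, self._norm = y, norm
        return y

    def backward(self, grad):
        y, norm = self._y, self._norm
        return (grad - y * (grad * y).sum(axis=1, keepdims=True)) / norm


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_arrays().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state(self, arrays: dict):
        for key, value in arrays.items():
            name, attr = key.split(".", 1)
            layer = self.layers[int(name[5:])]
            layer.state_arrays()[attr][...] = value


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), v in zip(self.params, self.velocity):
            grad = g + self.wd * p
            v *= self.momentum
            v -= self.lr * grad
            p += v
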