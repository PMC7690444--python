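"""Minimal grouped neural-network engine (numpy, CPU).

Implements exactly the layer vocabulary the siamese embedding branches
need — 3x3 same-padding convolution, 2x2 max pooling, ReLU, flatten,
batch normalization, dense — with forward/backward passes and SGD with
momentum. Every layer carries a leading *group* axis of size G, holding G
independent weight sets evaluated in one batched BLAS call: the six
per-modality branches of the model are one layer stack with G = 6. A single
branch (for architecture inspection and parameter counting) is the same
stack with G = 1.

Tensor layout: (G, N, H, W, C) through convolutional stages and (G, N, F)
after flattening. All computation is deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32
"""Working precision of the engine; float32 keeps CPU training fast."""

__all__ = [
    "DTYPE",
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Flatten",
    "BatchNorm",
    "Dense",
    "SGDMomentum",
    "count_parameters",
    "forward_stack",
    "backward_stack",
]


class Layer:
    """Base layer: parameters, gradients, and trainability bookkeeping."""

    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        """Learnable parameter arrays (updated by the optimizer when trainable)."""
        return {}

    def buffers(self) -> dict:
        """Non-learnable state (e.g. batch-norm moving statistics)."""
        return {}

    def grads(self) -> dict:
        return {}

    def param_counts(self) -> tuple[int, int]:
        """(trainable, non_trainable) scalar parameter counts."""
        n_params = sum(int(p.size) for p in self.params().values())
        n_buf = sum(int(b.size) for b in self.buffers().values())
        if self.trainable:
            return n_params, n_buf
        return 0, n_params + n_buf


class Conv2D(Layer):
    """3x3 (configurable) same-padding, stride-1 grouped convolution.

    Weights: (G, k*k*c_in, c_out) in kh-major/kw/c_in patch order, plus a
    (G, c_out) bias. Random init is He-normal (fan-in of one patch).
    """

    def __init__(
        self,
        groups: int,
        c_in: int,
        c_out: int,
        ksize: int = 3,
        trainable: bool = True,
        rng: Optional[np.random.Generator] = None,
        dtype=None,
    ) -> None:
        dtype = dtype or DTYPE
        self.groups, self.c_in, self.c_out, self.ksize = groups, c_in, c_out, ksize
        self.trainable = trainable
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(groups, fan_in, c_out)).astype(dtype)
        self.b = np.zeros((groups, c_out), dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[tuple] = None

    def params(self) -> dict:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict:
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g, n, h, w, c = x.shape
        k = self.ksize
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (G,N,H,W,C,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 4)).reshape(g, n * h * w, k * k * c)
        y = np.matmul(cols, self.W) + self.b[:, None, :]
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(g, n, h, w, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        g, n, h, w, _ = dy.shape
        k, c = self.ksize, self.c_in
        dyf = dy.reshape(g, n * h * w, self.c_out)
        self.dW = np.matmul(self._cols.transpose(0, 2, 1), dyf)
        self.db = dyf.sum(axis=1)
        self._cols = None
        if not need_dx:
            return dy  # placeholder; caller stops here
        dcols = np.matmul(dyf, self.W.transpose(0, 2, 1))
        dcols = dcols.reshape(g, n, h, w, k, k, c)
        p = (k - 1) // 2
        dxp = np.zeros((g, n, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j, :]
        return dxp[:, :, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling; odd trailing rows/columns are dropped."""

    trainable = False

    def __init__(self, size: int = 2) -> None:
        self.size = size
        self._idx = None
        self._xshape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g, n, h, w, c = x.shape
        s = self.size
        h2, w2 = h // s, w // s
        xr = x[:, :, : h2 * s, : w2 * s, :].reshape(g, n, h2, s, w2, s, c)
        xp = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5)).reshape(g, n, h2, w2, c, s * s)
        idx = xp.argmax(axis=-1)
        y = np.take_along_axis(xp, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        g, n, h, w, c = self._xshape
        s = self.size
        h2, w2 = h // s, w // s
        d = np.zeros((g, n, h2, w2, c, s * s), dtype=dy.dtype)
        np.put_along_axis(d, self._idx[..., None], dy[..., None], axis=-1)
        d = d.reshape(g, n, h2, w2, c, s, s).transpose(0, 1, 2, 5, 3, 6, 4)
        dx = np.zeros((g, n, h, w, c), dtype=dy.dtype)
        dx[:, :, : h2 * s, : w2 * s, :] = d.reshape(g, n, h2 * s, w2 * s, c)
        self._idx = None
        return dx


class ReLU(Layer):
    trainable = False

    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    trainable = False

    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        return dy.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over the sample axis of (G, N, F) activations.

    Scale/shift (gamma, beta) are learnable; the moving mean/variance used
    at evaluation time are non-learnable buffers, as in the standard
    formulation (and counted as non-trainable parameters).
    """

    def __init__(
        self,
        groups: int,
        n_features: int,
        trainable: bool = True,
        momentum: float = 0.99,
        eps: float = 1e-3,
        dtype=None,
    ) -> None:
        dtype = dtype or DTYPE
        self.trainable = trainable
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones((groups, n_features), dtype=dtype)
        self.beta = np.zeros((groups, n_features), dtype=dtype)
        self.moving_mean = np.zeros((groups, n_features), dtype=dtype)
        self.moving_var = np.ones((groups, n_features), dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._xhat = None
        self._ivar = None

    def params(self) -> dict:
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self) -> dict:
        return {"moving_mean": self.moving_mean, "moving_var": self.moving_var}

    def grads(self) -> dict:
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=1, keepdims=True)
            var = x.var(axis=1, keepdims=True)
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * ivar
            m = self.momentum
            self.moving_mean = m * self.moving_mean + (1 - m) * mu[:, 0, :]
            self.moving_var = m * self.moving_var + (1 - m) * var[:, 0, :]
            self._xhat, self._ivar = xhat, ivar
        else:
            ivar = 1.0 / np.sqrt(self.moving_var[:, None, :] + self.eps)
            xhat = (x - self.moving_mean[:, None, :]) * ivar
        return self.gamma[:, None, :] * xhat + self.beta[:, None, :]

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        n = dy.shape[1]
        self.dgamma = (dy * xhat).sum(axis=1)
        self.dbeta = dy.sum(axis=1)
        dxhat = dy * self.gamma[:, None, :]
        dx = (
            ivar
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
            )
        )
        self._xhat = self._ivar = None
        return dx


class Dense(Layer):
    """Grouped fully connected layer, optionally with ReLU activation.

    Weights are initialized from N(0, init_sd); biases start at zero.
    """

    def __init__(
        self,
        groups: int,
        n_in: int,
        n_out: int,
        relu: bool = False,
        trainable: bool = True,
        init_sd: float = 0.01,
        rng: Optional[np.random.Generator] = None,
        dtype=None,
    ) -> None:
        dtype = dtype or DTYPE
        self.trainable = trainable
        self.relu = relu
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, init_sd, size=(groups, n_in, n_out)).astype(dtype)
        self.b = np.zeros((groups, n_out), dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None
        self._mask = None

    def params(self) -> dict:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict:
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = np.matmul(x, self.W) + self.b[:, None, :]
        if self.relu:
            if train:
                self._mask = z > 0
            z = np.maximum(z, 0)
        if train:
            self._x = x
        return z

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
            self._mask = None
        self.dW = np.matmul(self._x.transpose(0, 2, 1), dy)
        self.db = dy.sum(axis=1)
        self._x = None
        if not need_dx:
            return dy
        return np.matmul(dy, self.W.transpose(0, 2, 1))


def first_backward_index(layers: Sequence[Layer]) -> int:
    """Index of the earliest layer whose gradients are ever needed.

    Backpropagation can stop at the first layer holding trainable
    parameters; anything below it (frozen backbone blocks) needs neither
    activations cached nor gradients computed.
    """
    for i, layer in enumerate(layers):
        if layer.trainable and layer.params():
            return i
    return len(layers)


def forward_stack(
    layers: Sequence[Layer], x: np.ndarray, train: bool, cache_from: int = 0
) -> np.ndarray:
    """Run the stack forward. ``train`` controls batch-norm semantics and
    activation caching; layers below ``cache_from`` skip the caching."""
    for i, layer in enumerate(layers):
        if isinstance(layer, BatchNorm):
            x = layer.forward(x, train)
        else:
            x = layer.forward(x, train and i >= cache_from)
    return x


def backward_stack(layers: Sequence[Layer], dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
    """Backpropagate down to (and including) layer ``stop_at``; the input
    gradient of that deepest layer is not materialized."""
    for i in range(len(layers) - 1, stop_at - 1, -1):
        dy = layers[i].backward(dy, need_dx=i > stop_at)
    return dy


def count_parameters(layers: Sequence[Layer]) -> tuple[int, int, int]:
    """(total, trainable, non_trainable) over a layer stack.

    A frozen layer's weights count as non-trainable; batch-norm moving
    statistics are always non-trainable.
    """
    trainable = non_trainable = 0
    for layer in layers:
        t, nt = layer.param_counts()
        trainable += t
        non_trainable += nt
    return trainable + non_trainable, trainable, non_trainable


class SGDMomentum:
    """Classic momentum SGD: v <- mu*v - lr*g; w <- w + v.

    Only layers flagged trainable are updated, so frozen weights are
    bit-identical before and after training. lr = 0 leaves all weights
    untouched.
    """

    def __init__(self, layers: Sequence[Layer], lr: float, momentum: float) -> None:
        self.layers = [l for l in layers if l.trainable and l.params()]
        self.lr, self.momentum = lr, momentum
        self.velocity = [
            {name: np.zeros_like(p) for name, p in layer.params().items()} for layer in self.layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            grads = layer.grads()
            for name, p in layer.params().items():
                v = vel[name]
                v *= self.momentum
                v -= self.lr * grads[name]
                p += v
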