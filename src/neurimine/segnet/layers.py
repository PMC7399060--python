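"""Minimal 3D CNN layers with explicit forward/backward passes, in numpy.

Tensors are float32 with layout ``(N, C, D, H, W)``. Convolutions use an
im2col lowering to one GEMM per layer; transposed convolutions are restricted
to ``kernel == stride`` (non-overlapping upsampling blocks), which is all the
architecture here needs and keeps both passes exact and simple.

Each layer caches what its backward pass needs during ``forward(train=True)``
and accumulates parameter gradients in ``.grads``; an optimizer reads
``.params``/``.grads`` pairs.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = ["Conv3d", "ConvTranspose3d", "BatchNorm3d", "ReLU", "Sequential", "Layer"]

DTYPE = np.float32


class Layer:
    """Base: parameterless layers override forward/backward only."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0


class Conv3d(Layer):
    """3D convolution, kernel k, stride s, 'same'-style padding k//2.

    He-normal initialisation (ReLU fan-in); weights ``(C_out, C_in, k, k, k)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel ** 3
        if zero_init:
            # classifier heads start at exactly zero logits (p = 0.5 softmax),
            # keeping the summed deep-supervision output unsaturated at init
            self.W = np.zeros((c_out, c_in, kernel, kernel, kernel), dtype=DTYPE)
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=(c_out, c_in, kernel, kernel, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _out_size(self, d: int) -> int:
        return (d + 2 * self.pad - self.k) // self.s + 1

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        k, s, p = self.k, self.s, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        view = view[:, :, ::s, ::s, ::s]
        do, ho, wo = view.shape[2:5]
        # one contiguous copy in GEMM layout: (C*k^3, N*L)
        cols = np.ascontiguousarray(
            view.transpose(1, 5, 6, 7, 0, 2, 3, 4), dtype=DTYPE
        ).reshape(c * k ** 3, n * do * ho * wo)
        wmat = self.W.reshape(self.c_out, -1)
        y = wmat @ cols + self.b[:, None]  # (C_out, N*L)
        y = y.reshape(self.c_out, n, do, ho, wo).transpose(1, 0, 2, 3, 4)
        if train:
            self._cache = (cols, x.shape, (do, ho, wo))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (do, ho, wo) = self._cache
        n, c, d, h, w = x_shape
        k, s, p = self.k, self.s, self.pad
        dy_mat = np.ascontiguousarray(dy.transpose(1, 0, 2, 3, 4)).reshape(
            self.c_out, n * do * ho * wo)
        self.dW += (dy_mat @ cols.T).reshape(self.W.shape)
        self.db += dy_mat.sum(axis=1)
        # (C*k^3, N*L) -> per-offset contiguous blocks, scatter-add into dxp
        dcols = (self.W.reshape(self.c_out, -1).T @ dy_mat).reshape(
            c, k, k, k, n, do, ho, wo)
        dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=DTYPE)
        dxp_t = dxp.transpose(1, 0, 2, 3, 4)  # (C, N, ...) view
        for i, j, l in product(range(k), range(k), range(k)):
            dxp_t[:, :, i : i + s * do : s, j : j + s * ho : s, l : l + s * wo : s] += (
                dcols[:, i, j, l]
            )
        return dxp[:, :, p : p + d, p : p + h, p : p + w] if p else dxp


class ConvTranspose3d(Layer):
    """Transposed 3D convolution with kernel == stride (block upsampling).

    Each input voxel populates a disjoint ``s³`` output block, so the output
    side is exactly ``s`` times the input side. Weights ``(C_in, C_out, s, s, s)``.
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.s = c_in, c_out, stride
        fan_in = c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_in, c_out, stride, stride, stride)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        s = self.s
        t = np.einsum("ncdhw,cmijl->nmdihjwl", x, self.W, optimize=True)
        y = t.reshape(n, self.c_out, d * s, h * s, w * s)
        y = y + self.b[None, :, None, None, None]
        if train:
            self._cache = x
        return np.ascontiguousarray(y.astype(DTYPE))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, d, h, w = x.shape
        s = self.s
        dyr = dy.reshape(n, self.c_out, d, s, h, s, w, s)
        self.dW += np.einsum("ncdhw,nmdihjwl->cmijl", x, dyr, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("nmdihjwl,cmijl->ncdhw", dyr, self.W, optimize=True)
        return np.ascontiguousarray(dx.astype(DTYPE))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W); running stats for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        y = self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]
        if train:
            self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE))
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.dbeta += dy.sum(axis=axes)
        self.dgamma += (dy * xhat).sum(axis=axes)
        dxhat = dy * self.gamma[None, :, None, None, None]
        sum_dxhat = dxhat.sum(axis=axes)[None, :, None, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
        dx = (inv_std[None, :, None, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def iter_layers(self):
        for l in self.layers:
            if isinstance(l, Sequential):
                yield from l.iter_layers()
            else:
                yield l
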