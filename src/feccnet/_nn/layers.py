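"""Core layers operating on (N, C, H, W) arrays.

Conventions:
- convolutions use size-preserving zero padding (stride 1 only; resolution
  changes happen exclusively in the explicit pooling/upsampling layers);
- conv kernels are He-uniform initialised from a caller-supplied
  ``numpy.random.Generator`` so a seed fully determines the graph;
- convolutions followed by batch normalisation carry no bias (it would be
  absorbed by the BN shift).
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2d(Layer):
    """Dense 2D convolution (im2col), odd kernel, stride 1, same padding.

    ``dilation`` spaces the kernel taps, giving a 3-tap kernel an effective
    receptive field of ``2*dilation + 1`` per axis at constant parameter cost.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        dilation: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        if out_channels < 1 or in_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        if dilation < 1:
            raise ConfigurationError("dilation must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.dilation = dilation
        self.weight = Param(
            he_uniform(rng, (out_channels, in_channels, k, k), in_channels * k * k, dtype),
            "conv.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, d = self.kernel_size, self.dilation
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
        t = 0
        for i in range(k):
            for j in range(k):
                cols[:, :, t] = xp[:, :, i * d : i * d + h, j * d : j * d + w]
                t += 1
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ConfigurationError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        col = self._im2col(x)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        y = np.matmul(wmat, col).reshape(n, self.out_channels, h, w)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        k, d = self.kernel_size, self.dilation
        col = self._im2col(x)  # recomputed: cheaper than caching per layer
        dy_mat = dy.reshape(n, self.out_channels, h * w)
        dw = np.einsum("nop,ncp->oc", dy_mat, col, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        wmat = self.weight.data.reshape(self.out_channels, -1)
        dcol = np.matmul(wmat.T, dy_mat).reshape(n, c, k * k, h, w)
        p = d * (k // 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        t = 0
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d : i * d + h, j * d : j * d + w] += dcol[:, :, t]
                t += 1
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class DepthwiseConv2d(Layer):
    """Per-channel 3x3 (or kxk) spatial convolution, same padding, no bias."""

    def __init__(
        self,
        channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        self.channels = channels
        self.kernel_size = k
        self.weight = Param(he_uniform(rng, (channels, k, k), k * k, dtype), "dwconv.weight")
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ConfigurationError(f"expected {self.channels} channels, got {c}")
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                y += self.weight.data[None, :, i, j, None, None] * xp[:, :, i : i + h, j : j + w]
        self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        k = self.kernel_size
        p = k // 2
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.weight.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", dy, xp[:, :, i : i + h, j : j + w], optimize=True
                )
                dxp[:, :, i : i + h, j : j + w] += (
                    self.weight.data[None, :, i, j, None, None] * dy
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch moments over (N, H, W); evaluation
    mode uses exponential running averages (momentum 0.9). Scale and shift
    (gamma, beta) are the 2C trainable scalars.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9, dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1.0 - m) * mean
            self.running_var = m * self.running_var + (1.0 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        n, c, h, w = shape
        self.gamma.grad += np.einsum("nchw,nchw->c", dy, xhat, optimize=True)
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = np.einsum("nchw,nchw->c", dxhat, xhat, optimize=True)
        dx = (
            inv_std[None, :, None, None]
            / m
            * (m * dxhat - s1[None, :, None, None] - xhat * s2[None, :, None, None])
        )
        return dx


class Dense(Layer):
    """Fully connected layer on (N, F) arrays, with bias."""

    def __init__(self, in_features: int, out_features: int, rng=None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(
            he_uniform(rng, (out_features, in_features), in_features, dtype), "dense.weight"
        )
        self.bias = Param(np.zeros(out_features, dtype=dtype), "dense.bias")
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2. Ties split the gradient evenly."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError("spatial size must be even for 2x2 pooling")
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = x6.max(axis=(3, 5))
        mask = x6 == y[:, :, :, None, :, None]
        self._mask = mask
        self._counts = mask.sum(axis=(3, 5), keepdims=True)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, hh, ww = dy.shape
        dx6 = self._mask * (dy[:, :, :, None, :, None] / self._counts)
        return dx6.reshape(n, c, hh * 2, ww * 2)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic 2x bilinear interpolation matrix (half-pixel centres)."""
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in), dtype=dtype)
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0c), 1.0 - frac)
    np.add.at(m, (rows, i1c), frac)
    return m


class UpsampleBilinear2x(Layer):
    """Fixed (parameter-free) 2x bilinear upsampling; backward is the exact adjoint."""

    def __init__(self) -> None:
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    def _mat(self, n_in: int, dtype) -> np.ndarray:
        key = (n_in, np.dtype(dtype).num)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(2 * n_in, n_in, dtype)
        return self._mats[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        mh = self._mat(h, x.dtype)
        mw = self._mat(w, x.dtype)
        y = np.einsum("ph,nchw->ncpw", mh, x, optimize=True)
        y = np.einsum("qw,ncpw->ncpq", mw, y, optimize=True)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        mh = self._mat(h, dy.dtype)
        mw = self._mat(w, dy.dtype)
        dx = np.einsum("qw,ncpq->ncpw", mw, dy, optimize=True)
        dx = np.einsum("ph,ncpw->nchw", mh, dx, optimize=True)
        return dx


class GlobalAvgPool2d(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)
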