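"""Minimal 3D convolutional layer stack with hand-derived backpropagation.

Tensors are ``(N, C, Z, Y, X)`` float32. Convolutions run as im2col + BLAS
matmul; their adjoints scatter-add over the 27 (or 1) kernel offsets. Each
layer caches what its backward pass needs when called with ``training=True``
and exposes its parameters for the optimizer.

This is deliberately a small, fixed-topology toolkit — enough to express an
encoder with strided down-sampling, residual units, a refinement decoder with
x2 up-sampling, and a softmax head — not a general autograd engine.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Upsample",
    "Sequential",
    "ConvBNReLU",
    "ResBlock",
    "softmax",
]

# split im2col along z when the column matrix would exceed this many bytes
_COL_BYTES_LIMIT = 1 << 28


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Forward/backward interface shared by all layers."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _triple(v: int | Sequence[int]) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(a) for a in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 values, got {t}")
    return t


class Conv3d(Layer):
    """3D convolution with 'same' padding for odd kernels.

    He fan-in initialization; bias is off by default because every backbone
    conv is followed by batch normalization.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | Sequence[int] = 3,
        stride: int | Sequence[int] = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        role: str = "conv",
    ) -> None:
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = tuple(k // 2 for k in self.kernel_size)
        self.role = role
        rng = rng or np.random.default_rng()
        fan_in = in_channels * math.prod(self.kernel_size)
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Parameter(
            w.reshape(out_channels, in_channels, *self.kernel_size), f"{role}.weight"
        )
        self.bias = Parameter(np.zeros(out_channels), f"{role}.bias") if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(
            (s + 2 * p - k) // st + 1
            for s, p, k, st in zip(spatial, self.padding, self.kernel_size, self.stride)
        )

    def _im2col(self, xp: np.ndarray, z0: int, z1: int) -> np.ndarray:
        """Column matrix for output slices [z0, z1) of the padded input."""
        kz, ky, kx = self.kernel_size
        sz, sy, sx = self.stride
        zin0 = z0 * sz
        zin1 = (z1 - 1) * sz + kz
        win = sliding_window_view(xp[:, :, zin0:zin1], self.kernel_size, axis=(2, 3, 4))
        win = win[:, :, ::sz, ::sy, ::sx]
        n, c, zo, yo, xo = win.shape[:5]
        col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * zo * yo * xo, -1)
        return np.ascontiguousarray(col, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        pz, py, px = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
        zo, yo, xo = self._out_shape(x.shape[2:])
        wmat = self.weight.data.reshape(self.out_channels, -1)

        row_bytes = 4 * self.in_channels * math.prod(self.kernel_size) * n * yo * xo
        chunk = max(1, _COL_BYTES_LIMIT // max(row_bytes, 1)) if not training else zo
        out = np.empty((n, zo, yo, xo, self.out_channels), dtype=np.float32)
        col_full = None
        for z0 in range(0, zo, chunk):
            z1 = min(z0 + chunk, zo)
            col = self._im2col(xp, z0, z1)
            out[:, z0:z1] = (col @ wmat.T).reshape(n, z1 - z0, yo, xo, self.out_channels)
            if training:
                col_full = col
        if self.bias is not None:
            out += self.bias.data
        out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
        if training:
            self._cache = (col_full, x.shape, (zo, yo, xo))
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        col, x_shape, (zo, yo, xo) = self._cache
        n = x_shape[0]
        g = grad_out.transpose(0, 2, 3, 4, 1).reshape(-1, self.out_channels)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += (g.T @ col).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)

        dcol = (g @ wmat).reshape(n, zo, yo, xo, self.in_channels, *self.kernel_size)
        dcol = dcol.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        pz, py, px = self.padding
        sz, sy, sx = self.stride
        zp, yp, xp_ = (s + 2 * p for s, p in zip(x_shape[2:], self.padding))
        dxp = np.zeros((n, self.in_channels, zp, yp, xp_), dtype=np.float32)
        kz, ky, kx = self.kernel_size
        for iz, iy, ix in itertools.product(range(kz), range(ky), range(kx)):
            dxp[
                :,
                :,
                iz : iz + (zo - 1) * sz + 1 : sz,
                iy : iy + (yo - 1) * sy + 1 : sy,
                ix : ix + (xo - 1) * sx + 1 : sx,
            ] += dcol[..., iz, iy, ix]
        self._cache = None
        return dxp[:, :, pz : pz + x_shape[2], py : py + x_shape[3], px : px + x_shape[4]]


class BatchNorm3d(Layer):
    """Per-channel batch normalization with affine parameters."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, self.channels, 1, 1, 1)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if training:
            self._cache = (xhat, inv_std)
        return (self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)).astype(
            np.float32
        )

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = grad_out.size // self.channels
        shape = (1, self.channels, 1, 1, 1)
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.data.reshape(shape)
        dx = (
            g - g.mean(axis=axes).reshape(shape) - xhat * (g * xhat).mean(axis=axes).reshape(shape)
        ) * inv_std.reshape(shape)
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before a training-mode forward")
        grad = grad_out * self._mask
        self._mask = None
        return grad


def _upsample_matrix(n: int, mode: str) -> np.ndarray:
    """Linear map from n samples to 2n, edge-clamped.

    Output sample i sits at source coordinate (i + 0.5)/2 - 0.5; linear mode
    interpolates the two neighbours, nearest mode copies the closer one.
    """
    u = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        if mode == "nearest":
            u[i, min(max(int(round(src)), 0), n - 1)] = 1.0
            continue
        lo = math.floor(src)
        w = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        u[i, lo_c] += 1.0 - w
        u[i, hi_c] += w
    return u


class Upsample(Layer):
    """x2 up-sampling along selected axes (trilinear or nearest).

    Separable per-axis linear operators; the backward pass applies their
    transposes, i.e. the exact adjoint of the interpolation.
    """

    def __init__(self, factors: tuple[int, int, int] = (1, 2, 2), mode: str = "trilinear") -> None:
        if mode not in ("trilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        if any(f not in (1, 2) for f in factors):
            raise ValueError(f"factors must be 1 or 2, got {factors}")
        self.factors = factors
        self.mode = mode
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape: tuple | None = None

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _upsample_matrix(n, "nearest" if self.mode == "nearest" else "linear")
        return self._mats[n]

    def _apply(self, x: np.ndarray, transpose: bool) -> np.ndarray:
        for axis_offset, f in enumerate(self.factors):
            if f == 1:
                continue
            axis = 2 + axis_offset
            n = x.shape[axis]
            u = self._mat(n // 2 if transpose else n)
            u = u.T if transpose else u
            x = np.moveaxis(np.tensordot(u, x, axes=(1, axis)), 0, axis)
        return np.ascontiguousarray(x, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return self._apply(x, transpose=False)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self._apply(grad_out, transpose=True)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class ConvBNReLU(Sequential):
    """conv -> BN -> ReLU, the backbone's standard unit."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | Sequence[int] = 3,
        stride: int | Sequence[int] = 1,
        rng: np.random.Generator | None = None,
        role: str = "conv",
    ) -> None:
        super().__init__(
            Conv3d(in_channels, out_channels, kernel_size, stride, rng=rng, role=role),
            BatchNorm3d(out_channels),
            ReLU(),
        )

    @property
    def conv(self) -> Conv3d:
        return self.layers[0]


class ResBlock(Layer):
    """Two 3x3x3 convolutions with an identity shortcut.

    Ordering follows the residual-network convention: conv-BN-ReLU,
    conv-BN, add identity, final ReLU.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None) -> None:
        self.branch1 = ConvBNReLU(channels, channels, 3, rng=rng, role="resblock")
        self.conv2 = Conv3d(channels, channels, 3, rng=rng, role="resblock")
        self.bn2 = BatchNorm3d(channels)
        self.relu = ReLU()

    def parameters(self) -> list[Parameter]:
        return self.branch1.parameters() + self.conv2.parameters() + self.bn2.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.branch1.forward(x, training=training)
        h = self.bn2.forward(self.conv2.forward(h, training=training), training=training)
        return self.relu.forward(h + x, training=training)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        d = self.relu.backward(grad_out)
        dh = self.branch1.backward(self.conv2.backward(self.bn2.backward(d)))
        return dh + d


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
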