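"""Minimal numpy layer framework for the segmentation network.

Implements exactly the pieces the encoder-decoder needs — 3x3 same-padding
convolution (im2col + GEMM), spatial batch normalization, ReLU, 2x2 max-pool
with recorded argmax indices, the paired max-unpool, element-wise skip
addition / concatenation — each with an explicit ``backward``.  Tensors are
NHWC ``float32`` by default (``float64`` supported for numerical gradient
checks).  There is no autograd: the network in :mod:`nucseg.network` wires
forwards and backwards by hand, which is cheap for a fixed topology and keeps
every operation traceable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "MaxUnpool2x2",
    "Add",
    "Concat",
    "softmax",
    "softmax_cross_entropy",
    "he_normal",
]


class Parameter:
    """A trainable array with its gradient accumulator.

    ``is_weight`` marks parameters subject to L2 regularization (conv kernels);
    biases and batch-norm scale/shift are exempt, following the usual framework
    convention.
    """

    __slots__ = ("data", "grad", "is_weight", "name")

    def __init__(self, data: np.ndarray, is_weight: bool, name: str):
        self.data = data
        self.grad = np.zeros_like(data)
        self.is_weight = is_weight
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def he_normal(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    """Fan-in-scaled normal initializer (std = sqrt(2/fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, C*9) patch matrix for a 3x3 same-padding conv.

    Column order is (kh, kw, c): all channels of patch position (0,0) first.
    """
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    # windows over the two spatial axes -> (N, H, W, C, 3, 3)
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # -> (N, H, W, 3, 3, C) so a C-contiguous reshape yields (kh, kw, c) columns
    v = v.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(v).reshape(n * h * w, 9 * c)


class Conv2d:
    """3x3 convolution, stride 1, same (zero) padding, with bias.

    Weight layout is (9*C_in, C_out) matching the im2col column order, so the
    forward pass is a single GEMM.  The input gradient is computed as a full
    correlation of the output gradient with the spatially flipped, transposed
    kernel — a second GEMM — avoiding an explicit col2im scatter.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, name: str, dtype=np.float32):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = 9 * in_channels
        self.weight = Parameter(
            he_normal(rng, fan_in, (fan_in, out_channels), dtype),
            is_weight=True, name=f"{name}.weight")
        self.bias = Parameter(
            np.zeros(out_channels, dtype=dtype), is_weight=False,
            name=f"{name}.bias")
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        col = _im2col3x3(x)
        if training:
            self._col = col
            self._shape = x.shape
        y = col @ self.weight.data
        y += self.bias.data
        return y.reshape(n, h, w, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, co = dy.shape
        dyf = dy.reshape(n * h * w, co)
        self.weight.grad += self._col.T @ dyf
        self.bias.grad += dyf.sum(axis=0, dtype=dyf.dtype)
        self._col = None
        # dx = dy (*) rot180(W)^T: build the backward kernel (9*C_out, C_in)
        wk = self.weight.data.reshape(3, 3, self.in_channels, co)
        wb = wk[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,C_out,C_in), flipped
        wb = np.ascontiguousarray(wb).reshape(9 * co, self.in_channels)
        dx = _im2col3x3(dy) @ wb
        return dx.reshape(self._shape)


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes by batch statistics and maintains exponential
    running averages (momentum 0.1) used in inference mode.
    """

    def __init__(self, channels: int, name: str, dtype=np.float32,
                 eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype), False, f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), False, f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    @property
    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        dtype = x.dtype
        if training:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
            var = np.square(x.astype(np.float64) - mean).mean(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(dtype)
        xhat = (x - mean.astype(dtype)) * invstd
        if training:
            self._xhat = xhat
            self._invstd = invstd
        return xhat * self.gamma.data + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        axes = (0, 1, 2)
        dbeta = dy.sum(axis=axes, dtype=dy.dtype)
        dgamma = (dy * xhat).sum(axis=axes, dtype=dy.dtype)
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        # standard batch-norm input gradient
        dx = (self.gamma.data * invstd / m) * (
            m * dy - dbeta - xhat * dgamma
        )
        self._xhat = None
        return dx.astype(dy.dtype, copy=False)


class ReLU:
    parameters: list[Parameter] = []

    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2x2 stride-2 max pooling with floor rounding on odd sizes.

    Records the input spatial size and per-window argmax indices so the paired
    :class:`MaxUnpool2x2` can place values back where they came from.  With an
    odd input size the last row/column never enters any window (125 -> 62) and
    receives zero gradient.
    """

    parameters: list[Parameter] = []

    def __init__(self):
        self.indices: np.ndarray | None = None
        self.input_hw: tuple[int, int] | None = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        xr = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(xr).reshape(n, h2, w2, 4, c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self.input_hw = x.shape[1:3]
        xr = self._windows(x)
        idx = xr.argmax(axis=3)
        self.indices = idx.astype(np.int8)
        return np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _unpool_scatter(dy, self.indices, self.input_hw)

    def clear(self) -> None:
        self.indices = None


def _unpool_scatter(y: np.ndarray, indices: np.ndarray,
                    out_hw: tuple[int, int]) -> np.ndarray:
    """Place (N,h2,w2,C) values at recorded argmax positions of (N,H,W,C)."""
    n, h2, w2, c = y.shape
    h, w = out_hw
    xr = np.zeros((n, h2, w2, 4, c), dtype=y.dtype)
    np.put_along_axis(xr, indices[:, :, :, None, :].astype(np.intp),
                      y[:, :, :, None, :], axis=3)
    xr = xr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    out = np.zeros((n, h, w, c), dtype=y.dtype)
    out[:, : 2 * h2, : 2 * w2, :] = xr.reshape(n, 2 * h2, 2 * w2, c)
    return out


class MaxUnpool2x2:
    """Max-unpooling driven by the indices of a paired :class:`MaxPool2x2`.

    Restores the recorded pre-pool spatial size, so 62 -> 125 round-trips.
    A ``nearest`` mode (plain 2x nearest-neighbour upsampling cropped to the
    recorded size) is available as a configuration fallback.
    """

    parameters: list[Parameter] = []

    def __init__(self, pool: MaxPool2x2, mode: str = "indices"):
        if mode not in ("indices", "nearest"):
            raise ValueError(f"unknown unpool mode {mode!r}")
        self.pool = pool
        self.mode = mode

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h, w = self.pool.input_hw
        if self.mode == "nearest":
            up = x.repeat(2, axis=1).repeat(2, axis=2)
            n, _, _, c = x.shape
            out = np.zeros((n, h, w, c), dtype=x.dtype)
            out[:, : up.shape[1], : up.shape[2], :] = up[:, :h, :w, :]
            return out
        return _unpool_scatter(x, self.pool.indices, (h, w))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.mode == "nearest":
            h2, w2 = self.pool.indices.shape[1:3] if self.pool.indices is not None \
                else (dy.shape[1] // 2, dy.shape[2] // 2)
            dc = dy[:, : 2 * h2, : 2 * w2, :]
            n, _, _, c = dy.shape
            return dc.reshape(n, h2, 2, w2, 2, c).sum(axis=(2, 4))
        xr = MaxPool2x2._windows(dy)
        idx = self.pool.indices[:, :, :, None, :].astype(np.intp)
        return np.take_along_axis(xr, idx, axis=3)[:, :, :, 0, :]


class Add:
    """Element-wise identity-mapping skip addition (no learned projection)."""

    parameters: list[Parameter] = []

    @staticmethod
    def forward(local: np.ndarray, transferred: np.ndarray) -> np.ndarray:
        if local.shape != transferred.shape:
            raise ValueError(
                f"skip shape mismatch: {local.shape} vs {transferred.shape}"
            )
        return local + transferred

    @staticmethod
    def backward(dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return dy, dy


class Concat:
    """Channel-concatenation skip (the ablation alternative to addition)."""

    parameters: list[Parameter] = []

    @staticmethod
    def forward(local: np.ndarray, transferred: np.ndarray) -> np.ndarray:
        if local.shape[:3] != transferred.shape[:3]:
            raise ValueError(
                f"skip shape mismatch: {local.shape} vs {transferred.shape}"
            )
        return np.concatenate([local, transferred], axis=3)

    @staticmethod
    def backward(dy: np.ndarray, local_channels: int):
        return dy[..., :local_channels], dy[..., local_channels:]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel softmax over the last axis, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``targets`` holds integer class labels of shape ``logits.shape[:-1]``.
    Returns (loss, dlogits) with the 1/M mean factor already applied.
    """
    p = softmax(logits)
    m = targets.size
    onehot_p = np.take_along_axis(p, targets[..., None], axis=-1)[..., 0]
    loss = float(-np.log(np.clip(onehot_p, 1e-12, None)).mean(dtype=np.float64))
    dlogits = p.copy()
    flat = dlogits.reshape(-1, logits.shape[-1])
    flat[np.arange(m), targets.reshape(-1)] -= 1.0
    dlogits /= m
    return loss, dlogits
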