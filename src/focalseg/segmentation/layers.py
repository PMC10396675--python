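"""Minimal numpy layers with explicit forward/backward passes.

All arrays are float32 in NCHW layout. Convolutions are stride-1 with
symmetric zero padding and are computed as im2col matrix products; the
input gradient of a stride-1 convolution is itself a stride-1 convolution
with the spatially flipped, channel-swapped kernel, so no scatter-add
(col2im) is needed anywhere.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from focalseg.errors import ShapeError

DTYPE = np.float32


class Param:
    """A trainable array and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(N, C, H, W) -> (N*H'*W', C*kh*kw) patch matrix for stride-1 conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N, C, H', W', kh, kw)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), (n, ho, wo)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None, pad: int):
    """Stride-1 cross-correlation. weight: (Cout, Cin, kh, kw)."""
    cout, _cin, kh, kw = weight.shape
    cols, (n, ho, wo) = _im2col(x, kh, kw, pad)
    out = cols @ weight.reshape(cout, -1).T
    if bias is not None:
        out += bias
    return out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2), cols


def conv2d_input_grad(dout: np.ndarray, weight: np.ndarray, pad: int, in_hw) -> np.ndarray:
    """Gradient w.r.t. the conv input: full correlation with the flipped kernel."""
    _cout, _cin, kh, kw = weight.shape
    wflip = np.ascontiguousarray(weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx_pad, _ = conv2d(dout, wflip, None, kh - 1)
    h, w = in_hw
    return dx_pad[:, :, pad : pad + h, pad : pad + w]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


class ZeroCenter(Layer):
    """Subtract the training-set per-channel mean and apply a fixed rescale.

    The rescale keeps 8-bit inputs in a numerically comfortable range for
    He-initialised weights; it is a constant, not a trained statistic.
    """

    def __init__(self, n_channels: int = 3, scale: float = 1.0 / 128.0):
        self.mean = np.zeros(n_channels, dtype=DTYPE)
        self.scale = DTYPE(scale)

    def set_mean(self, mean: np.ndarray) -> None:
        self.mean = np.asarray(mean, dtype=DTYPE).reshape(-1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean[None, :, None, None]) * self.scale

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.scale


class Conv2D(Layer):
    """3x3 / 1x1 stride-1 convolution with zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        pad: int,
        rng: np.random.Generator,
    ):
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(DTYPE)
        )
        self.b = Param(np.zeros(out_channels, dtype=DTYPE))
        self.pad = pad
        self._cols: np.ndarray | None = None
        self._in_hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = x.shape[2:]
        out, self._cols = conv2d(x, self.w.value, self.b.value, self.pad)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cout = self.w.value.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.w.grad = (dflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad = dflat.sum(axis=0)
        self._cols = None
        return conv2d_input_grad(dout, self.w.value, self.pad, self._in_hw)

    def parameters(self) -> list[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"max pool requires even spatial dims, got {h}x{w}")
        patches = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        patches = np.ascontiguousarray(patches).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = patches.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(patches, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dpatches = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dpatches, self._argmax[..., None], dout[..., None], axis=-1)
        dpatches = dpatches.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dpatches).reshape(n, c, h, w)


class UpConv2D(Layer):
    """Trainable x2 up-sampling: transposed convolution with a 4x4 kernel,
    stride [2 2] and a one-pixel crop on every border, so output spatial
    dims are exactly twice the input's.

    Implemented as its algebraic equivalent: zero-interleave the input and
    run a stride-1 convolution with padding kernel - 1 - crop = 2.
    """

    CROP = 1
    KERNEL = 4

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        k = self.KERNEL
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, (out_channels, in_channels, k, k)).astype(DTYPE))
        self.b = Param(np.zeros(out_channels, dtype=DTYPE))

    @property
    def _pad(self) -> int:
        return self.KERNEL - 1 - self.CROP

    @staticmethod
    def _stuff(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        z = np.zeros((n, c, 2 * h - 1, 2 * w - 1), dtype=x.dtype)
        z[:, :, ::2, ::2] = x
        return z

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self._stuff(x)
        self._z_hw = z.shape[2:]
        out, self._cols = conv2d(z, self.w.value, self.b.value, self._pad)
        return out  # (N, Cout, 2H, 2W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cout = self.w.value.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.w.grad = (dflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad = dflat.sum(axis=0)
        self._cols = None
        dz = conv2d_input_grad(dout, self.w.value, self._pad, self._z_hw)
        return dz[:, :, ::2, ::2]

    def parameters(self) -> list[Param]:
        return [self.w, self.b]


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of an NCHW tensor."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
):
    """Mean per-pixel weighted cross-entropy and its gradient w.r.t. logits.

    ``targets``: (N, H, W) integer class ids; ``class_weights``: (K,).
    """
    probs = softmax_channels(logits)
    k = logits.shape[1]
    onehot = np.eye(k, dtype=logits.dtype)[targets].transpose(0, 3, 1, 2)
    w_pix = class_weights.astype(logits.dtype)[targets]  # (N, H, W)
    norm = w_pix.sum()
    p_true = np.clip((probs * onehot).sum(axis=1), 1e-12, None)
    loss = float(-(w_pix * np.log(p_true)).sum() / norm)
    grad = (probs - onehot) * w_pix[:, None, :, :] / norm
    return loss, grad


class SGDMomentum:
    """Classic momentum update: v <- mu v - lr g; w <- w + v (in place)."""

    def __init__(self, parameters: list[Param], lr: float, momentum: float = 0.9):
        self.parameters = parameters
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in parameters]

    def step(self) -> None:
        for p, v in zip(self.parameters, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
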