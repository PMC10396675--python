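"""The 14-layer encoder-decoder pixel-classification network.

Counted units: input (zero-center), three (conv 3x3 + ReLU) pairs, 2x2 max
pool, one more (conv 3x3 + ReLU), a 4x4/stride-2 transposed convolution
(crop 1), a 1x1 conv to 2 channels, softmax, and the pixel-classification
loss. One x1/2 down-sample is cancelled by one x2 up-sample, so output
spatial dims always equal input dims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from focalseg.errors import ShapeError, ValidationError
from focalseg.segmentation.layers import (
    DTYPE,
    Conv2D,
    Layer,
    MaxPool2,
    Param,
    ReLU,
    UpConv2D,
    ZeroCenter,
    softmax_channels,
)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class SegNetConfig:
    """Architecture parameters. The layer stack itself is fixed."""

    input_size: tuple[int, int, int] = (128, 128, 3)
    n_filters: int = 32
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, c = self.input_size
        if h % 2 or w % 2:
            raise ShapeError(
                f"input spatial dims must be divisible by 2 (pool/up-sample pair), got {h}x{w}"
            )
        if c != 3:
            raise ValidationError("input_size must have 3 channels")
        if self.n_filters < 1:
            raise ValidationError("n_filters must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")


class SegNet:
    """Pure-numpy trainable network; forward yields per-pixel logits."""

    def __init__(self, config: SegNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, k = config.n_filters, config.n_classes
        self.zero_center = ZeroCenter(n_channels=config.input_size[2])
        self.layers: list[Layer] = [
            self.zero_center,
            Conv2D(config.input_size[2], f, 3, 1, rng), ReLU(),
            Conv2D(f, f, 3, 1, rng), ReLU(),
            Conv2D(f, f, 3, 1, rng), ReLU(),
            MaxPool2(),
            Conv2D(f, f, 3, 1, rng), ReLU(),
            UpConv2D(f, f, rng),
            Conv2D(f, k, 1, 0, rng),
        ]

    # -- inference ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:  # single (H, W, C) image
            x = x.transpose(2, 0, 1)[None]
        elif x.ndim == 4 and x.shape[-1] == self.config.input_size[2]:
            x = x.transpose(0, 3, 1, 2)
        h, w, c = self.config.input_size
        if x.shape[1] != c or x.shape[2] % 2 or x.shape[3] % 2:
            raise ShapeError(
                f"expected (N, H, W, {c}) input with even spatial dims, got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) or (H, W, 3) 8-bit input -> (N, K, H, W) logits."""
        out = self._check_input(x)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(..., H, W, 3) -> (N, H, W, K) per-pixel class probabilities."""
        probs = softmax_channels(self.forward(x))
        return probs.transpose(0, 2, 3, 1)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        state["zero_center_mean"] = self.zero_center.mean
        return state

    def save(self, path) -> None:
        np.savez(
            path,
            checkpoint_version=np.int64(CHECKPOINT_VERSION),
            input_size=np.array(self.config.input_size),
            n_filters=np.int64(self.config.n_filters),
            n_classes=np.int64(self.config.n_classes),
            seed=np.int64(self.config.seed),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "SegNet":
        with np.load(path) as data:
            version = int(data["checkpoint_version"])
            if version != CHECKPOINT_VERSION:
                raise ValidationError(
                    f"checkpoint version {version} unsupported (expected {CHECKPOINT_VERSION})"
                )
            config = SegNetConfig(
                input_size=tuple(int(v) for v in data["input_size"]),
                n_filters=int(data["n_filters"]),
                n_classes=int(data["n_classes"]),
                seed=int(data["seed"]),
            )
            net = cls(config)
            for i, p in enumerate(net.parameters()):
                p.value[...] = data[f"param_{i}"]
            net.zero_center.set_mean(data["zero_center_mean"])
        return net


def build_network(config: SegNetConfig) -> SegNet:
    """Construct the (untrained) pixel-classification network."""
    return SegNet(config)


def predict_mask(network: SegNet, image: np.ndarray) -> np.ndarray:
    """Arg-max over the per-pixel class probabilities -> {0,1} uint8 grid.

    Ties break toward the lower class index (background); ``np.argmax``
    returns the first maximal index, which implements exactly that rule.
    """
    probs = network.predict_proba(image)
    return probs[0].argmax(axis=-1).astype(np.uint8)
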