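"""Training harness: 70/30 slice-level split, weighted pixel cross-entropy,
stochastic gradient descent with momentum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from focalseg.errors import ValidationError
from focalseg.segmentation.layers import DTYPE, SGDMomentum, weighted_cross_entropy
from focalseg.segmentation.metrics import SegMetrics, compute_seg_metrics, per_class_iou
from focalseg.segmentation.network import SegNet, predict_mask
from focalseg.synthetic_data import MALIGNANT, LabeledSlice

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.70
    epochs: int = 30
    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 4
    class_weighting: str = "inverse-frequency"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.class_weighting not in ("none", "inverse-frequency"):
            raise ValidationError("class_weighting must be 'none' or 'inverse-frequency'")


@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)  # epoch, loss, val_iou
    train_indices: list[int] = field(default_factory=list)
    test_indices: list[int] = field(default_factory=list)
    val_metrics: SegMetrics | None = None


def split_slices(
    slices: list[LabeledSlice], train_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Deterministic slice-level split, stratified on 'contains a malignant
    nodule'; the train side has exactly round(train_fraction * n) slices."""
    n = len(slices)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    strata: dict[bool, list[int]] = {True: [], False: []}
    for i, sl in enumerate(slices):
        has_mal = any(nod.label == MALIGNANT for nod in sl.nodules)
        strata[has_mal].append(i)

    # proportional allocation, largest-remainder rounding to hit n_train exactly
    keys = [k for k in (False, True) if strata[k]]
    quotas = {k: train_fraction * len(strata[k]) for k in keys}
    takes = {k: int(np.floor(quotas[k])) for k in keys}
    remaining = n_train - sum(takes.values())
    for k in sorted(keys, key=lambda k: quotas[k] - takes[k], reverse=True):
        if remaining <= 0:
            break
        if takes[k] < len(strata[k]):
            takes[k] += 1
            remaining -= 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for k in keys:
        order = rng.permutation(strata[k])
        train_idx.extend(int(i) for i in order[: takes[k]])
        test_idx.extend(int(i) for i in order[takes[k] :])
    return sorted(train_idx), sorted(test_idx)


def _stack(slices: list[LabeledSlice]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in slices]).astype(DTYPE)  # (N, H, W, 3)
    masks = np.stack([s.mask for s in slices]).astype(np.int64)
    return images, masks


def evaluate(network: SegNet, slices: list[LabeledSlice]) -> SegMetrics:
    """Pool pixel confusion over slices (metrics computed on concatenated masks)."""
    preds = [predict_mask(network, s.image) for s in slices]
    pred_all = np.concatenate([p.ravel() for p in preds]).reshape(1, -1)
    truth_all = np.concatenate([s.mask.ravel() for s in slices]).reshape(1, -1)
    # BF score is geometric; compute it per slice and average, the pixel
    # metrics on the pooled confusion.
    pooled = compute_seg_metrics(pred_all, truth_all, bf_tolerance=0.0)
    bf = float(
        np.mean(
            [
                compute_seg_metrics(p, s.mask).mean_bf_score
                for p, s in zip(preds, slices)
            ]
        )
    )
    return SegMetrics(
        global_accuracy=pooled.global_accuracy,
        mean_accuracy=pooled.mean_accuracy,
        mean_iou=pooled.mean_iou,
        weighted_iou=pooled.weighted_iou,
        mean_bf_score=bf,
    )


def nodule_iou(network: SegNet, slices: list[LabeledSlice]) -> float:
    """Pooled nodule-class IoU over a slice set."""
    tp = fp = fn = 0
    for s in slices:
        pred = predict_mask(network, s.image).astype(bool)
        truth = s.mask.astype(bool)
        tp += int((pred & truth).sum())
        fp += int((pred & ~truth).sum())
        fn += int((~pred & truth).sum())
    union = tp + fp + fn
    return tp / union if union else float("nan")


def train(
    network: SegNet, slices: list[LabeledSlice], cfg: TrainConfig
) -> TrainResult:
    """Fit the network on a 70/30 slice split; returns history and held-out metrics."""
    if len(slices) < 2:
        raise ValidationError("need at least 2 slices to train")
    train_idx, test_idx = split_slices(slices, cfg.train_fraction, cfg.seed)
    train_slices = [slices[i] for i in train_idx]
    test_slices = [slices[i] for i in test_idx]

    images, masks = _stack(train_slices)
    for cls, name in ((0, "background"), (1, "nodule")):
        if not (masks == cls).any():
            raise ValidationError(f"class '{name}' absent from training pixels")

    network.zero_center.set_mean(images.mean(axis=(0, 1, 2)))

    if cfg.class_weighting == "inverse-frequency":
        counts = np.array([(masks == 0).sum(), (masks == 1).sum()], dtype=float)
        weights = counts.sum() / (2.0 * counts)
    else:
        weights = np.ones(2)

    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = SGDMomentum(network.parameters(), cfg.learning_rate, cfg.momentum)
    result = TrainResult(train_indices=train_idx, test_indices=test_idx)

    n = len(train_slices)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            logits = network.forward(images[batch])
            loss, dlogits = weighted_cross_entropy(logits, masks[batch], weights)
            network.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        val_iou = nodule_iou(network, test_slices)
        result.history.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)), "val_iou": val_iou}
        )
        logger.info("epoch %d: loss=%.4f val_nodule_iou=%.4f", epoch + 1, np.mean(losses), val_iou)

    result.val_metrics = evaluate(network, test_slices)
    return result
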