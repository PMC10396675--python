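"""Segmentation scoring: the five-metric suite over binary masks.

Conventions: per-class IoU = TP / (TP + FP + FN); mean accuracy averages
per-class recall over classes present in the truth; weighted IoU weights
per-class IoU by truth pixel frequency; the boundary-F1 (BF) score matches
boundary pixels between prediction and truth within a pixel tolerance
(default 0.75% of the image diagonal) and averages F1 over classes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from focalseg.errors import ShapeError


@dataclass(frozen=True)
class SegMetrics:
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_bf_score: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _validate(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not set(np.unique(arr).tolist()) <= {0, 1}:
            raise ShapeError(f"{name} must be binary {{0,1}}, found {np.unique(arr)}")
    return pred.astype(bool), truth.astype(bool)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` adjacent (4-connectivity) to a pixel outside it.

    Image-border pixels are not boundary unless an in-image neighbour differs.
    """
    eroded = ndimage.binary_erosion(mask, border_value=1)
    return mask & ~eroded


def _bf_score_class(pred_c: np.ndarray, truth_c: np.ndarray, tol: float) -> float:
    pb, tb = _boundary(pred_c), _boundary(truth_c)
    if not pb.any() and not tb.any():
        return 1.0
    if not pb.any() or not tb.any():
        return 0.0
    dist_to_truth = ndimage.distance_transform_edt(~tb)
    dist_to_pred = ndimage.distance_transform_edt(~pb)
    precision = float((dist_to_truth[pb] <= tol).mean())
    recall = float((dist_to_pred[tb] <= tol).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_seg_metrics(
    pred: np.ndarray, truth: np.ndarray, bf_tolerance: float | None = None
) -> SegMetrics:
    """Score a predicted binary mask against the ground truth."""
    pred_b, truth_b = _validate(pred, truth)
    h, w = truth_b.shape
    if bf_tolerance is None:
        bf_tolerance = 0.0075 * float(np.hypot(h, w))

    n = truth_b.size
    recalls, ious, freqs, bfs = [], [], [], []
    correct = 0
    for cls in (False, True):
        p_c, t_c = pred_b == cls, truth_b == cls
        tp = int((p_c & t_c).sum())
        fp = int((p_c & ~t_c).sum())
        fn = int((~p_c & t_c).sum())
        correct += tp
        if t_c.any():
            recalls.append(tp / (tp + fn))
        union = tp + fp + fn
        if union > 0:
            ious.append(tp / union)
            freqs.append(int(t_c.sum()))
        bfs.append(_bf_score_class(p_c, t_c, bf_tolerance))

    freq_arr = np.asarray(freqs, dtype=float)
    iou_arr = np.asarray(ious, dtype=float)
    weighted = float((freq_arr / freq_arr.sum()) @ iou_arr) if freq_arr.sum() else 0.0
    return SegMetrics(
        global_accuracy=correct / n,
        mean_accuracy=float(np.mean(recalls)),
        mean_iou=float(np.mean(iou_arr)),
        weighted_iou=weighted,
        mean_bf_score=float(np.mean(bfs)),
    )


def per_class_iou(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """IoU per class name ('background', 'nodule'); NaN where the union is empty."""
    pred_b, truth_b = _validate(pred, truth)
    out = {}
    for name, cls in (("background", False), ("nodule", True)):
        p_c, t_c = pred_b == cls, truth_b == cls
        union = int((p_c | t_c).sum())
        out[name] = float((p_c & t_c).sum() / union) if union else float("nan")
    return out
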