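"""Weighted cross-entropy loss and the segmentation evaluation suite.

The loss is the class-weighted multinomial cross-entropy

    loss(x, class) = weight[class] * (-x[class] + log sum_j exp(x[j]))

averaged over pixels with the applied weights as the denominator.  The
default weights (0.8, 1, 1.2) for (background, crop, vacancy) upweight the
rare vacancy class.  An auxiliary loss from an early backbone stage is added
with a small proportion ("loss reuse").

Evaluation derives everything from a 3×3 confusion matrix: pixel accuracy,
per-class IoU and mIoU, and the vacancy ratio VR = V / (C + V) with its
relative error |VR_f - VR_p| / VR_f between reference and predicted masks.
The relative form makes the error forgiving when the true vacancy ratio is
already high and strict when the field is nearly fully planted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grad import Tensor

NUM_CLASSES = 3
DEFAULT_CLASS_WEIGHTS = (0.8, 1.0, 1.2)   # background, crop, vacancy


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (NUM_CLASSES,) or (w <= 0).any():
        raise ValueError(f"class weights must be 3 positive reals, got {weights}")
    return w


def weighted_ce_loss(logits, mask, weights=DEFAULT_CLASS_WEIGHTS,
                     reduction: str = "weighted_mean"):
    """Class-weighted cross-entropy over all pixels.

    `logits` is a Tensor or array of shape (B,3,H,W) (or (3,H,W)); `mask`
    holds class indices of matching spatial shape.  Returns a scalar Tensor
    (differentiable when `logits` is part of a graph), computed with a
    numerically stable log-sum-exp.

    Reductions: ``weighted_mean`` (default) divides the sum of weighted
    per-pixel losses by the sum of applied weights, so uniformly scaling the
    weights leaves the loss unchanged; ``mean`` divides by the pixel count,
    reporting the plain average of the weighted per-pixel losses; ``sum``
    applies no normalization.
    """
    if reduction not in ("weighted_mean", "mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    w = _check_weights(weights)
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    if not np.isfinite(logits.data).all():
        raise ValueError("logits contain non-finite values")
    b, c, h, wd = logits.shape
    if c != NUM_CLASSES or mask.shape != (b, h, wd):
        raise ValueError(f"shape mismatch: logits {logits.shape} vs mask {mask.shape}")
    # stable log-sum-exp; the shift is a constant w.r.t. the gradient
    shift = logits.data.max(axis=1, keepdims=True)
    lse = (logits - shift).exp().sum(axis=1, keepdims=True).log() + shift
    onehot = np.zeros((b, c, h, wd), dtype=logits.data.dtype)
    np.put_along_axis(onehot, mask[:, None].astype(np.intp), 1.0, axis=1)
    picked = (logits * onehot).sum(axis=1, keepdims=True)
    pixel_w = w[mask][:, None]
    num = ((lse - picked) * pixel_w).sum()
    if reduction == "sum":
        return num
    denom = float(pixel_w.sum()) if reduction == "weighted_mean" else float(pixel_w.size)
    return num * (1.0 / denom)


def total_loss(main_logits, aux_logits, mask, weights=DEFAULT_CLASS_WEIGHTS,
               aux_lambda: float = 0.4):
    """Main weighted cross-entropy plus `aux_lambda` times the auxiliary one."""
    if aux_lambda < 0:
        raise ValueError("aux_lambda must be nonnegative")
    main = weighted_ce_loss(main_logits, mask, weights)
    if aux_logits is None or aux_lambda == 0:
        return main
    return main + aux_lambda * weighted_ce_loss(aux_logits, mask, weights)


def confusion(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """3×3 confusion counts; rows are the reference class, columns the prediction."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    idx = ref.astype(np.intp).ravel() * NUM_CLASSES + pred.astype(np.intp).ravel()
    return np.bincount(idx, minlength=NUM_CLASSES ** 2).reshape(NUM_CLASSES, NUM_CLASSES)


def vacancy_ratio(vacancy_area: float, crop_area: float) -> float | None:
    """VR = V / (C + V); undefined (None) when the field has no crop or vacancy."""
    total = crop_area + vacancy_area
    return None if total == 0 else vacancy_area / total


def vacancy_ratio_error(vr_true: float | None, vr_pred: float | None) -> float | None:
    """Relative vacancy-ratio error |VR_f - VR_p| / VR_f; None when undefined."""
    if vr_true is None or vr_pred is None or vr_true == 0:
        return None
    return abs(vr_true - vr_pred) / vr_true


@dataclass
class SegMetrics:
    pixel_accuracy: float
    iou_per_class: tuple
    miou: float
    vr_true: float | None
    vr_pred: float | None
    vr_error: float | None

    def as_dict(self) -> dict:
        return {"pixel_accuracy": self.pixel_accuracy,
                "iou_background": self.iou_per_class[0],
                "iou_crop": self.iou_per_class[1],
                "iou_vacancy": self.iou_per_class[2],
                "miou": self.miou,
                "vr_true": self.vr_true, "vr_pred": self.vr_pred,
                "vr_error": self.vr_error}


def compute_metrics(cm: np.ndarray) -> SegMetrics:
    """All evaluation metrics from one confusion matrix.

    mIoU averages only the classes whose union is nonzero in the evaluated
    set.  The vacancy ratio uses reference counts (row sums) for VR_f and
    predicted counts (column sums) for VR_p, with the background class
    excluded from both numerator and denominator.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.shape != (NUM_CLASSES, NUM_CLASSES) or (cm < 0).any():
        raise ValueError("confusion matrix must be 3×3 nonnegative counts")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    pa = np.trace(cm) / total
    row, col = cm.sum(axis=1), cm.sum(axis=0)
    ious = []
    for i in range(NUM_CLASSES):
        union = row[i] + col[i] - cm[i, i]
        ious.append(cm[i, i] / union if union > 0 else np.nan)
    defined = [v for v in ious if not np.isnan(v)]
    miou = float(np.mean(defined)) if defined else float("nan")
    vr_t = vacancy_ratio(row[2], row[1])
    vr_p = vacancy_ratio(col[2], col[1])
    return SegMetrics(pixel_accuracy=float(pa),
                      iou_per_class=tuple(float(v) for v in ious),
                      miou=miou, vr_true=vr_t, vr_pred=vr_p,
                      vr_error=vacancy_ratio_error(vr_t, vr_p))


def evaluate_masks(pred_masks, ref_masks) -> tuple[SegMetrics, list[SegMetrics]]:
    """Pooled metrics over paired masks plus the per-image breakdown."""
    pooled = np.zeros((NUM_CLASSES, NUM_CLASSES), dtype=np.int64)
    per_image = []
    for pred, ref in zip(pred_masks, ref_masks):
        cm = confusion(pred, ref)
        pooled += cm
        per_image.append(compute_metrics(cm))
    return compute_metrics(pooled), per_image
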