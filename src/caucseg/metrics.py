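"""Pixel-wise segmentation metrics.

All rates derive from one-vs-rest confusion tallies pooled over every evaluated
pixel.  Accuracy, precision, recall and F1 come in micro (counts pooled over
classes first), per-class, and macro (unweighted mean of per-class) modes.
MIoU is the macro mean of pixel-pooled per-class IoU, excluding classes absent
from both prediction and truth.  The loss is the per-pixel mean categorical
cross-entropy, commensurable with percentage-scale reporting.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .palettes import NUM_CLASSES, SOIL


@dataclass
class ConfusionTally:
    """Per-class one-vs-rest pixel tallies; tp+fp+tn+fn is the same for every
    class and equals the total pixel count."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    num_classes: int

    @property
    def total(self):
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion(pred, truth, num_classes=NUM_CLASSES):
    """Tally one-vs-rest confusion counts over batches of class rasters."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size and (pred.max() >= num_classes or truth.max() >= num_classes):
        raise ValueError(f"class entries must be < {num_classes}")
    joint = np.bincount(truth.ravel() * num_classes + pred.ravel(),
                        minlength=num_classes * num_classes).reshape(num_classes, num_classes)
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = joint.sum() - tp - fp - fn
    return ConfusionTally(tp=tp, fp=fp, fn=fn, tn=tn, num_classes=num_classes)


def _safe_div(num, den, what):
    num, den = np.asarray(num, dtype=np.float64), np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    zero = den == 0
    if np.any(zero):
        warnings.warn(f"zero denominator in {what}; defining the rate as 0", stacklevel=3)
    np.divide(num, den, out=out, where=~zero)
    return out


def _modal(per_class, tally, mode, micro_num, micro_den, what):
    if mode == "per_class":
        return per_class
    if mode == "macro":
        return float(per_class.mean())
    if mode == "micro":
        return float(_safe_div(micro_num, micro_den, what))
    raise ValueError(f"mode must be micro/per_class/macro, got {mode!r}")


def accuracy(tally, mode="micro"):
    """(TP+TN) / (TP+FP+TN+FN).

    In micro mode this is the overall pixel accuracy (pooled TP over total,
    identical to micro precision and recall for single-label pixels);
    per-class/macro modes use the one-vs-rest form.
    """
    per = _safe_div(tally.tp + tally.tn, tally.tp + tally.fp + tally.tn + tally.fn, "accuracy")
    return _modal(per, tally, mode, tally.tp.sum(), tally.total, "accuracy")


def precision(tally, mode="micro"):
    """TP / (TP+FP)."""
    per = _safe_div(tally.tp, tally.tp + tally.fp, "precision")
    return _modal(per, tally, mode, tally.tp.sum(), (tally.tp + tally.fp).sum(), "precision")


def recall(tally, mode="micro"):
    """TP / (TP+FN)."""
    per = _safe_div(tally.tp, tally.tp + tally.fn, "recall")
    return _modal(per, tally, mode, tally.tp.sum(), (tally.tp + tally.fn).sum(), "recall")


def f1(tally, mode="micro"):
    """Harmonic mean of precision and recall (same mode)."""
    p, r = precision(tally, mode), recall(tally, mode)
    if mode == "per_class":
        return _safe_div(2 * p * r, p + r, "f1")
    return float(_safe_div(2 * p * r, p + r, "f1"))


def cce_loss(pred_prob, onehot_truth, eps=1e-7):
    """Mean per-pixel categorical cross-entropy, -sum_j A_ij log P_ij."""
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(onehot_truth, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {y.shape}")
    p = np.clip(p, eps, 1.0)
    npix = int(np.prod(p.shape[:-1]))
    return float(-(y * np.log(p)).sum() / npix)


def mean_iou(pred, truth, num_classes=NUM_CLASSES, include_soil=True):
    """Macro mean over classes of pixel-pooled intersection-over-union.

    Classes absent from both prediction and truth are excluded from the mean;
    ``include_soil=False`` additionally drops the background class.
    """
    tally = confusion(pred, truth, num_classes)
    union = tally.tp + tally.fp + tally.fn
    keep = union > 0
    if not include_soil:
        keep = keep & (np.arange(num_classes) != SOIL)
    if not keep.any():
        raise ValueError("no class present in either prediction or truth")
    iou = tally.tp[keep] / union[keep]
    return float(iou.mean())


def per_class_iou(pred, truth, num_classes=NUM_CLASSES):
    tally = confusion(pred, truth, num_classes)
    union = tally.tp + tally.fp + tally.fn
    return _safe_div(tally.tp, union, "iou")


def mean_response_time(model, batch, repeats=3):
    """Mean wall-clock seconds per image for inference, with the sample
    variance across repeats.  Reported, never asserted."""
    from .model import forward as model_forward

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    batch = np.asarray(batch)
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model_forward(model, batch)
        times.append((time.perf_counter() - t0) / max(len(batch), 1))
    times = np.asarray(times)
    return float(times.mean()), float(times.var(ddof=1)) if repeats > 1 else 0.0


@dataclass
class MetricsReport:
    """Bundle of the evaluation metrics for one model/dataset pair."""

    n_samples: int
    num_classes: int
    accuracy_micro: float
    loss: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    miou: float
    miou_no_soil: float
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    npm: int = 0
    mrt_seconds: float = float("nan")
    mrt_variance: float = float("nan")
    notes: list = field(default_factory=list)

    def as_dict(self):
        return dict(self.__dict__)


def evaluate_predictions(pred_prob, truth_classes, npm=0, mrt=(float("nan"), float("nan"))):
    """Assemble a MetricsReport from probability volumes and truth rasters."""
    from .palettes import classes_to_onehot

    pred_prob = np.asarray(pred_prob)
    truth_classes = np.asarray(truth_classes)
    pred_classes = pred_prob.argmax(axis=-1)
    tally = confusion(pred_classes, truth_classes)
    onehot = np.stack([classes_to_onehot(t, tally.num_classes) for t in truth_classes])
    notes = []
    present = np.union1d(np.unique(pred_classes), np.unique(truth_classes))
    absent = sorted(set(range(tally.num_classes)) - set(present.tolist()))
    if absent:
        notes.append(f"classes absent from prediction and truth, excluded from MIoU: {absent}")
    return MetricsReport(
        n_samples=len(truth_classes),
        num_classes=tally.num_classes,
        accuracy_micro=accuracy(tally),
        loss=cce_loss(pred_prob, onehot),
        precision_micro=precision(tally),
        recall_micro=recall(tally),
        f1_micro=f1(tally),
        miou=mean_iou(pred_classes, truth_classes),
        miou_no_soil=mean_iou(pred_classes, truth_classes, include_soil=False),
        per_class={
            "precision": precision(tally, "per_class").tolist(),
            "recall": recall(tally, "per_class").tolist(),
            "f1": f1(tally, "per_class").tolist(),
            "iou": per_class_iou(pred_classes, truth_classes).tolist(),
        },
        macro={
            "precision": precision(tally, "macro"),
            "recall": recall(tally, "macro"),
            "f1": f1(tally, "macro"),
        },
        npm=npm,
        mrt_seconds=mrt[0],
        mrt_variance=mrt[1],
        notes=notes,
    )
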