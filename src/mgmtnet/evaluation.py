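"""Metrics, ROC/AUC, fold aggregation, and the end-to-end prediction path.

Classification metrics follow the confusion-count definitions with
"methylated" as the positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

Zero-denominator cases return 0 (with a warning).  Segmentation quality is
the Dice coefficient of the binarized probability map against the truth
mask; two empty masks count as perfect agreement.  Cross-validated results
are reported as "mean ± standard deviation" over folds, sample standard
deviation, three decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classification_model import (CLASS_ORDER, MethylationCNN, cascade_input,
                                   classify)
from .preprocessing import (StandardScale, foreground_mask, standardize_image,
                            zscore_foreground)
from .segmentation_model import SegmentationNet, soft_dice

__all__ = [
    "ConfusionCounts", "RocCurve", "PipelinePrediction",
    "confusion_counts", "classification_metrics", "roc_auc",
    "evaluate_segmentation", "aggregate_folds", "predict_pipeline",
    "majority_vote", "plot_roc",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class RocCurve:
    """ROC curve points, from (0,0) to (1,1), threshold-decreasing."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                      "tpr": self.tpr}).to_csv(path, index=False)


@dataclass
class PipelinePrediction:
    mask: np.ndarray
    label: str
    p_methylated: float
    empty_mask: bool = False


def confusion_counts(true_labels, predicted_labels,
                     positive_class=1) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the given positive class (default: the
    methylated / 1 encoding)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label lists must be equal-length and non-empty")
    tp = int(((t == positive_class) & (p == positive_class)).sum())
    tn = int(((t != positive_class) & (p != positive_class)).sum())
    fp = int(((t != positive_class) & (p == positive_class)).sum())
    fn = int(((t == positive_class) & (p != positive_class)).sum())
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision and F1 from confusion counts."""
    if c.total < 1:
        raise ValueError("confusion counts are all zero")
    acc = (c.TP + c.TN) / c.total
    rec = _safe_div(c.TP, c.TP + c.FN, "recall")
    prec = _safe_div(c.TP, c.TP + c.FP, "precision")
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1")
    return {"accuracy": acc, "recall": rec, "precision": prec, "f1": f1}


def roc_auc(scores, true_labels) -> tuple[RocCurve, float]:
    """ROC curve (threshold sweep over unique scores) and trapezoidal AUC.

    The AUC equals the Mann-Whitney pair statistic with ties counted 1/2.
    Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    if s.shape != t.shape:
        raise ValueError("scores and labels must be parallel")
    if np.unique(t).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(t, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr), auc


def evaluate_segmentation(pred_map, truth_mask, threshold: float = 0.5) -> float:
    """Dice of the thresholded probability map against the binary truth.

    Two empty masks give 1.0 (perfect agreement); the epsilon-regularized
    formula alone would give 0 for that degenerate case.
    """
    p = np.asarray(pred_map, dtype=float)
    t = np.asarray(truth_mask)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    pb = (p >= threshold).astype(float)
    tb = (t > 0).astype(float)
    if pb.sum() == 0 and tb.sum() == 0:
        return 1.0
    return soft_dice(pb, tb)


def aggregate_folds(values) -> tuple[str, tuple[float, float]]:
    """Cross-validation report entry: "m.mmm ± s.sss" (sample std, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 fold values")
    m = float(v.mean())
    s = float(v.std(ddof=1))
    return f"{m:.3f} ± {s:.3f}", (m, s)


def majority_vote(case_ids, slice_probabilities,
                  threshold: float = 0.5) -> dict[str, str]:
    """Optional patient-level aggregation of slice predictions.

    Classification is evaluated per slice by default; this helper averages
    each case's slice-level methylation probabilities and thresholds the
    mean, for workflows that want one call per patient.
    """
    probs: dict[str, list[float]] = {}
    for cid, p in zip(case_ids, slice_probabilities):
        probs.setdefault(cid, []).append(float(p))
    return {cid: (CLASS_ORDER[0] if float(np.mean(v)) > threshold
                  else CLASS_ORDER[1])
            for cid, v in probs.items()}


def plot_roc(curves: dict, path=None, title: str = "ROC"):
    """Plot one or more named ROC curves (label -> (RocCurve, auc)).

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, (curve, auc) in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def predict_pipeline(raw_image, scale: StandardScale, seg_model: SegmentationNet,
                     cls_model: MethylationCNN,
                     threshold: float = 0.5) -> PipelinePrediction:
    """End-to-end inference on one raw slice.

    standardize -> foreground z-score -> segment -> binarize at the
    threshold -> mask the image, crop to the tumor bounding box and
    resample to the classifier geometry -> classify.  An empty predicted
    mask is flagged but classification still runs (on the all-zero input).
    """
    raw = np.asarray(raw_image, dtype=float)
    fg = foreground_mask(raw)
    std = standardize_image(raw, scale)
    z = zscore_foreground(std, mask=fg)
    prob = seg_model.predict_proba(z)
    mask = (prob >= threshold).astype(np.uint8)
    empty = mask.sum() == 0
    if empty:
        warnings.warn("empty predicted tumor mask; classifying zero image",
                      stacklevel=2)
    c = cls_model.config
    masked = cascade_input(z, mask, c.input_height, c.input_width)
    cp = classify(masked, cls_model)
    return PipelinePrediction(mask=mask, label=cp.label,
                              p_methylated=cp.p_methylated, empty_mask=empty)
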