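"""High-level orchestration shared by the CLI, tests and reports.

Glues the stages together: load / generate slices, fit the intensity
standard scale on training cases only (no leakage into validation or
test), train the segmenter, cascade the classifier on
segmentation-masked inputs, and score both stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification_model import (CLASS_ORDER, ClsConfig, MethylationCNN,
                                   cascade_input)
from .data_model import DatasetManifest
from .evaluation import (classification_metrics, confusion_counts,
                         evaluate_segmentation, roc_auc)
from .preprocessing import (fit_standard_scale, foreground_mask,
                            standardize_image, zscore_foreground)
from .segmentation_model import SegConfig, SegmentationNet
from .synthetic_data import load_slice
from .training import (ClsTrainConfig, SegTrainConfig, TrainingResult,
                       train_classifier, train_segmentation)

__all__ = ["SliceDataset", "ExperimentResult", "label_to_int",
           "run_experiment"]


def label_to_int(label: str) -> int:
    """0 = methylated (positive class), 1 = unmethylated."""
    return CLASS_ORDER.index(label)


@dataclass
class SliceDataset:
    """Flat slice-level arrays with case bookkeeping."""

    images: list
    masks: list
    labels: list
    case_ids: list

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest) -> "SliceDataset":
        images, masks, labels, case_ids = [], [], [], []
        for c in manifest.cases:
            for s, m in zip(c.slice_refs, c.mask_refs):
                images.append(load_slice(s))
                masks.append((load_slice(m) > 0).astype(np.uint8))
                labels.append(c.label)
                case_ids.append(c.case_id)
        return cls(images, masks, labels, case_ids)

    def indices_for(self, case_set) -> list[int]:
        s = set(case_set)
        return [i for i, c in enumerate(self.case_ids) if c in s]


@dataclass
class ExperimentResult:
    """Everything one train/evaluate cycle produces."""

    seg_result: TrainingResult
    cls_result: TrainingResult
    scale: object
    test_dice: list[float] = field(default_factory=list)
    test_metrics: dict = field(default_factory=dict)
    test_auc: float = float("nan")
    val_dice: list[float] = field(default_factory=list)
    val_metrics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["== segmentation ==", self.seg_result.summary(),
                 f"test Dice: {np.mean(self.test_dice):.3f}",
                 "== classification ==", self.cls_result.summary()]
        for k, v in self.test_metrics.items():
            lines.append(f"test {k}: {v:.3f}")
        if np.isfinite(self.test_auc):
            lines.append(f"test AUC: {self.test_auc:.3f}")
        return "\n".join(lines)


def _preprocess(dataset: SliceDataset, train_idx, percentiles=(1.0, 99.0)):
    scale = fit_standard_scale([dataset.images[i] for i in train_idx],
                               percentiles)
    z = []
    for img in dataset.images:
        fg = foreground_mask(img)
        z.append(zscore_foreground(standardize_image(img, scale),
                                   mask=fg).astype(np.float32))
    return scale, z


def run_experiment(dataset: SliceDataset, train_cases, val_cases, test_cases,
                   seg_config: SegConfig, seg_train: SegTrainConfig,
                   cls_config: ClsConfig, cls_train: ClsTrainConfig,
                   percentiles=(1.0, 99.0), mask_threshold: float = 0.5,
                   augment_seg=None, augment_cls=True) -> ExperimentResult:
    """Train and score the cascaded pipeline for one split.

    ``augment_seg``: optional AugmentationPlan for the segmentation
    training slices (off by default at desk scale, where the segmenter
    converges without it).  ``augment_cls``: apply the default nine-angle
    rotation sweep to the classifier's training slices (on by default; the
    small-cohort classifier depends on it).
    """
    fit_idx = dataset.indices_for(train_cases)
    val_idx = dataset.indices_for(val_cases)
    test_idx = dataset.indices_for(test_cases)
    if not fit_idx or not val_idx:
        raise ValueError("empty training or validation partition")
    scale, z = _preprocess(dataset, fit_idx, percentiles)

    Xf = [z[i] for i in fit_idx]
    Yf = [dataset.masks[i] for i in fit_idx]
    if augment_seg is not None:
        from .preprocessing import augment_rotations

        aug_pairs = [p for i in fit_idx
                     for p in augment_rotations(z[i], dataset.masks[i],
                                                augment_seg)]
        Xf = [p[0].astype(np.float32) for p in aug_pairs]
        Yf = [p[1] for p in aug_pairs]
    seg_result = train_segmentation(
        (np.stack(Xf), np.stack(Yf)),
        (np.stack([z[i] for i in val_idx]),
         np.stack([dataset.masks[i] for i in val_idx])),
        seg_config, seg_train)
    seg: SegmentationNet = seg_result.model

    pred_masks = {i: (seg.predict_proba(z[i]) >= mask_threshold).astype(np.uint8)
                  for i in fit_idx + val_idx + test_idx}

    def masked(i: int) -> np.ndarray:
        return cascade_input(z[i], pred_masks[i],
                             cls_config.input_height, cls_config.input_width)

    yint = [label_to_int(l) for l in dataset.labels]
    if augment_cls:
        from .preprocessing import AugmentationPlan, augment_rotations

        plan = AugmentationPlan()
        Xc, yc = [], []
        for i in fit_idx:
            for im_r, mk_r in augment_rotations(z[i], pred_masks[i], plan):
                Xc.append(cascade_input(im_r, mk_r, cls_config.input_height,
                                        cls_config.input_width))
                yc.append(yint[i])
    else:
        Xc = [masked(i) for i in fit_idx]
        yc = [yint[i] for i in fit_idx]
    cls_result = train_classifier(
        (np.stack(Xc), np.array(yc)),
        (np.stack([masked(i) for i in val_idx]),
         np.array([yint[i] for i in val_idx])),
        cls_config, cls_train)
    cls: MethylationCNN = cls_result.model

    def score(idx):
        dice = [evaluate_segmentation(seg.predict_proba(z[i]),
                                      dataset.masks[i], mask_threshold)
                for i in idx]
        p = cls.predict_proba(np.stack([masked(i) for i in idx]))
        y = np.array([yint[i] for i in idx])
        pred = p.argmax(axis=1)
        cc = confusion_counts((y == 0).astype(int), (pred == 0).astype(int), 1)
        metrics = classification_metrics(cc)
        auc = float("nan")
        if np.unique(y).size == 2:
            _, auc = roc_auc(p[:, 0], (y == 0).astype(int))
        return dice, metrics, auc

    val_dice, val_metrics, _ = score(val_idx)
    test_dice, test_metrics, test_auc = (score(test_idx) if test_idx
                                         else ([], {}, float("nan")))
    return ExperimentResult(seg_result=seg_result, cls_result=cls_result,
                            scale=scale, test_dice=test_dice,
                            test_metrics=test_metrics, test_auc=test_auc,
                            val_dice=val_dice, val_metrics=val_metrics)
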