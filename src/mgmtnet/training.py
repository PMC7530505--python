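"""Training loops, learning-rate scheduling and cross-validation.

Segmentation training uses Adam starting at 1e-4 with a
reduce-on-plateau rule: when the best validation loss has not improved for
5 consecutive epochs the learning rate is halved (and the patience counter
resets).  Classifier training uses Adam at 2e-4 with accuracy-stability
early stopping: training ends once the running best validation accuracy
has not improved by more than 1e-4 for 10 consecutive epochs.  Both loops
are fully deterministic given their seeds (data order, initialization,
dropout masks and VAE samples all derive from them).

``fit``-style entry points return a :class:`TrainingResult` bundling the
trained network with its per-epoch log and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification_model import ClsConfig, MethylationCNN, build_classifier
from .nn import Adam, Tensor, log_softmax
from .segmentation_model import (SegConfig, SegmentationNet, build_seg_model,
                                 seg_training_loss)

__all__ = [
    "SegTrainConfig", "ClsTrainConfig", "TrainLog", "TrainingResult",
    "PlateauScheduler", "plateau_lr", "early_stop",
    "train_segmentation", "train_classifier", "run_cross_validation",
]


@dataclass
class SegTrainConfig:
    lr0: float = 1e-4
    plateau_patience: int = 5
    lr_factor: float = 0.5
    max_epochs: int = 50
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0 or not 0 < self.lr_factor < 1:
            raise ValueError("lr0 > 0 and 0 < lr_factor < 1 required")


@dataclass
class ClsTrainConfig:
    lr: float = 2e-4
    max_epochs: int = 50
    batch_size: int = 32
    early_stop_patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainLog:
    """Per-epoch record of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.train_loss)
        return pd.DataFrame({
            "epoch": np.arange(1, n + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss if self.val_loss else [np.nan] * n,
            "val_accuracy": (self.val_accuracy if self.val_accuracy
                             else [np.nan] * n),
            "lr": self.learning_rate,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TrainingResult:
    """Trained network plus its log; ``summary()`` gives a short report."""

    model: object
    log: TrainLog

    def summary(self) -> str:
        lines = [f"model: {type(self.model).__name__}",
                 f"epochs run: {self.log.stop_epoch}",
                 f"seed: {self.log.seed}"]
        if self.log.train_loss:
            lines.append(f"final train loss: {self.log.train_loss[-1]:.4f}")
        if self.log.val_loss:
            lines.append(f"final val loss: {self.log.val_loss[-1]:.4f}")
        if self.log.val_accuracy:
            lines.append(f"final val accuracy: {self.log.val_accuracy[-1]:.4f}")
        lines.append(f"final lr: {self.log.learning_rate[-1]:.2e}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# scheduler / early-stop state machines

class PlateauScheduler:
    """Halve the learning rate when the best validation loss has not
    improved for ``patience`` consecutive epochs; the counter resets after
    each halving.  Improvement means a strictly lower best loss."""

    def __init__(self, lr0: float, patience: int = 5, factor: float = 0.5):
        self.lr = float(lr0)
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.stale = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


def plateau_lr(val_loss_history, config: SegTrainConfig) -> float:
    """Learning rate after replaying a validation-loss history."""
    if len(val_loss_history) == 0:
        raise ValueError("history must be non-empty")
    sched = PlateauScheduler(config.lr0, config.plateau_patience,
                             config.lr_factor)
    for v in val_loss_history:
        sched.step(float(v))
    return sched.lr


def early_stop(val_accuracy_history, patience: int,
               min_delta: float = 1e-4) -> bool:
    """True iff the running best accuracy has not improved by more than
    ``min_delta`` for ``patience`` consecutive epochs."""
    if len(val_accuracy_history) == 0:
        raise ValueError("history must be non-empty")
    best = -np.inf
    stale = 0
    for a in val_accuracy_history:
        if a > best + min_delta:
            best = a
            stale = 0
        else:
            stale += 1
    return stale >= patience


# ----------------------------------------------------------------------
# helpers

def _stack_xy(pairs_or_tuple):
    """Accept a list of (image, mask/label) pairs or an (X, Y) tuple."""
    if (isinstance(pairs_or_tuple, tuple) and len(pairs_or_tuple) == 2
            and isinstance(pairs_or_tuple[0], np.ndarray)
            and pairs_or_tuple[0].ndim == 3):
        X, Y = pairs_or_tuple
        return np.asarray(X, dtype=np.float32), np.asarray(Y)
    X = np.stack([p[0] for p in pairs_or_tuple]).astype(np.float32)
    Y = np.stack([np.asarray(p[1]) for p in pairs_or_tuple])
    return X, Y


def _check_finite(loss: float, epoch: int, batch: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite loss ({loss}) at epoch {epoch}, batch {batch}; "
            "reduce the learning rate or check input normalization")


# ----------------------------------------------------------------------
# segmentation training

def train_segmentation(train_data, val_data, seg_config: SegConfig | None = None,
                       config: SegTrainConfig | None = None,
                       model: SegmentationNet | None = None) -> TrainingResult:
    """Train the VAE-regularized segmentation network.

    ``train_data`` / ``val_data`` are (images, masks) tuples or lists of
    (image, mask) pairs of 2D float arrays.  Returns a
    :class:`TrainingResult`; the per-epoch learning-rate trace is
    non-increasing by the plateau rule.
    """
    cfg = config or SegTrainConfig()
    Xtr, Ytr = _stack_xy(train_data)
    Xva, Yva = _stack_xy(val_data)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ValueError("empty training or validation set")
    if model is None:
        seg_config = seg_config or SegConfig(input_height=Xtr.shape[1],
                                             input_width=Xtr.shape[2])
        model = build_seg_model(seg_config, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    sched = PlateauScheduler(cfg.lr0, cfg.plateau_patience, cfg.lr_factor)
    log = TrainLog(seed=cfg.seed)
    n = Xtr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(Xtr[idx][:, None])
            y = Tensor(Ytr[idx][:, None].astype(np.float32))
            out = model(x, rng=rng)
            loss, _ = seg_training_loss(model, out, x, y)
            _check_finite(float(loss.data), epoch, bi)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = _seg_eval_loss(model, Xva, Yva, cfg.batch_size)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val_loss)
        log.learning_rate.append(opt.lr)
        opt.lr = sched.step(val_loss)
        log.stop_epoch = epoch
    return TrainingResult(model=model, log=log)


def _seg_eval_loss(model: SegmentationNet, X, Y, batch_size: int) -> float:
    model.eval()
    losses, weights = [], []
    for start in range(0, X.shape[0], batch_size):
        x = Tensor(X[start:start + batch_size][:, None])
        y = Tensor(Y[start:start + batch_size][:, None].astype(np.float32))
        out = model(x)
        loss, _ = seg_training_loss(model, out, x, y)
        losses.append(float(loss.data))
        weights.append(x.shape[0])
    return float(np.average(losses, weights=weights))


# ----------------------------------------------------------------------
# classifier training

def train_classifier(train_data, val_data, cls_config: ClsConfig | None = None,
                     config: ClsTrainConfig | None = None,
                     model: MethylationCNN | None = None) -> TrainingResult:
    """Train the shallow methylation CNN with cross-entropy.

    ``train_data`` / ``val_data`` are (images, labels) with integer labels
    (0 = methylated, 1 = unmethylated).  Early stopping follows the
    accuracy-stability rule.
    """
    cfg = config or ClsTrainConfig()
    Xtr, ytr = _stack_xy(train_data)
    Xva, yva = _stack_xy(val_data)
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ValueError("empty training or validation set")
    if model is None:
        cls_config = cls_config or ClsConfig(input_height=Xtr.shape[1],
                                             input_width=Xtr.shape[2])
        model = build_classifier(cls_config, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    log = TrainLog(seed=cfg.seed)
    n = Xtr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for bi, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(Xtr[idx][:, None])
            z = model.logits(x)
            logp = log_softmax(z, axis=1)
            picked = Tensor(
                np.eye(model.config.n_classes, dtype=np.float32)[ytr[idx]])
            loss = -(logp * picked).sum() * (1.0 / len(idx))
            _check_finite(float(loss.data), epoch, bi)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        pva = model.predict_proba(Xva)
        acc = float((pva.argmax(axis=1) == yva).mean())
        val_loss = float(-np.log(
            np.clip(pva[np.arange(len(yva)), yva], 1e-12, None)).mean())
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val_loss)
        log.val_accuracy.append(acc)
        log.learning_rate.append(opt.lr)
        log.stop_epoch = epoch
        if early_stop(log.val_accuracy, cfg.early_stop_patience, cfg.min_delta):
            break
    return TrainingResult(model=model, log=log)


# ----------------------------------------------------------------------
# cross-validation

def run_cross_validation(split, train_fn, eval_fn) -> list[dict]:
    """k-fold cross-validation orchestration.

    For each fold: train on the other k-1 folds (``train_fn(train_ids,
    val_ids)`` -> model), then score with ``eval_fn(model, val_ids,
    test_ids)`` -> dict of metric values.  Returns one record per fold
    (with a ``fold`` key added); feed the per-metric columns to
    :func:`mgmtnet.evaluation.aggregate_folds` for mean ± std reporting.
    """
    if not split.folds:
        raise ValueError("split has no folds; call make_folds first")
    records = []
    for i, fold in enumerate(split.folds):
        val_ids = list(fold)
        train_ids = [cid for f in split.folds if f is not fold for cid in f]
        model = train_fn(train_ids, val_ids)
        rec = {"fold": i}
        rec.update(eval_fn(model, val_ids, list(split.test_ids)))
        records.append(rec)
    return records
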