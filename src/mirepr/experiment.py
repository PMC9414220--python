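"""Dataset splitting, supervised training and accuracy evaluation.

The protocol splits pooled samples 80/10/10 into train/validation/test by
a seeded permutation (validation and test take floor(N/10) each, the
remainder trains).  Training minimizes 3-class cross-entropy with a
validation-accuracy-driven learning-rate reduction and keeps the
best-validation checkpoint.  Accuracy is the fraction of correctly
classified test samples, reported with the full 3x3 confusion tally.

The pooled random split follows the source protocol even though it mixes
subjects across splits; a stricter ``unit='subject'`` split is available
and the choice is the caller's to record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import Model
from .recording import LABELS
from . import nn

__all__ = [
    "LABEL_TO_INDEX", "SplitConfig", "TrainConfig", "Metrics",
    "DivergenceError", "split_dataset", "train", "evaluate",
    "samples_to_arrays",
]

LABEL_TO_INDEX = {label: i for i, label in enumerate(LABELS)}


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class SplitConfig:
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    unit: str = "sample"            # 'sample' (pooled) or 'subject'

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.unit not in ("sample", "subject"):
            raise ValueError("unit must be 'sample' or 'subject'")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    lr_factor: float = 0.1          # multiplier on plateau
    lr_patience: int = 5            # epochs without val-accuracy improvement
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    optimizer: str = "adam"         # 'adam' or 'sgd'

    def __post_init__(self):
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")
        if min(self.learning_rate, self.lr_patience, self.epochs,
               self.batch_size) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class Metrics:
    confusion: np.ndarray           # [3 x 3], rows true, cols predicted

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def per_class_counts(self) -> Dict[str, int]:
        return {label: int(self.confusion[i].sum())
                for i, label in enumerate(LABELS)}

    @property
    def per_class_accuracy(self) -> Dict[str, float]:
        out = {}
        for i, label in enumerate(LABELS):
            total = self.confusion[i].sum()
            out[label] = float(self.confusion[i, i] / total) if total else float("nan")
        return out

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "per_class_counts": self.per_class_counts,
                "per_class_accuracy": self.per_class_accuracy,
                "confusion": self.confusion.tolist()}


def split_dataset(manifest_or_n, cfg: SplitConfig,
                  subjects: Optional[Sequence[str]] = None
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint (train, val, test) index arrays covering all N samples.

    Validation and test receive floor(N * fraction) samples each; the
    remainder goes to training.  The permutation is fully determined by
    the seed.  With ``unit='subject'`` whole subjects are assigned to one
    split (``subjects`` gives each sample's subject id).
    """
    n = manifest_or_n if isinstance(manifest_or_n, int) \
        else manifest_or_n.total
    if n <= 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    f_train, f_val, f_test = cfg.fractions
    if cfg.unit == "sample":
        perm = rng.permutation(n)
        n_val = int(n * f_val)
        n_test = int(n * f_test)
        n_train = n - n_val - n_test
        return (np.sort(perm[:n_train]),
                np.sort(perm[n_train:n_train + n_val]),
                np.sort(perm[n_train + n_val:]))
    if subjects is None:
        raise ValueError("unit='subject' requires per-sample subject ids")
    subjects = np.asarray(subjects)
    if len(subjects) != n:
        raise ValueError("subjects must have one entry per sample")
    uniq = sorted(set(subjects.tolist()))
    order = rng.permutation(len(uniq))
    n_val_s = int(len(uniq) * f_val)
    n_test_s = int(len(uniq) * f_test)
    val_s = {uniq[i] for i in order[:n_val_s]}
    test_s = {uniq[i] for i in order[n_val_s:n_val_s + n_test_s]}
    idx = np.arange(n)
    val = idx[np.isin(subjects, list(val_s))]
    test = idx[np.isin(subjects, list(test_s))]
    train_mask = ~(np.isin(subjects, list(val_s | test_s)))
    return idx[train_mask], val, test


def samples_to_arrays(samples: Sequence, input_shape: Tuple[int, ...]
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Stack representation samples into (X, y) model-ready arrays.

    ``input_shape`` is the model-side sample shape, e.g. ``(1, 640)`` for
    vectors or ``(1, 21, 640)`` for raw matrices (leading plane axis added
    as needed).
    """
    xs, ys = [], []
    for s in samples:
        a = getattr(s, "values", None)
        if a is None:   # spectrogram image: HxWx3 uint8 -> 3xHxW float
            a = np.transpose(s.pixels, (2, 0, 1)).astype(np.float32) / 255.0
        a = np.asarray(a, dtype=np.float32).reshape(input_shape)
        xs.append(a)
        ys.append(LABEL_TO_INDEX[s.label])
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def _check_finite(value: float, epoch: int) -> None:
    if not np.isfinite(value):
        raise DivergenceError(f"non-finite loss at epoch {epoch}")


def train(model: Model,
          train_set: Tuple[np.ndarray, np.ndarray],
          val_set: Tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig) -> Tuple[Model, List[dict]]:
    """Mini-batch training with plateau LR reduction.

    Returns the model restored to its best-validation-accuracy parameters
    and the per-epoch history (loss, validation accuracy, learning rate).
    All randomness (shuffling) flows from ``cfg.seed``; dropout draws from
    the model's own seeded generator.
    """
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if x_tr.shape[1:] != model.input_shape:
        raise ValueError(
            f"training samples {x_tr.shape[1:]} do not match model input "
            f"{model.input_shape}")
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    opt: nn._Optimizer
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(params, lr=cfg.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    history: List[dict] = []
    best_acc = -1.0
    best_state: Optional[List[np.ndarray]] = None
    since_improvement = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            logits = model.forward(x_tr[batch], training=True)
            loss, grad = nn.cross_entropy(logits, y_tr[batch])
            _check_finite(loss, epoch)
            epoch_loss += loss * len(batch)
            opt.zero_grad()
            model.backward(grad,
                           through_backbone=any(
                               p.trainable for p in
                               (model.backbone.params() if model.backbone
                                else [])))
            opt.step()
        epoch_loss /= len(x_tr)
        val_acc = float((model.predict(x_val) == y_val).mean())
        history.append({"epoch": epoch, "loss": epoch_loss,
                        "val_accuracy": val_acc, "lr": opt.lr})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = [a.copy() for a in model.state_arrays()]
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                since_improvement = 0
    if best_state is not None:
        for a, saved in zip(model.state_arrays(), best_state):
            a[...] = saved
    return model, history


def evaluate(model: Model, test_set: Tuple[np.ndarray, np.ndarray],
             batch_size: int = 256) -> Metrics:
    """Confusion tally and accuracy over a test set (order-invariant)."""
    x, y = test_set
    if len(x) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    pred = model.predict(x, batch_size=batch_size)
    confusion = np.zeros((3, 3), dtype=np.int64)
    np.add.at(confusion, (np.asarray(y), pred), 1)
    return Metrics(confusion)
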