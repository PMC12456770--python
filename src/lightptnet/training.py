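"""Training protocol and evaluation metrics.

Training follows a fixed-epoch protocol: Adam on categorical cross-entropy
with seeded per-epoch shuffling and plateau learning-rate reduction (the
rate is multiplied by ``plateau_factor`` once the validation loss has
stagnated for ``plateau_patience`` consecutive epochs, never dropping below
``min_lr``).  There is no early stopping and no checkpoint selection: the
final-epoch weights are what gets evaluated.

Evaluation reports accuracy, macro-averaged precision/recall/F1 (weighted
averaging available as an option) and the confusion matrix, computed with
scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .data import WindowedDataset
from .network import LightPTNet, softmax
from .specs import TrainConfig
from . import nn

__all__ = [
    "categorical_cross_entropy",
    "PlateauScheduler",
    "TrainHistory",
    "train",
    "EvalReport",
    "evaluate",
    "TrainingResults",
]

_EPS = 1e-7


def categorical_cross_entropy(y_true: np.ndarray, p_hat: np.ndarray) -> float:
    """Mean over samples of ``-sum_k y_k log(p_k)``; probabilities are
    clipped to ``[1e-7, 1]`` before the log."""
    y_true = np.asarray(y_true, dtype=np.float64)
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if y_true.shape != p_hat.shape:
        raise ValueError(
            f"shape mismatch: y_true {y_true.shape} vs p_hat {p_hat.shape}")
    p = np.clip(p_hat, _EPS, 1.0)
    return float(-(y_true * np.log(p)).sum(axis=1).mean())


class PlateauScheduler:
    """Reduce-learning-rate-on-plateau state machine.

    After ``patience`` consecutive epochs without a strict decrease of the
    monitored validation loss, the learning rate becomes
    ``max(lr * factor, min_lr)`` and the stagnation counter resets.
    """

    def __init__(self, initial_lr: float, factor: float = 0.1,
                 patience: int = 3, min_lr: float = 1e-4,
                 min_delta: float = 0.0):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.stagnant = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the lr for the next."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.stagnant = 0
        return self.lr


@dataclass
class TrainHistory:
    """Per-epoch training curves."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "learning_rate": self.learning_rate,
        })


def _dataset_loss_acc(model: LightPTNet, ds: WindowedDataset,
                      batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(ds.windows, batch_size=batch_size)
    loss = categorical_cross_entropy(ds.one_hot_labels(), probs)
    acc = float((probs.argmax(axis=1) == ds.labels).mean())
    return loss, acc


def train(model: LightPTNet, train_set: WindowedDataset,
          val_set: WindowedDataset, cfg: TrainConfig,
          verbose: bool = False) -> "TrainingResults":
    """Train for exactly ``cfg.epochs`` epochs; returns the results object
    (the model is updated in place)."""
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    model.rng = rng  # dropout masks follow the training seed
    for block in model.blocks:
        for level in block.levels:
            for head in level.heads:
                for layer in head.layers:
                    if isinstance(layer, nn.Dropout):
                        layer.rng = rng
    optim = nn.Adam(model.params())
    sched = PlateauScheduler(cfg.initial_lr, cfg.plateau_factor,
                             cfg.plateau_patience, cfg.min_lr)
    history = TrainHistory()
    eye = np.eye(model.spec.n_classes, dtype=np.float32)
    x_all = np.asarray(train_set.windows, dtype=np.float32)
    y_all = train_set.labels
    lr = sched.lr
    for epoch in range(1, cfg.epochs + 1):
        order = (rng.permutation(len(x_all)) if cfg.shuffle
                 else np.arange(len(x_all)))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb = x_all[idx]
            yb = eye[y_all[idx]]
            logits = model.forward(xb, training=True)
            probs = softmax(logits)
            losses.append(categorical_cross_entropy(yb, probs) * len(idx))
            hits += int((probs.argmax(axis=1) == y_all[idx]).sum())
            seen += len(idx)
            optim.zero_grad()
            model.backward((probs - yb).astype(np.float32) / len(idx))
            optim.step(lr)
        val_loss, val_acc = _dataset_loss_acc(model, val_set, cfg.batch_size)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.sum(losses) / seen))
        history.train_accuracy.append(hits / seen)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        lr = sched.step(val_loss)
        if verbose:
            print(f"epoch {epoch:3d}  loss {history.train_loss[-1]:.4f}  "
                  f"acc {history.train_accuracy[-1]:.4f}  "
                  f"val_loss {val_loss:.4f}  val_acc {val_acc:.4f}  "
                  f"lr {history.learning_rate[-1]:.2e}")
    return TrainingResults(model=model, history=history, config=cfg,
                           train_subjects=sorted(set(train_set.subjects)))


@dataclass
class EvalReport:
    """Held-out classification metrics.

    confusion rows are true classes, columns predictions; ``precision``,
    ``recall`` and ``f1`` are averaged over classes (macro by default).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    class_names: list[str]
    support: np.ndarray
    average: str = "macro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "average": self.average,
            "class_names": self.class_names,
            "support": self.support.tolist(),
            "confusion": self.confusion.tolist(),
        }

    def confusion_text(self) -> str:
        width = max(len(n) for n in self.class_names) + 1
        head = " " * width + " ".join(f"{n[:6]:>6}" for n in self.class_names)
        lines = [head]
        for name, row in zip(self.class_names, self.confusion):
            lines.append(f"{name:<{width}}"
                         + " ".join(f"{v:>6d}" for v in row))
        return "\n".join(lines)

    def plot_confusion(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion, cmap="Blues")
        ax.set_xticks(range(len(self.class_names)), self.class_names,
                      rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.class_names)), self.class_names,
                      fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate(model: LightPTNet, test_set: WindowedDataset,
             average: str = "macro",
             train_subjects: list[str] | None = None) -> EvalReport:
    """Confusion matrix + accuracy/precision/recall/F1 on a held-out set.

    Classes absent from the test set are excluded from the averaged
    metrics with a warning.  If ``train_subjects`` is given and overlaps
    the test subjects, a leakage warning is raised.
    """
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    if train_subjects is not None:
        overlap = set(train_subjects) & set(test_set.subjects.tolist())
        if overlap:
            warnings.warn(
                f"test subjects overlap training subjects: {sorted(overlap)}"
                " — this is not a subject-independent evaluation")
    K = test_set.n_classes
    _, pred = model.predict(test_set.windows)
    cm = _sk_confusion(test_set.labels, pred, labels=np.arange(K))
    support = cm.sum(axis=1)
    present = np.flatnonzero(support > 0)
    if len(present) < K:
        absent = [test_set.class_names[i]
                  for i in range(K) if support[i] == 0]
        warnings.warn(f"classes absent from test set excluded from "
                      f"averaged metrics: {absent}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division inside sklearn
        prec, rec, f1, _ = precision_recall_fscore_support(
            test_set.labels, pred, labels=present, average=average,
            zero_division=0)
    acc = float(np.trace(cm) / cm.sum())
    return EvalReport(accuracy=acc, precision=float(prec), recall=float(rec),
                      f1=float(f1), confusion=cm,
                      class_names=test_set.class_names, support=support,
                      average=average)


@dataclass
class TrainingResults:
    """What ``fit`` returns: the trained model, its history and helpers."""

    model: LightPTNet
    history: TrainHistory
    config: TrainConfig
    train_subjects: list[str]

    def evaluate(self, test_set: WindowedDataset,
                 average: str = "macro") -> EvalReport:
        return evaluate(self.model, test_set, average=average,
                        train_subjects=self.train_subjects)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Light-PTNet training results",
            "----------------------------",
            f"trainable parameters : {self.model.n_parameters:,}",
            f"epochs               : {len(h.epoch)}",
            f"batch size           : {self.config.batch_size}",
            f"final train loss/acc : {h.train_loss[-1]:.4f} / "
            f"{h.train_accuracy[-1]:.4f}",
            f"final val loss/acc   : {h.val_loss[-1]:.4f} / "
            f"{h.val_accuracy[-1]:.4f}",
            f"final learning rate  : {h.learning_rate[-1]:.2e}",
            f"training subjects    : {len(self.train_subjects)}",
        ]
        return "\n".join(lines)
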