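"""Class-weighted loss, k-fold cross-validation, adaptive learning rate, and
final retraining.

The class weight of class ``c`` is ``n_samples / (n_classes * count_c)``:
rare classes receive proportionally larger loss contributions, and the
weighted per-class contributions sum exactly to ``n_samples`` scaled by the
mean loss.  Cross-validation trains ``k`` fresh networks on stratified folds,
halving the learning rate whenever the monitored loss fails to improve for
five consecutive epochs, and selects the optimal epoch as the rounded mean of
the per-fold epochs of minimum validation loss.  The final model is then
re-initialized and trained on the full training set for exactly that many
epochs; test data is never touched during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataio import N_CLASSES, SegmentDataset
from .model import ModelSpec, NetworkHandle, build_network
from .nn import OPTIMIZERS

logger = logging.getLogger(__name__)

LOSS_EPS = 1e-7  # probability clipping inside the loss


# --------------------------------------------------------------------------
# class weights and weighted loss
# --------------------------------------------------------------------------

def class_weights(counts) -> np.ndarray:
    """Per-class loss weights ``n_samples / (n_classes * count_c)``.

    Balanced counts give all-ones; the weighted counts always sum back to
    ``n_samples``.  A zero count leaves the weight undefined and raises.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(counts < 1):
        raise ValueError(
            f"class weight undefined for zero-count class (counts={counts}); "
            "merge or drop the class first")
    return counts.sum() / (counts.size * counts)


def weighted_cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                           weights: np.ndarray | None = None) -> float:
    """Mean over samples of ``-w_y * log p(y)`` with probabilities clipped at
    ``LOSS_EPS``.  Unit weights reduce to plain categorical cross-entropy."""
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    p_true = np.clip((probs * onehot).sum(axis=1), LOSS_EPS, 1.0)
    nll = -np.log(p_true)
    if weights is not None:
        nll = nll * np.asarray(weights)[onehot.argmax(axis=1)]
    return float(nll.mean())


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(labels, dtype=int)]


# --------------------------------------------------------------------------
# fold assignment and the learning-rate schedule
# --------------------------------------------------------------------------

def kfold_split(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1) per sample, seeded shuffle.

    Folds partition the index set with sizes differing by at most one, and
    per-fold class proportions track the global proportions.  A class with
    fewer members than ``k`` is distributed best-effort (with a warning).
    """
    labels = np.asarray(labels)
    if labels.size < k:
        raise ValueError(f"need at least k={k} samples, got {labels.size}")
    counts = np.bincount(labels)
    rare = np.flatnonzero((counts > 0) & (counts < k))
    if rare.size:
        logger.warning("classes %s have fewer than k=%d members; "
                       "distributed best-effort", rare.tolist(), k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=np.int64)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[val_idx] = fold
    return assignment


@dataclass
class ReduceLROnPlateau:
    """Halve the learning rate after five consecutive non-improving epochs.

    An epoch improves when its monitored loss is strictly below the best seen
    so far.  The non-improvement counter resets on improvement and after each
    halving.
    """

    lr: float
    factor: float = 0.5
    patience: int = 5
    best: float = field(default=np.inf, init=False)
    wait: int = field(default=0, init=False)

    def update(self, epoch_loss: float) -> float:
        if epoch_loss < self.best:
            self.best = epoch_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


# --------------------------------------------------------------------------
# training loops
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    optimizer: str = "adam"
    initial_lr: float = 0.001
    lr_factor: float = 0.5
    lr_patience: int = 5
    k: int = 10
    use_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.lr_patience < 1:
            raise ValueError("lr_patience must be >= 1")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {sorted(OPTIMIZERS)}")


@dataclass
class EpochLog:
    loss: float
    accuracy: float
    lr: float
    val_loss: float | None = None
    val_accuracy: float | None = None


@dataclass
class FoldResult:
    history: list[EpochLog]
    best_epoch: int                      # 1-based argmin of validation loss
    val_indices: np.ndarray
    val_probs: np.ndarray                # predictions at the final epoch


@dataclass
class CvResult:
    folds: list[FoldResult]
    selected_epoch: int

    @property
    def k(self) -> int:
        return len(self.folds)


def _epoch_pass(handle: NetworkHandle, x, onehot, weights, optimizer,
                rng) -> tuple[float, float]:
    """One shuffled pass over the data; returns (mean loss, accuracy)."""
    n = x.shape[0]
    order = rng.permutation(n)
    bs = optimizer.batch_size
    total_nll = 0.0
    correct = 0
    for lo in range(0, n, bs):
        idx = order[lo:lo + bs]
        xb, yb = x[idx], onehot[idx]
        probs = handle.net.forward(xb, training=True)
        wy = (np.ones(len(idx)) if weights is None
              else weights[yb.argmax(axis=1)])
        p_true = np.clip((probs * yb).sum(axis=1), LOSS_EPS, 1.0)
        total_nll += float((wy * -np.log(p_true)).sum())
        correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
        handle.net.zero_grads()
        delta = (wy[:, None] * (probs - yb)) / len(idx)
        handle.net.backward(delta, last_grad_is_preactivation=True)
        optimizer.step()
    return total_nll / n, correct / n


def _evaluate(handle: NetworkHandle, x, onehot, weights) -> tuple[float, float, np.ndarray]:
    probs = handle.net.forward(x, training=False)
    loss = weighted_cross_entropy(probs, onehot, weights)
    acc = float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())
    return loss, acc, probs


class _BatchedOptimizer:
    """Couples an optimizer with the batch size and a mutable learning rate."""

    def __init__(self, name, net, lr, batch_size):
        self.opt = OPTIMIZERS[name](net, lr=lr)
        self.batch_size = batch_size

    @property
    def lr(self):
        return self.opt.lr

    @lr.setter
    def lr(self, value):
        self.opt.lr = value

    def step(self):
        self.opt.step()


def _as_x(ds: SegmentDataset) -> np.ndarray:
    return ds.segments[:, :, None]


def train_fold(ds: SegmentDataset, spec: ModelSpec, cfg: TrainConfig,
               train_idx, val_idx, seed: int) -> FoldResult:
    """Train one fresh network on ``train_idx`` and monitor ``val_idx``."""
    x, labels = _as_x(ds), ds.labels
    handle = build_network(spec, seed=seed)
    weights = None
    if cfg.use_weights:
        weights = class_weights(np.bincount(labels[train_idx],
                                            minlength=spec.n_classes))
    onehot = one_hot(labels, spec.n_classes)
    optimizer = _BatchedOptimizer(cfg.optimizer, handle.net, cfg.initial_lr,
                                  cfg.batch_size)
    schedule = ReduceLROnPlateau(cfg.initial_lr, cfg.lr_factor, cfg.lr_patience)
    rng = np.random.default_rng(seed)
    history: list[EpochLog] = []
    val_probs = None
    for _ in range(cfg.epochs):
        loss, acc = _epoch_pass(handle, x[train_idx], onehot[train_idx],
                                weights, optimizer, rng)
        val_loss, val_acc, val_probs = _evaluate(
            handle, x[val_idx], onehot[val_idx], weights)
        optimizer.lr = schedule.update(val_loss)
        history.append(EpochLog(loss, acc, optimizer.lr, val_loss, val_acc))
    # inference statistics: exact training-split moments, not the noisy
    # small-batch moving averages accumulated along the way
    handle.net.recalibrate_batchnorm(x[train_idx])
    _, _, val_probs = _evaluate(handle, x[val_idx], onehot[val_idx], weights)
    best = int(np.argmin([h.val_loss for h in history])) + 1
    return FoldResult(history=history, best_epoch=best,
                      val_indices=np.asarray(val_idx),
                      val_probs=val_probs)


def run_cross_validation(ds: SegmentDataset, spec: ModelSpec,
                         cfg: TrainConfig) -> CvResult:
    """k-fold cross-validation; class weights come from each fold's training
    split (never the validation part), avoiding leakage."""
    assignment = kfold_split(ds.labels, k=cfg.k, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    fold_seeds = rng.integers(0, 2**31, size=cfg.k)
    folds = []
    for fold in range(cfg.k):
        val_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        folds.append(train_fold(ds, spec, cfg, train_idx, val_idx,
                                seed=int(fold_seeds[fold])))
        logger.info("fold %d/%d: best epoch %d, final val loss %.4f",
                    fold + 1, cfg.k, folds[-1].best_epoch,
                    folds[-1].history[-1].val_loss)
    selected = int(round(float(np.mean([f.best_epoch for f in folds]))))
    return CvResult(folds=folds, selected_epoch=max(1, selected))


def train_final(ds: SegmentDataset, spec: ModelSpec, cfg: TrainConfig,
                optimal_epoch: int) -> NetworkHandle:
    """Re-initialize and train on the entire dataset for exactly
    ``optimal_epoch`` epochs; the plateau monitor watches the training loss
    (no validation set exists at this stage)."""
    if optimal_epoch < 1:
        raise ValueError("optimal_epoch must be >= 1")
    x, labels = _as_x(ds), ds.labels
    handle = build_network(spec, seed=cfg.seed)
    weights = None
    if cfg.use_weights:
        weights = class_weights(np.bincount(labels, minlength=spec.n_classes))
    onehot = one_hot(labels, spec.n_classes)
    optimizer = _BatchedOptimizer(cfg.optimizer, handle.net, cfg.initial_lr,
                                  cfg.batch_size)
    schedule = ReduceLROnPlateau(cfg.initial_lr, cfg.lr_factor, cfg.lr_patience)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(optimal_epoch):
        loss, _ = _epoch_pass(handle, x, onehot, weights, optimizer, rng)
        optimizer.lr = schedule.update(loss)
    handle.net.recalibrate_batchnorm(x)
    return handle


def history_to_rows(result: CvResult) -> list[dict]:
    """Flatten CV curves for CSV logging."""
    rows = []
    for fold, fr in enumerate(result.folds):
        for epoch, h in enumerate(fr.history, start=1):
            rows.append({"fold": fold, "epoch": epoch, "loss": h.loss,
                         "accuracy": h.accuracy, "lr": h.lr,
                         "val_loss": h.val_loss, "val_accuracy": h.val_accuracy})
    return rows
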