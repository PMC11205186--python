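"""Training recipe for the cell-state classifier.

Mirrors a fairly conventional small-CNN regime: Adam at an initial learning
rate of 0.01, mini-batches of 128, a hard cap of 20 epochs with the learning
rate dropping by a fixed factor every 10 epochs, L2 regularization at 0.005,
an 80/20 stratified train/validation split, per-epoch reshuffling, validation
every 50 mini-batches, and early stopping once the best validation loss has
not improved for 5 consecutive epochs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .labels import LABEL_ORDER, LABEL_TO_INDEX, CellStateLabel, as_label
from .model import INTENSITY_SCALE
from .nn import Adam, SequentialCNN, cross_entropy, softmax


@dataclass(frozen=True)
class TrainingConfig:
    initial_learning_rate: float = 0.01
    lr_drop_period: int = 10  # epochs
    lr_drop_factor: float = 0.1
    max_epochs: int = 20
    batch_size: int = 128
    l2_regularization: float = 0.005
    validation_frequency: int = 50  # mini-batches
    validation_patience: int = 5  # epochs
    train_fraction: float = 0.8
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def learning_rate_at(self, epoch: int) -> float:
        """Piecewise-constant schedule; epoch is 1-based."""
        drops = (epoch - 1) // self.lr_drop_period
        return self.initial_learning_rate * self.lr_drop_factor**drops

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TrainingHistory:
    """Per-iteration log of losses, validation metrics and learning rate."""

    records: pd.DataFrame

    COLUMNS = (
        "iteration",
        "epoch",
        "training_loss",
        "validation_loss",
        "validation_accuracy",
        "learning_rate",
    )

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingHistory":
        return cls(pd.read_csv(path))


def labels_to_indices(labels) -> np.ndarray:
    return np.array([LABEL_TO_INDEX[as_label(l)] for l in labels], dtype=np.int64)


def split_dataset(
    crops: np.ndarray,
    labels,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stratified, disjoint, exhaustive train/validation split.

    Returns ((train_crops, train_idx), (val_crops, val_idx)) with integer
    class indices. Per class, floor(n * train_fraction) (at least 1) goes to
    training and the rest to validation; deterministic given the seed.
    """
    if len(crops) == 0:
        raise ValueError("corpus is empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = labels_to_indices(labels)
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(
                f"class {LABEL_ORDER[cls].value!r} has fewer than 2 members; "
                "cannot form a stratified split"
            )
        idx = rng.permutation(idx)
        n_train = min(max(int(round(len(idx) * train_fraction)), 1), len(idx) - 1)
        train_parts.append(idx[:n_train])
        val_parts.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    val_idx = np.sort(np.concatenate(val_parts))
    return (crops[train_idx], y[train_idx]), (crops[val_idx], y[val_idx])


def _evaluate(
    net: SequentialCNN, x: np.ndarray, y: np.ndarray, batch_size: int
) -> tuple[float, float]:
    probs = net.predict_proba(x, batch_size=batch_size)
    loss = cross_entropy(probs, y)
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    net: SequentialCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig = TrainingConfig(),
    verbose: bool = False,
) -> tuple[SequentialCNN, TrainingHistory]:
    """Run the training loop; returns the trained network and full history.

    Early stopping monitors the epoch-end validation loss: once it has not
    improved for ``validation_patience`` consecutive epochs, training halts.
    Mid-epoch validation is also evaluated every ``validation_frequency``
    mini-batches (logged, not used for patience). A non-finite training loss
    aborts with a diagnostic naming the iteration.

    The returned network carries the weights of the best-validation epoch
    (not necessarily the last). At every epoch end the batch-norm inference
    statistics are recomputed as population statistics over the training set,
    so the monitored validation metric, the early-stopping decision, and
    final-model inference all share the same semantics.
    """
    x_train = np.asarray(train_set[0], dtype=np.float32) / np.float32(INTENSITY_SCALE)
    y_train = np.asarray(train_set[1], dtype=np.int64)
    x_val = np.asarray(val_set[0], dtype=np.float32) / np.float32(INTENSITY_SCALE)
    y_val = np.asarray(val_set[1], dtype=np.int64)
    if x_train.ndim == 3:
        x_train = x_train[..., None]
    if x_val.ndim == 3:
        x_val = x_val[..., None]

    rng = np.random.default_rng(config.seed)
    opt = Adam(net, lr=config.initial_learning_rate)
    rows = []
    iteration = 0
    best_val_loss = np.inf
    best_epoch = 0
    n = len(x_train)

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.learning_rate_at(epoch)
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            iteration += 1
            logits = net.forward_logits(xb, train=True)
            probs = softmax(logits)
            data_loss = cross_entropy(probs, yb)
            if not np.isfinite(data_loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at iteration {iteration}"
                )
            net.backward_from_probs(probs, yb)
            penalty = net.l2_penalty_and_grad(config.l2_regularization)
            opt.step()
            val_loss = val_acc = np.nan
            if iteration % config.validation_frequency == 0:
                val_loss, val_acc = _evaluate(net, x_val, y_val, config.batch_size)
            rows.append(
                (iteration, epoch, data_loss + penalty, val_loss, val_acc, opt.lr)
            )
        # epoch-end validation uses population batch-norm statistics so the
        # monitored metric matches final-model inference exactly; mid-epoch
        # validations (above) use the cheaper running statistics
        net.finalize_batchnorm(x_train, config.batch_size)
        val_loss, val_acc = _evaluate(net, x_val, y_val, config.batch_size)
        rows.append((iteration, epoch, np.nan, val_loss, val_acc, opt.lr))
        if verbose:
            print(
                f"epoch {epoch:3d}  val_loss={val_loss:.4f}  val_acc={val_acc:.4f}"
                f"  lr={opt.lr:g}"
            )
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
        elif epoch - best_epoch >= config.validation_patience:
            break

    if best_epoch > 0:
        # the snapshot already carries that epoch's population statistics
        net.load_state_arrays(best_state)
    history = TrainingHistory(
        pd.DataFrame(rows, columns=list(TrainingHistory.COLUMNS))
    )
    net.release_buffers()
    return net, history


def loss(
    logits: np.ndarray,
    label: int | CellStateLabel,
    l2: float = 0.005,
    parameters: list[np.ndarray] | None = None,
) -> float:
    """Softmax cross-entropy of one logit vector plus l2 * sum of squared
    weights over ``parameters``."""
    logits = np.asarray(logits, dtype=np.float64).reshape(1, -1)
    if logits.shape[1] != len(LABEL_ORDER):
        raise ValueError(f"expected {len(LABEL_ORDER)} logits, got {logits.shape[1]}")
    idx = label if isinstance(label, (int, np.integer)) else LABEL_TO_INDEX[as_label(label)]
    data = cross_entropy(softmax(logits), np.array([idx]))
    penalty = 0.0
    if parameters:
        penalty = l2 * float(sum((np.asarray(p, dtype=np.float64) ** 2).sum() for p in parameters))
    return data + penalty
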