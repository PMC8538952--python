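"""Dataset splitting, the training recipe, checkpointing, prediction.

Training follows the source recipe: Adam, learning rate 1e-4, batch size
4, per-pixel categorical cross-entropy, a fixed number of epochs; after
every epoch training/validation loss and overall pixel accuracy are
recorded and the weights with the best validation accuracy so far are
retained, so reported test metrics always come from the best checkpoint
rather than the last epoch.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .metrics import ConfusionMatrix, confusion, evaluate
from .network import SegmentationUNet
from .raster_io import LabelMask, TilePair
from .nn import Adam, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainHistory",
    "split_dataset",
    "to_arrays",
    "train",
    "predict",
    "evaluate_model",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 200
    seed: int = 0
    betas: tuple = (0.9, 0.999)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return self.records[self.best_epoch - 1].val_accuracy if self.best_epoch > 0 else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy", "is_best"])
            for r in self.records:
                w.writerow(
                    [r.epoch, f"{r.train_loss:.6f}", f"{r.train_accuracy:.6f}",
                     f"{r.val_loss:.6f}", f"{r.val_accuracy:.6f}", int(r.epoch == self.best_epoch)]
                )


def split_dataset(pairs, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Seeded shuffle then floor-allocated partition; remainder goes to train."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot split an empty collection")
    if len(ratios) != 3 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be three nonnegative numbers summing to 1")
    n = len(pairs)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = order[:n_train]
    val_idx = order[n_train : n_train + n_val]
    test_idx = order[n_train + n_val :]
    pick = lambda idx: [pairs[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Stack tile pairs into (N,C,H,W) float32 inputs and (N,H,W) labels."""
    xs, ys = [], []
    for p in pairs:
        img = p.image if isinstance(p, TilePair) else p
        xs.append(np.moveaxis(img.image.pixels if hasattr(img, "fusion_kind") else img.pixels, -1, 0))
        ys.append(p.mask.labels)
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.int64)


def _epoch_eval(model: SegmentationUNet, x: np.ndarray, y: np.ndarray, batch: int):
    """Loss and pixel accuracy in inference mode (running BN statistics)."""
    total_loss, correct, seen = 0.0, 0, 0
    for s in range(0, len(x), batch):
        xb, yb = x[s : s + batch], y[s : s + batch]
        logits = model.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        total_loss += loss * yb.size
        correct += int((logits.argmax(axis=1) == yb).sum())
        seen += yb.size
    return total_loss / seen, correct / seen


def train(model: SegmentationUNet, train_set, val_set, config: TrainConfig):
    """Train and return (model restored to best checkpoint, history)."""
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be nonempty")
    x_tr, y_tr = to_arrays(train_set)
    x_va, y_va = to_arrays(val_set)
    for arr in (x_tr, x_va):
        if arr.shape[1] != model.spec.in_channels:
            raise ValueError(
                f"tiles have {arr.shape[1]} channels, model expects {model.spec.in_channels}"
            )
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate, betas=config.betas)
    history = TrainHistory()
    best_state, best_acc = None, -1.0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss, correct, seen = 0.0, 0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * yb.size
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += yb.size
        val_loss, val_acc = _epoch_eval(model, x_va, y_va, config.batch_size)
        history.records.append(
            EpochRecord(epoch, ep_loss / seen, correct / seen, val_loss, val_acc)
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.copy_state()
            history.best_epoch = epoch
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def predict(model: SegmentationUNet, tiles) -> list[LabelMask]:
    """Per-pixel argmax segmentation (ties break toward the lowest class)."""
    single = not isinstance(tiles, (list, tuple))
    items = [tiles] if single else list(tiles)
    xs = []
    for t in items:
        pixels = t.image.pixels if hasattr(t, "fusion_kind") else t.pixels
        xs.append(np.moveaxis(pixels, -1, 0))
    x = np.stack(xs).astype(np.float32)
    if x.shape[1] != model.spec.in_channels:
        raise ValueError(f"tiles have {x.shape[1]} channels, model expects {model.spec.in_channels}")
    out = []
    for s in range(0, len(x), 4):
        logits = model.forward(x[s : s + 4], train=False)
        for lab in logits.argmax(axis=1):
            out.append(LabelMask(lab.astype(np.int64)))
    return out[0] if single else out


def evaluate_model(model: SegmentationUNet, test_set):
    """Accumulate one confusion matrix over the test set and report metrics."""
    cm = ConfusionMatrix()
    images = [p.image for p in test_set]
    preds = predict(model, images)
    for pred, pair in zip(preds, test_set):
        cm = cm + confusion(pred, pair.mask)
    return evaluate(cm), cm
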