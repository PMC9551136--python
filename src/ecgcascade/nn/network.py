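"""Architecture builder, Adam optimizer and the training protocol.

The network is a 19-layer 1-D CNN: four conv/pool/dropout blocks
(two same-padded convolutions each, filter ladder 16-16-32-32-32-32-256-256,
the last block closed by a global max pool), then Dense(64)-Dense(64)-Dense(4)
with ReLU, feeding a softmax head of 2 (Normal/Abnormal) or 3
(PVC/LBBB/RBBB) neurons. Training uses Adam (lr 0.001), batch size 32, at
most 50 epochs, early stopping after 10 epochs without a validation-accuracy
improvement, and checkpointing of the best-validation-accuracy weights.

``width_multiplier`` scales the conv filter counts and the two Dense(64)
layers so that desk-scale experiments train in minutes on one CPU; the
architecture audit is defined at multiplier 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import LeakageError, ParameterError, ShapeError
from .layers import Conv1D, Dense, Dropout, GlobalMaxPool1D, Layer, MaxPool1D
from .losses import EPSILON, softmax

INPUT_LENGTH = 2160
CONV_FILTERS = (16, 16, 32, 32, 32, 32, 256, 256)


@dataclass
class TrainingConfig:
    """Optimization protocol: Adam, lr 0.001, batch 32, <=50 epochs,
    patience 10 on validation accuracy, best-epoch checkpointing."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.patience > self.max_epochs:
            raise ParameterError("patience cannot exceed max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("batch size and max_epochs must be positive")


class CnnModel:
    """An ordered stack of layers ending in a K-neuron softmax head."""

    def __init__(self, layers: list[Layer], k_classes: int, input_length: int,
                 width_multiplier: float):
        self.layers = layers
        self.k_classes = k_classes
        self.input_length = input_length
        self.width_multiplier = width_multiplier
        self.is_trained = False

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probability rows (summing to 1) for a (n, L, 1) input batch."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[..., None]
        if len(x) == 0:
            return np.zeros((0, self.k_classes))
        if x.shape[1] != self.input_length:
            raise ShapeError(
                f"expected input length {self.input_length}, got {x.shape[1]}"
            )
        out = [softmax(self.forward_logits(x[i : i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ShapeError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            p[...] = w

    def describe(self) -> list[dict]:
        """Per-layer hyperparameters, for the architecture audit."""
        return [layer.describe() for layer in self.layers]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "k_classes": self.k_classes,
            "input_length": self.input_length,
            "width_multiplier": self.width_multiplier,
            "is_trained": self.is_trained,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> "CnnModel":
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    model = build_model(meta["k_classes"], width_multiplier=meta["width_multiplier"],
                        input_length=meta["input_length"])
    model.set_weights(weights)
    model.is_trained = meta["is_trained"]
    return model


def _scaled(n: int, multiplier: float, floor: int = 1) -> int:
    return max(floor, int(round(n * multiplier)))


def build_model(
    k_classes: int,
    width_multiplier: float = 1.0,
    seed: int = 0,
    input_length: int = INPUT_LENGTH,
) -> CnnModel:
    """Build the (optionally width-scaled) 19-layer CNN plus softmax head.

    ``k_classes`` is 2 for the Normal/Abnormal stage, 3 for the arrhythmia
    stage. Weights are Glorot-uniform initialized under ``seed``.
    """
    if k_classes not in (2, 3):
        raise ParameterError(f"softmax head must have 2 or 3 neurons, got {k_classes}")
    if not 0 < width_multiplier <= 1:
        raise ParameterError("width_multiplier must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    f = [_scaled(n, width_multiplier) for n in CONV_FILTERS]
    d = _scaled(64, width_multiplier, floor=4)
    layers: list[Layer] = [
        Conv1D(1, f[0], 5, rng),
        Conv1D(f[0], f[1], 5, rng),
        MaxPool1D(2, 1),
        Dropout(0.10),
        Conv1D(f[1], f[2], 3, rng),
        Conv1D(f[2], f[3], 3, rng),
        MaxPool1D(2, 2),
        Dropout(0.10),
        Conv1D(f[3], f[4], 3, rng),
        Conv1D(f[4], f[5], 3, rng),
        MaxPool1D(2, 1),
        Dropout(0.10),
        Conv1D(f[5], f[6], 3, rng),
        Conv1D(f[6], f[7], 3, rng),
        GlobalMaxPool1D(),
        Dropout(0.20),
        Dense(f[7], d, rng),
        Dense(d, d, rng),
        Dense(d, 4, rng),
        Dense(4, k_classes, rng, activation=None),  # softmax head
    ]
    return CnnModel(layers, k_classes, input_length, width_multiplier)


class Adam(object):
    """Adam optimizer with bias correction; updates parameters in place."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def early_stopping_schedule(
    val_metrics: list[float], patience: int
) -> tuple[int, int]:
    """Apply the stopping rule to a 1-indexed metric trace.

    Returns ``(stop_epoch, best_epoch)``: training halts after the first
    epoch at which the metric has not strictly improved for ``patience``
    consecutive epochs; otherwise it runs the full trace.
    """
    best, best_epoch = -np.inf, 0
    for epoch, metric in enumerate(val_metrics, start=1):
        if metric > best:
            best, best_epoch = metric, epoch
        if epoch - best_epoch >= patience:
            return epoch, best_epoch
    return len(val_metrics), best_epoch


@dataclass
class ArrayDataset:
    """Stacked segments: inputs (n, L, 1), integer labels, subject ids."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    @classmethod
    def from_segments(cls, segments, label_map=None) -> "ArrayDataset":
        from ..core import segments_to_arrays

        X, y, subjects = segments_to_arrays(list(segments))
        if label_map is not None:
            y = np.array([label_map[v] for v in y], dtype=int)
        return cls(X, y, subjects)

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class TrainedModel:
    """A trained network plus its training history and stopping epochs."""

    model: CnnModel
    history: list[dict] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)

    @property
    def k_classes(self) -> int:
        return self.model.k_classes

    @property
    def is_trained(self) -> bool:
        return self.model.is_trained


def train(
    model: CnnModel,
    train_data: ArrayDataset,
    val_data: ArrayDataset,
    config: TrainingConfig | None = None,
    abort_epoch: int | None = None,
    abort_below: float = 0.0,
) -> TrainedModel:
    """Train with Adam under the early-stopping/checkpoint protocol.

    Refuses to run if any subject appears in both the training and the
    validation data — subject exclusivity is enforced at the API level.

    ``abort_epoch``/``abort_below`` optionally stop a run early when its
    best validation accuracy is still below ``abort_below`` after
    ``abort_epoch`` epochs — a cheap stuck-at-chance detector used by the
    multi-restart protocol. Disabled by default.
    """
    config = config or TrainingConfig()
    overlap = set(train_data.subjects) & set(val_data.subjects)
    if overlap:
        raise LeakageError(f"subjects in both train and val: {sorted(overlap)}")
    if len(train_data) == 0 or len(val_data) == 0:
        raise ParameterError("train and val sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), learning_rate=config.learning_rate)
    k = model.k_classes
    Xtr = np.asarray(train_data.X, dtype=np.float32)
    ytr = np.asarray(train_data.y, dtype=int)

    history: list[dict] = []
    best_acc, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    stop_epoch = config.max_epochs
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(ytr))
        loss_sum, correct = 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = model.forward_logits(xb, training=True, rng=rng)
            probs = softmax(logits)
            p_true = np.clip(probs[np.arange(len(yb)), yb], EPSILON, 1.0)
            loss_sum += float(-np.log(p_true).sum())
            correct += int((probs.argmax(axis=1) == yb).sum())
            delta = probs.astype(np.float32)
            delta[np.arange(len(yb)), yb] -= 1.0
            model.backward(delta / len(yb))
            opt.step(model.gradients())

        val_probs = model.predict(val_data.X)
        p_val = np.clip(val_probs[np.arange(len(val_data.y)), val_data.y], EPSILON, 1.0)
        val_acc = float((val_probs.argmax(axis=1) == val_data.y).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": loss_sum / len(ytr),
                "train_acc": correct / len(ytr),
                "val_loss": float(-np.log(p_val).mean()),
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = model.get_weights()
        if epoch - best_epoch >= config.patience:
            stop_epoch = epoch
            break
        if abort_epoch is not None and epoch >= abort_epoch and best_acc < abort_below:
            stop_epoch = epoch
            break

    model.set_weights(best_weights)
    model.is_trained = True
    return TrainedModel(model=model, history=history, stop_epoch=stop_epoch,
                        best_epoch=best_epoch)
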