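"""Classification losses and the softmax, with a fixed 1e-7 probability clip."""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError, ShapeError

EPSILON = 1e-7


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def binary_cross_entropy(targets: np.ndarray, predictions: np.ndarray) -> float:
    """Mean binary cross-entropy on the positive-class probability.

    ``targets`` are one-hot pairs, ``predictions`` probability pairs whose
    rows sum to 1; class index 1 is treated as the positive class, so the
    per-sample loss is ``-[y log a + (1 - y) log(1 - a)]`` with ``y`` and
    ``a`` the positive-class target and probability.
    """
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if targets.shape != predictions.shape or targets.ndim != 2 or targets.shape[1] != 2:
        raise ShapeError(
            f"expected matching (n, 2) arrays, got {targets.shape} vs {predictions.shape}"
        )
    a = np.clip(predictions[:, 1], EPSILON, 1.0 - EPSILON)
    y = targets[:, 1]
    return float(np.mean(-(y * np.log(a) + (1.0 - y) * np.log(1.0 - a))))


def sparse_categorical_cross_entropy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean negative log-probability of the true class (integer labels)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    if predictions.ndim != 2 or len(labels) != len(predictions):
        raise ShapeError(
            f"expected (n,) labels with (n, K) predictions, got "
            f"{labels.shape} vs {predictions.shape}"
        )
    k = predictions.shape[1]
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ParameterError(f"labels must lie in [0, {k})")
    p = np.clip(predictions[np.arange(len(labels)), labels], EPSILON, 1.0)
    return float(np.mean(-np.log(p)))
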