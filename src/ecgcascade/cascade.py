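"""Two-stage cascade inference and its evaluation metrics.

The binary stage labels each segment Normal or Abnormal; only the
Abnormal-predicted segments reach the multiclass stage, whose three
outputs map to PVC/LBBB/RBBB. Metrics are the one-vs-rest precision,
recall, accuracy and F1 derived from confusion-matrix counts
(Tp, Fp, Tn, Fn); aggregate values are macro averages, with overall
accuracy taken as trace/total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, LeakageError, ParameterError, ShapeError

BINARY_CLASS_NAMES = ("Normal", "Abnormal")
FOUR_CLASS_NAMES = ("N", "PVC", "LBBB", "RBBB")
MULTICLASS_NAMES = ("PVC", "LBBB", "RBBB")


@dataclass
class ConfusionMatrix:
    """K x K counts, entry (i, j) = segments of true class i predicted j."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ShapeError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ParameterError("confusion counts must be non-negative")
        if not self.class_names:
            self.class_names = tuple(str(i) for i in range(self.counts.shape[0]))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized_pct(self) -> np.ndarray:
        """Row-percentage form (per-true-class prediction shares)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / rows
        return np.where(rows > 0, pct, 0.0)

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(Tp, Fp, Tn, Fn) counts for class ``cls`` against the rest."""
        tp = int(self.counts[cls, cls])
        fp = int(self.counts[:, cls].sum() - tp)
        fn = int(self.counts[cls, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion(
    true_labels, predicted_labels, k: int, class_names: tuple[str, ...] = ()
) -> ConfusionMatrix:
    """Count the K x K confusion matrix of two equal-length label sequences."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ShapeError(f"label sequences must match: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k):
        raise ParameterError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


@dataclass
class KpiReport:
    """Per-class and aggregate precision/recall/accuracy/F1."""

    per_class: dict[str, dict[str, float]]
    precision: float
    recall: float
    accuracy: float
    f1: float
    averaging: str = "macro"

    def to_json(self) -> str:
        return json.dumps(
            {
                "averaging": self.averaging,
                "precision": self.precision,
                "recall": self.recall,
                "accuracy": self.accuracy,
                "f1": self.f1,
                "per_class": self.per_class,
            },
            indent=2,
        )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    return 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0


def kpis(cm: ConfusionMatrix, averaging: str = "macro") -> KpiReport:
    """One-vs-rest metrics per class; aggregates are macro averages,
    except accuracy which is trace/total."""
    if averaging != "macro":
        raise ParameterError(f"unsupported averaging mode {averaging!r}")
    if cm.total == 0:
        raise DegenerateInputError("cannot compute KPIs of an empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for c in range(cm.k):
        tp, fp, tn, fn = cm.one_vs_rest(c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        accuracy = (tp + tn) / cm.total
        per_class[cm.class_names[c]] = {
            "precision": precision,
            "recall": recall,
            "accuracy": accuracy,
            "f1": f1_score(precision, recall),
        }
    vals = list(per_class.values())
    return KpiReport(
        per_class=per_class,
        precision=float(np.mean([v["precision"] for v in vals])),
        recall=float(np.mean([v["recall"] for v in vals])),
        accuracy=float(np.trace(cm.counts)) / cm.total,
        f1=float(np.mean([v["f1"] for v in vals])),
        averaging=averaging,
    )


def _check_trained(model) -> None:
    if not getattr(model, "is_trained", True):
        raise RuntimeError("model must be trained before cascade inference")


def cascade_predict(binary_model, multiclass_model, x: np.ndarray) -> np.ndarray:
    """Final 4-class labels: binary argmax routes Abnormal segments to the
    multiclass stage; argmax ties break toward the lowest class index."""
    _check_trained(binary_model)
    _check_trained(multiclass_model)
    x = np.asarray(x)
    labels = np.zeros(len(x), dtype=int)
    if len(x) == 0:
        return labels
    binary_probs = binary_model.predict(x)
    abnormal = binary_probs.argmax(axis=1) == 1
    if abnormal.any():
        multi_probs = multiclass_model.predict(x[abnormal])
        labels[abnormal] = multi_probs.argmax(axis=1) + 1
    return labels


@dataclass
class CascadeReport:
    """Stage-wise and end-to-end confusion matrices with their KPIs."""

    binary_cm: ConfusionMatrix
    binary_kpis: KpiReport
    multiclass_cm: ConfusionMatrix
    multiclass_kpis: KpiReport | None
    end_to_end_cm: ConfusionMatrix
    end_to_end_kpis: KpiReport
    false_forwards: int = 0
    extras: dict = field(default_factory=dict)


def evaluate_cascade(
    binary_model,
    multiclass_model,
    x: np.ndarray,
    y_true: np.ndarray,
    subjects: np.ndarray | None = None,
    assignment=None,
) -> CascadeReport:
    """Evaluate both stages and the end-to-end cascade on a test set.

    The binary report collapses true labels to Normal/Abnormal. The
    multiclass report covers only the segments the binary stage forwarded
    whose true class is arrhythmic; true-Normal segments wrongly forwarded
    have no true arrhythmia class, so they are excluded there, counted as
    ``false_forwards``, and still charged to the end-to-end report.
    When a split ``assignment`` is given, test subjects must be disjoint
    from train/val subjects.
    """
    y_true = np.asarray(y_true, dtype=int)
    if assignment is not None and subjects is not None:
        trainval = assignment.subjects("train") | assignment.subjects("val")
        overlap = set(subjects) & trainval
        if overlap:
            raise LeakageError(f"test subjects seen in train/val: {sorted(overlap)}")

    _check_trained(binary_model)
    _check_trained(multiclass_model)
    binary_probs = binary_model.predict(x)
    binary_pred = (binary_probs.argmax(axis=1) == 1).astype(int)
    binary_true = (y_true != 0).astype(int)
    binary_cm = confusion(binary_true, binary_pred, 2, BINARY_CLASS_NAMES)

    forwarded = binary_pred == 1
    final = np.zeros(len(y_true), dtype=int)
    multi_cm = ConfusionMatrix(np.zeros((3, 3), dtype=int), MULTICLASS_NAMES)
    false_forwards = 0
    if forwarded.any():
        multi_pred = multiclass_model.predict(np.asarray(x)[forwarded]).argmax(axis=1)
        final[forwarded] = multi_pred + 1
        fwd_true = y_true[forwarded]
        arr = fwd_true != 0
        false_forwards = int((~arr).sum())
        multi_cm = confusion(fwd_true[arr] - 1, multi_pred[arr], 3, MULTICLASS_NAMES)
    multi_kpis = kpis(multi_cm) if multi_cm.total > 0 else None

    end_cm = confusion(y_true, final, 4, FOUR_CLASS_NAMES)
    return CascadeReport(
        binary_cm=binary_cm,
        binary_kpis=kpis(binary_cm),
        multiclass_cm=multi_cm,
        multiclass_kpis=multi_kpis,
        end_to_end_cm=end_cm,
        end_to_end_kpis=kpis(end_cm),
        false_forwards=false_forwards,
    )
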