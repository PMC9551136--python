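"""End-to-end experiment runner on a synthetic cohort.

Chains every stage — cohort generation, preprocessing, rule-based
subject-exclusive splitting, training of the binary and multiclass CNNs,
and cascade evaluation — under a single seed, and returns the stage
reports plus bookkeeping counts. This is the entry point both the CLI
``run`` command and the reproduction script use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import CascadeReport, evaluate_cascade
from .core import Segment
from .nn import ArrayDataset, TrainedModel, TrainingConfig, build_model, train  # noqa: F401
from .preprocess import PreprocessConfig, preprocess_record
from .split import SplitAssignment, SplitConfig, assign_subjects, downsample_normals, \
    materialize_splits
from .synth import CohortConfig, generate_cohort


def binary_dataset(segments: list[Segment]) -> ArrayDataset:
    """Collapse 4-class labels to 0=Normal / 1=Abnormal."""
    ds = ArrayDataset.from_segments(segments)
    return ArrayDataset(ds.X, (ds.y != 0).astype(int), ds.subjects)


def multiclass_dataset(segments: list[Segment]) -> ArrayDataset:
    """Keep only arrhythmic segments, relabeled 0=PVC, 1=LBBB, 2=RBBB."""
    arr = [s for s in segments if s.label != 0]
    ds = ArrayDataset.from_segments(arr)
    return ArrayDataset(ds.X, ds.y - 1, ds.subjects)


def train_with_restarts(
    k_classes: int,
    train_ds: ArrayDataset,
    val_ds: ArrayDataset,
    tc: TrainingConfig,
    width_multiplier: float,
    seed: int,
    min_val_acc: float | None = None,
    max_attempts: int = 3,
) -> TrainedModel:
    """Train, re-initializing on failure to converge.

    Narrow (width-scaled) networks occasionally fail to escape the
    chance-level saddle within the epoch budget; a run whose best
    validation accuracy stays below ``min_val_acc`` is restarted from a
    fresh initialization (a standard multi-restart protocol, driven purely
    by validation accuracy). Runs still at chance level after four epochs
    are aborted rather than run out. The attempt with the best validation
    accuracy is returned.

    The default bar is stage-specific — 0.9 for the binary stage, 0.8 for
    the multiclass stage — reflecting their different chance levels.
    """
    if min_val_acc is None:
        min_val_acc = 0.9 if k_classes == 2 else 0.8
    best: TrainedModel | None = None
    best_val = -np.inf
    abort_below = 0.45 if k_classes == 3 else 0.75
    for attempt in range(max_attempts):
        attempt_seed = (seed + 101 * attempt) % (2**31)
        model = build_model(k_classes, width_multiplier=width_multiplier,
                            seed=attempt_seed)
        attempt_tc = TrainingConfig(
            learning_rate=tc.learning_rate, batch_size=tc.batch_size,
            max_epochs=tc.max_epochs, patience=tc.patience, seed=attempt_seed,
        )
        trained = train(model, train_ds, val_ds, attempt_tc,
                        abort_epoch=4, abort_below=abort_below)
        val_acc = max(h["val_acc"] for h in trained.history)
        if val_acc > best_val:
            best, best_val = trained, val_acc
        if best_val >= min_val_acc:
            break
    return best


@dataclass
class ExperimentResult:
    report: CascadeReport
    assignment: SplitAssignment
    binary_model: TrainedModel
    multiclass_model: TrainedModel
    n_segments: int
    n_test: int


def run_experiment(
    seed: int = 0,
    cohort: CohortConfig | None = None,
    preprocess: PreprocessConfig | None = None,
    split: SplitConfig | None = None,
    width_multiplier: float = 0.25,
    max_epochs: int = 10,
    learning_rate: float = 1e-3,
) -> ExperimentResult:
    """Run the full cascade experiment on a synthetic cohort.

    Desk-scale defaults (20 subjects, 60 s records, width multiplier 0.25,
    at most 10 epochs) train both stages in a few minutes on one CPU.
    """
    cohort = cohort or CohortConfig(seed=seed)
    preprocess = preprocess or PreprocessConfig()
    split = split or SplitConfig(seed=seed)

    segments: list[Segment] = []
    for record, annotations in generate_cohort(cohort):
        segments.extend(preprocess_record(record, annotations, preprocess))
    segments = downsample_normals(segments, split.normal_remove_total, seed=split.seed)

    assignment = assign_subjects(segments, split)
    train_segs, val_segs, test_segs = materialize_splits(segments, assignment,
                                                         seed=split.seed)

    tc = TrainingConfig(
        learning_rate=learning_rate,
        max_epochs=max_epochs,
        patience=min(10, max_epochs),
        seed=seed,
    )
    binary = train_with_restarts(
        2, binary_dataset(train_segs), binary_dataset(val_segs), tc,
        width_multiplier, seed,
    )
    multiclass = train_with_restarts(
        3, multiclass_dataset(train_segs), multiclass_dataset(val_segs), tc,
        width_multiplier, seed + 1,
    )

    test_ds = ArrayDataset.from_segments(test_segs)
    report = evaluate_cascade(
        binary, multiclass, test_ds.X, test_ds.y,
        subjects=test_ds.subjects, assignment=assignment,
    )
    return ExperimentResult(
        report=report,
        assignment=assignment,
        binary_model=binary,
        multiclass_model=multiclass,
        n_segments=len(segments),
        n_test=len(test_segs),
    )


def summarize(result: ExperimentResult) -> dict:
    """Flat numeric summary of an experiment (percentages on 0-100 scale)."""
    rep = result.report
    out = {
        "n_segments": result.n_segments,
        "n_test_segments": result.n_test,
        "binary_accuracy_pct": 100 * rep.binary_kpis.accuracy,
        "end_to_end_accuracy_pct": 100 * rep.end_to_end_kpis.accuracy,
        "end_to_end_macro_f1_pct": 100 * rep.end_to_end_kpis.f1,
        "end_to_end_macro_precision_pct": 100 * rep.end_to_end_kpis.precision,
        "end_to_end_macro_recall_pct": 100 * rep.end_to_end_kpis.recall,
        "false_forwards": rep.false_forwards,
        "split_balance_score": result.assignment.balance_score,
        "binary_best_epoch": result.binary_model.best_epoch,
        "multiclass_best_epoch": result.multiclass_model.best_epoch,
    }
    if rep.multiclass_kpis is not None:
        out["multiclass_accuracy_pct"] = 100 * rep.multiclass_kpis.accuracy
    return {k: (round(v, 3) if isinstance(v, float) else v) for k, v in out.items()}
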