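"""Full-scale experiment on a local copy of the MIT-BIH Arrhythmia Database.

Not part of the test suite: it needs the clinical database (obtain the
WFDB files, e.g. from PhysioNet accession ``mitdb``, records 100-234) and
several hours of single-core compute at full network width.

Expected layout: a directory of ``<record>.hea`` / ``<record>.dat`` /
``<record>.atr`` files (format-16 or pre-converted; format-212 originals
must be converted to format 16 first, e.g. with `wfdb`'s ``xform``).

Usage:
    python scripts/full_scale_mitbih.py --data /path/to/mitdb --out results/mitbih
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from ecgcascade import io as ecg_io
from ecgcascade.cascade import evaluate_cascade
from ecgcascade.nn import ArrayDataset, TrainingConfig, build_model, train
from ecgcascade.pipeline import binary_dataset, multiclass_dataset
from ecgcascade.preprocess import PreprocessConfig, preprocess_record
from ecgcascade.split import SplitConfig, assign_subjects, downsample_normals, \
    materialize_splits


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True,
                        help="directory with WFDB .hea/.dat/.atr files")
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--remove-normals", type=int, default=17000,
                        help="Normal segments to drop before splitting")
    parser.add_argument("--theta", type=float, default=0.01,
                        help="arrhythmic-fraction bar for train/val eligibility")
    parser.add_argument("--epochs", type=int, default=50)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    segments = []
    config = PreprocessConfig()
    for hea in sorted(args.data.glob("*.hea")):
        record = ecg_io.read_record(hea)
        annotations = ecg_io.read_annotations(hea.with_suffix(".atr"))
        segments.extend(preprocess_record(record, annotations, config))
    print(f"{len(segments)} segments from {args.data}")

    split_cfg = SplitConfig(normal_remove_total=args.remove_normals,
                            theta=args.theta, seed=args.seed)
    segments = downsample_normals(segments, split_cfg.normal_remove_total,
                                  seed=args.seed)
    assignment = assign_subjects(segments, split_cfg)
    train_segs, val_segs, test_segs = materialize_splits(segments, assignment,
                                                         seed=args.seed)
    print("split sizes:", len(train_segs), len(val_segs), len(test_segs))

    tc = TrainingConfig(max_epochs=args.epochs, patience=10, seed=args.seed)
    binary = train(build_model(2, seed=args.seed),
                   binary_dataset(train_segs), binary_dataset(val_segs), tc)
    multiclass = train(build_model(3, seed=args.seed + 1),
                       multiclass_dataset(train_segs),
                       multiclass_dataset(val_segs), tc)

    test_ds = ArrayDataset.from_segments(test_segs)
    report = evaluate_cascade(binary, multiclass, test_ds.X, test_ds.y,
                              subjects=test_ds.subjects, assignment=assignment)

    args.out.mkdir(parents=True, exist_ok=True)
    binary.model.save(args.out / "binary.npz")
    multiclass.model.save(args.out / "multiclass.npz")
    (args.out / "report.json").write_text(json.dumps({
        "binary": json.loads(report.binary_kpis.to_json()),
        "multiclass": (json.loads(report.multiclass_kpis.to_json())
                       if report.multiclass_kpis else None),
        "end_to_end": json.loads(report.end_to_end_kpis.to_json()),
        "binary_confusion": report.binary_cm.counts.tolist(),
        "binary_confusion_row_pct": report.binary_cm.row_normalized_pct().tolist(),
        "multiclass_confusion": report.multiclass_cm.counts.tolist(),
        "end_to_end_confusion": report.end_to_end_cm.counts.tolist(),
        "false_forwards": report.false_forwards,
        "assignment": json.loads(assignment.to_json()),
    }, indent=2))
    print(f"end-to-end accuracy {100 * report.end_to_end_kpis.accuracy:.1f}%; "
          f"reports in {args.out}")


if __name__ == "__main__":
    main()
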