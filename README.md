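# ecgcascade

Two-stage 1-D CNN cascade for heartbeat-disorder classification in
single-lead ECG, with inter-patient (subject-exclusive) evaluation and a
synthetic annotated-cohort generator so the whole pipeline is testable
without a clinical database.

## Who this is for

Researchers and engineers working on beat-level ECG arrhythmia
classification who need: a reproducible preprocessing + segmentation
pipeline (notch filtering, baseline rejection, Z-score, R-peak-centered
6-s windows), a rule-based subject-exclusive data split that keeps the
classes balanced across train/validation/test, and a cascade classifier
whose second stage sees only the segments the first stage flags abnormal.

## The method in brief

Each annotated R peak `r` yields a half-open window `[r − H, r + H)` with
`H = 3 s × 360 Hz = 1080` samples (2160 samples per segment), labeled
`0=N, 1=PVC, 2=LBBB, 3=RBBB` by the central beat. A binary CNN estimates
`P(Abnormal)`; segments with `argmax = Abnormal` are routed to a 3-class
CNN over (PVC, LBBB, RBBB). Both stages share a 19-layer architecture
(8×Conv1D with filter ladder 16-16-32-32-32-32-256-256, 3×MaxPool, global
max pool, 4×Dropout, Dense 64-64-4, softmax head of 2 or 3 neurons),
trained with Adam (lr 0.001, batch 32, ≤50 epochs) under early stopping
(patience 10 on validation accuracy) with best-epoch checkpointing.

Performance is reported per stage and end-to-end with confusion matrices
and the usual one-vs-rest metrics

    Precision = Tp/(Tp+Fp)   Recall = Tp/(Tp+Fn)
    Accuracy  = (Tp+Tn)/N    F1 = 2·P·R/(P+R)

macro-averaged across classes (overall accuracy is trace/total).

See `docs/methods.md` for the full model description, the splitting
algorithm, the synthetic generator's assumptions, and known limitations.

## Worked example

Run the full desk-scale experiment — generate a 20-subject synthetic
cohort (180 s records at 360 Hz, 55/15/15/15 class mix), preprocess and
segment it, split it subject-exclusively, train both cascade stages
(width multiplier 0.25, ≤10 epochs), and evaluate on the held-out
patients:

```bash
ecgcascade run --seed 0
```

which prints (a few minutes on one CPU):

```json
{
  "n_segments": 4036,
  "n_test_segments": 808,
  "binary_accuracy_pct": 98.886,
  "end_to_end_accuracy_pct": 94.183,
  "end_to_end_macro_f1_pct": 90.995,
  "end_to_end_macro_precision_pct": 91.953,
  "end_to_end_macro_recall_pct": 91.289,
  "false_forwards": 6,
  "split_balance_score": 0.002,
  "binary_best_epoch": 10,
  "multiclass_best_epoch": 4,
  "multiclass_accuracy_pct": 89.356
}
```

Reading the numbers: of 4036 six-second segments, 808 belong to the test
patients (never seen in training). The binary stage separates
Normal/Abnormal at ~99 %; the multiclass stage names the arrhythmia
correctly for ~89 % of the segments it receives; end-to-end, ~94 % of all
test segments get the right 4-class label. `false_forwards` counts
true-Normal segments the binary stage wrongly routed to the arrhythmia
stage; the balance score is the split's deviation from perfectly
proportional class shares (0 is ideal).

The stage-wise tools are also exposed individually:

```bash
ecgcascade synth --out data/ --subjects 20 --seed 1
ecgcascade preprocess --data data/ --out segments.csv
ecgcascade split --segments segments.csv --out-dir splits/
ecgcascade train --train splits/train.csv --val splits/val.csv \
    --stage binary --width-multiplier 0.25 --epochs 10 --out binary.npz
ecgcascade train --train splits/train.csv --val splits/val.csv \
    --stage multiclass --width-multiplier 0.25 --epochs 10 --out multi.npz
ecgcascade evaluate --binary binary.npz --multiclass multi.npz \
    --segments splits/test.csv --out report.json
```

Library use mirrors the CLI (`ecgcascade.run_experiment`,
`ecgcascade.preprocess.preprocess_record`, `ecgcascade.split.assign_subjects`,
`ecgcascade.nn.build_model` / `train`, `ecgcascade.cascade.evaluate_cascade`).
Clinical WFDB records (format-16 `.hea`/`.dat`, beat `.atr`) are read via
`ecgcascade.io.read_record` / `read_annotations`, which map the standard
beat codes N/V/L/R onto the four classes; records at other sampling rates
are resampled to 360 Hz by linear interpolation.

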