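# Methods

## Problem and approach

`ecgcascade` classifies individual heartbeats in single-lead ECG into four
classes — Normal (N), premature ventricular contraction (PVC), left
bundle-branch block (LBBB) and right bundle-branch block (RBBB) — with a
two-stage cascade of 1-D convolutional networks. A binary stage labels each
beat-centered segment Normal/Abnormal; only segments the binary stage flags
Abnormal reach a three-class stage that names the arrhythmia. The cascade
exists because the class mix is heavily skewed toward Normal: the second
stage trains on a balanced, arrhythmia-only subset and is never asked to
model the dominant class.

Evaluation is *inter-patient* (subject-exclusive): every segment from one
patient lands in exactly one of train/validation/test. Beats from one
patient resemble each other far more than beats across patients, so any
split that mixes a patient across sets inflates accuracy; the training API
refuses subject overlap outright.

## Preprocessing

Per record, in order:

1. **50 Hz notch** (IIR, quality factor Q = 30) against power-line
   interference;
2. **baseline rejection**: a zero-phase second-order Butterworth high-pass
   at 0.05 Hz. A true 0.05 Hz notch at fs = 360 Hz is numerically fragile;
   the contract is attenuation of the drift band, and the high-pass meets
   it while also removing DC;
3. **Z-score** over the whole record (population standard deviation —
   fixed so exact-value tests are well defined; at record lengths of 10^4+
   samples the sample/population distinction is negligible);
4. **resampling** to 360 Hz by linear interpolation when the source rate
   differs, with annotation indices rescaled by the same ratio;
5. **segmentation**: one half-open window `[r − H, r + H)` per annotated R
   peak, `H = 3 s × 360 Hz = 1080` samples, so every window holds exactly
   2160 samples. The label is the *central* annotation's class regardless
   of neighboring beats inside the window. An inclusive 3-s-each-side
   window would hold 2161 samples; the half-open convention is what makes
   the stated 2160 exact. Beats closer than H to a record edge are skipped
   (windows are never zero-padded), and skips are logged.

All filtering is forward-backward (zero phase), so R-peak sample indices
remain valid after filtering; the two filter stages are linear and commute
to numerical precision.

## Network architecture

Both stages share a 19-layer 1-D CNN (all hidden activations ReLU,
input 2160 × 1):

| block | layers |
|---|---|
| 1 | Conv(k5, 16) × 2 → MaxPool(2, stride 1) → Dropout 0.1 |
| 2 | Conv(k3, 32) × 2 → MaxPool(2, stride 2) → Dropout 0.1 |
| 3 | Conv(k3, 32) × 2 → MaxPool(2, stride 1) → Dropout 0.1 |
| 4 | Conv(k3, 256) × 2 → GlobalMaxPool → Dropout 0.2 |
| head | Dense 64 → Dense 64 → Dense 4 → softmax Dense (K = 2 or 3) |

Convolutions use "same" padding and stride 1; pooling is "valid". The
feature-map length trace at full width is 2160 → 2159 → 1079 → 1078 → 1
(global pool). A `width_multiplier` scales the conv-filter ladder and the
two Dense-64 layers (floor 1 filter / 4 units) so desk-scale experiments
train in minutes on one CPU; the architecture audit is defined at
multiplier 1. The Dense(4)-before-softmax bottleneck is unusual but is part
of the reference layer table and is implemented verbatim.

Weights are Glorot-uniform initialized under the run seed. With symmetric
He-style initialization the narrow (width-scaled) variants sit at
chance-level loss for many epochs before breaking out; Glorot-uniform —
the convention of the Keras stack this architecture is written in — breaks
out within the first few epochs.

## Losses and training protocol

The binary stage minimizes binary cross-entropy on the positive-class
(Abnormal) probability, `−[y log a + (1 − y) log(1 − a)]` averaged over the
batch; the multiclass stage minimizes sparse categorical cross-entropy
`−log a_true`. Probabilities are clipped at 1e-7. (For a 2-way softmax the
two losses coincide, which is also how the shared training loop computes
gradients: `(softmax − onehot)/batch`.)

Optimization: Adam, learning rate 0.001, batch size 32, at most 50 epochs.
Early stopping halts training once validation accuracy has not strictly
improved for 10 consecutive epochs; the returned weights are those of the
best-validation-accuracy epoch (checkpointing). Training-set order is
reshuffled every epoch under the run seed.

Narrow width-scaled networks occasionally fail to leave the chance-level
saddle within a short epoch budget. `pipeline.train_with_restarts` wraps
the protocol with a standard multi-restart rule: a run whose best
validation accuracy stays below a stage-specific bar (0.9 binary, 0.8
multiclass — the stages have different chance levels) is re-initialized
(new seed-derived init, at most 3 attempts), runs still at chance after
four epochs are aborted early, and the best-validation attempt is kept.
The decision uses validation data only.

## Rule-based splitting

1. **Normal downsampling** (optional; default off at desk scale): remove a
   requested total of Normal segments spread evenly across subjects (equal
   per-subject quota, remainder redistributed to subjects with normals to
   spare; within a subject, uniform at random under the seed).
2. **Non-arrhythmic exclusion**: a subject whose arrhythmic fraction is
   strictly below θ (default 0.01) is barred from train/val — such
   subjects carry no class-balance information — but remains eligible for
   test, where unseen-patient generalization is measured.
3. **Assignment**: subjects are placed whole into train/val/test
   (default fractions 0.6/0.2/0.2 by segment share) minimizing the balance
   score `Σ_splits Σ_classes |count(split, class) − fraction(split) ·
   count(class)| / total`, which is zero exactly when every split holds
   its proportional share of every class. Cohorts of ≤ 10 subjects are
   solved exactly by enumeration; larger cohorts use a largest-first
   greedy pass polished by steepest-descent single moves and pairwise
   swaps. Ties break lexicographically, making the assignment
   deterministic.

## Synthetic cohort generator

The generator exists so that every stage is testable without access to a
clinical database. One beat is a sum of five Gaussian bumps (P, Q, R, S, T;
RBBB adds an R′ bump 0.05 s after R). The class templates encode the
clinically distinguishing morphology: PVC — no P wave, wide QRS
(half-max width ≈ 0.11 s vs ≈ 0.05 s for N), inverted T; LBBB — wide
slurred QRS with P preserved; RBBB — near-normal QRS plus the R′
deflection. Template parameters are free constants of the generator,
documented in `synth.default_templates`.

Per subject, one lognormal amplitude factor and one width factor per class
(scale 0.10) perturb the templates, so within-subject beats are more alike
than between-subject beats — the property subject-exclusive evaluation is
about. RR intervals are Gaussian around the configured heart rate
(70 ± 5 bpm), truncated at 0.4 s. Records add a 50 Hz sinusoid (0.05 mV),
slow sinusoidal baseline wander (0.10 mV at 0.2 Hz) and white noise
(0.02 mV).

**Rhythm episodes, not i.i.d. beats.** Within a record, beat classes are
laid out as contiguous quota-exact episodes (one block per class, random
order), not drawn independently per beat. This mirrors real arrhythmia
recordings — bundle-branch block is a persistent conduction condition, and
ventricular ectopy clusters in bigeminy/trigeminy episodes — and it
matters for learnability: the architecture ends in a global max pool and
is therefore position-blind within the 6-s window. Under i.i.d. beat
classes, window *content* is nearly independent of the *central* beat's
label and no content-based classifier can recover it; under episode
structure the two coincide except in windows straddling an episode
boundary. Default records are 180 s (~200 beats), keeping boundary windows
a small fraction (~5–10 %) of the data — they are the generator's built-in
irreducible error for this architecture.

What the generator does **not** emulate: 12-lead geometry, respiratory and
heart-rate-variability modulation, electrode artifacts, fusion and
aberrant beats, morphology drift within a subject, and realistic episode
alternation statistics. Passing tests on this cohort therefore demonstrate
that the pipeline's mechanics and the cascade's learning dynamics are
correct — not that clinical-database accuracy carries over.

## Desk-scale study conditions

The end-to-end recovery experiment (also what `scripts/acceptance.py`
runs) uses: 20 subjects × 180 s at 360 Hz, class mix 55/15/15/15,
width multiplier 0.25, at most 10 epochs per stage, ~4000 segments total,
~800 of them in the held-out test split. This trains both stages in a few
minutes on one CPU. Full-scale runs (multiplier 1, 50-epoch budget, WFDB
input) use the same code paths.

## Numerical choices and edge cases

* argmax ties (binary and multiclass heads) break toward the lowest class
  index — deterministic cascade routing.
* Z-score of a constant signal raises a degenerate-input error rather than
  returning NaN.
* Wrongly forwarded true-Normal segments have no true arrhythmia class:
  they are excluded from the 3-class confusion matrix, counted separately
  as `false_forwards`, and charged as errors in the end-to-end report.
* Multiclass aggregate metrics are macro-averaged (recorded in the report);
  overall accuracy is trace/total.
* Segment CSV round trips are lossless (`%.17g` on write, round-trip float
  parsing on read); the WFDB format-16 path quantizes at 1/200 mV.
* Duplicate annotations (identical index and symbol) collapse to one with
  a logged warning; annotation order is normalized to ascending sample
  index.

## Known limitations

* The WFDB codec covers format-16 signals and beat-type `.atr` annotations
  only — enough to round-trip the generator's output and read simple
  clinical records; format 212 and multi-segment records are out of scope.
* The exhaustive splitter is exponential and hence capped at 10 subjects;
  beyond that the polished greedy is a heuristic with no optimality bound
  (it is oracle-checked against enumeration on small instances).
* Training is plain numpy on one core; full-width training is
  possible but slow (hours, not minutes).
* Accuracy on the synthetic cohort is an upper bound on mechanism
  correctness, not a clinical claim; see the generator's non-goals above.
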