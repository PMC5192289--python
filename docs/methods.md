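# Methods

`nodulefpr` implements the false-positive-reduction (FPR) stage of a lung
nodule CAD pipeline: given a candidate region of interest (ROI) flagged by an
upstream detector, classify it as nodule or nonnodule.  This note records the
model, the procedural choices that were genuinely open, and what the synthetic
test bed does and does not establish.

## ROI extraction

Annotations arrive as LIDC-style XML: freehand contours for nodules ≥ 3 mm
(one `edgeMap` point list per slice ROI) and single centroid marks for small
nodules and nonnodules.  For each record:

1. the geometric center is the arithmetic mean of the contour vertices,
   rounded half-up per axis;
2. the region extent is the inclusive bounding box of the vertices;
3. if the extent fits within 32×32, a direct 32×32 crop is taken around the
   center; otherwise a 64×64 crop is taken and reduced by non-overlapping
   2×2 mean pooling.  The branch depends only on geometry, never on
   intensities.  Mean pooling was chosen over interpolation because it
   preserves the image mean exactly, which makes the reduction testable to
   machine precision.

Conventions the annotation format leaves open, fixed here: 0-based
`(row, col)` coordinates with `xCoord` the column; half-open crops
`[c − size/2, c + size/2)` for even windows; crops beyond the slice are padded
with the intensity-window floor (air-equivalent).  Intensities are mapped to
[0, 1] by a fixed linear window — the full stored dynamic range of the slice
dtype for array inputs, [−1000, 400] HU for DICOM — so normalization never
depends on the dataset statistics and reruns are reproducible.

## Network

The 32×32 single-channel patch passes through

    conv(8 @ 5×5, stride 1) → maxpool(2×2, stride 2)
    → conv(16 @ 5×5, stride 1) → maxpool(2×2, stride 2)
    → fc(150) → fc(100) → fc(50) → fc(2) → softmax

All convolutions are "valid" (no padding) cross-correlations; the activation
chain of flattened unit counts is 1024 → 6272 → 1568 → 1600 → 400 → 150 →
100 → 50 → 2.  Conv and hidden fc layers use `y = max(0, ωx + B)`; the final
fc layer feeds the softmax directly (applying ReLU to the logits would
truncate one class's evidence).  Class index 0 is nonnodule, 1 is nodule; an
exact probability tie predicts nonnodule, the conservative choice for an FPR
tool.  The 400-unit count after the second pooling layer follows from shape
arithmetic (16 maps × 5 × 5) and is validated by the shape-inference tests.

Open choices resolved here:

* **Loss** — softmax paired with cross-entropy, the standard probabilistic
  pairing; gradients at the logits are then `p − onehot(y)`.
* **Initialization** — fan-in/fan-out scaled uniform weights
  (bound `sqrt(6/(fan_in+fan_out))`), zero biases, always from an explicit
  seed.  A He-normal scheme is available as an option.
* **Numerics** — all accumulation in float64; softmax subtracts the max
  logit; probabilities are clamped to `[1e-12, 1]` before logs; max-pool ties
  route the gradient to the first maximum in row-major order.
* **64×64 inputs** — the layer kinds generalize and shape inference handles
  any square input, but no default 64×64 parameterization is claimed; users
  supply their own `NetworkConfig`.

The vectorized conv/pool forward and backward passes are cross-checked in the
test suite against nested-loop oracles (exact to round-off) and against
central-difference gradients (< 1e-5 relative per layer, < 1e-4 end to end).
The end-to-end check samples random coordinates per parameter tensor — the
default network has ~2.7·10⁵ parameters — and excludes coordinates whose
finite-difference stencil straddles a ReLU kink or a pooling argmax flip,
detected by comparing difference quotients at two step sizes.

## Training

Classical momentum SGD: `v ← μv − ηg`, `w ← w + v`, gradients averaged over
minibatches, the training set reshuffled from a seeded generator every epoch.
Protocol defaults: η₀ = 5·10⁻⁴, μ = 0.9, a 50-epoch horizon, batch size 32
(the batch size is this package's choice; the protocol source does not state
one).

Two schedules:

* `constant` — used by the cross-validation protocol;
* `decay_on_precision` — once the training-set accuracy first reaches 0.85,
  η is multiplied by 5/6 at the end of that and every subsequent epoch
  (η = η₀·(5/6)^d after d post-threshold epochs).  The triggering metric is
  training-set accuracy, and the decay repeats per epoch; both points are
  interpretations of an underspecified rule, so a one-shot variant
  (`decay_mode="one_shot"`) is exposed as well.  The rate never increases,
  even if precision later dips below the threshold.

Termination: `max_epochs`; or training precision ≥ `target_accuracy` when
set; or a concrete convergence rule — epoch loss improving by less than 1e-6
for 5 consecutive epochs.  A non-finite loss aborts with the diagnostic state
attached rather than continuing from poisoned parameters.

## Evaluation

* **CF-test**: k-fold cross-validation (k = 10 by convention; smaller k for
  scaled-down runs).  The headline report pools confusion counts across folds
  (micro-average); per-fold reports and the macro-averaged accuracy are also
  returned, since the two aggregations can differ.
* **DD-test**: one seeded holdout split with |train| = round(0.857·n); the
  fixed test set is re-scored after every epoch, giving a trajectory.

Metrics, with nodule = positive: accuracy, sensitivity = TP/(TP+FN),
F-measure taken as F1 (the harmonic mean of precision and sensitivity — the
protocol source never defines it), and FP/exam = FP divided by the number of
distinct exams contributing patches to the evaluated set (the denominator is
likewise this package's definition).  Zero-denominator cases report 0 and set
a `degenerate` flag instead of raising.

Splits are patch-level by default, matching the protocol's silence on the
question; `grouping="by_exam"` is provided because patch-level splits let
exam-level appearance leak between train and test, and grouped splits are the
defensible choice for real data.

## Synthetic data

The generator emulates the appearance classes the classifier must separate:
solid (compact bright Gaussian blob), semisolid (bright core in a fainter
halo), ground-glass opacity (wide, half-contrast blob) as nodules; an
elongated bright ridge at random orientation (a longitudinally cut vessel)
and faint off-center lumps over noise as nonnodules.  Structures sit within
±2 px of the patch center, as if a candidate detector had fired there.
Default class imbalance mirrors the LIDC-scale extraction ratio
40,772 : 21,720 ≈ 1.877.

`separation` sets the contrast-to-noise ratio: peak contrast/noise σ of
0.55/0.04 (`high`), 0.25/0.08 (`medium`), 0.03/0.12 (`low`) over a 0.25
background level.  `high` is cleanly learnable; `low` buries the signal so
holdout accuracy collapses to chance, which the suite uses as a negative
control against label leakage.  Exam ids are dealt round-robin so grouped
splits are deterministic.

Limitations: intensities are not Hounsfield-calibrated, there is no scanner
noise model, no 3-D context, no reader disagreement, and class appearance is
far more homogeneous than real LIDC nodules.  Passing the learnability
checks therefore demonstrates that the extraction, network, optimizer and
protocols function and interoperate correctly — not that the published
real-data operating points would be reproduced.  Reproducing those requires
the LIDC-IDRI download and multi-hour training runs, supported through the
`extract`/`train`/`evaluate` CLI but outside the test surface.

## Problem sizes in the checks

The shipped checks run the default network on a 2,000-patch high-separation
dataset at the mirrored class ratio: full training (≤ 30 epochs, early stop
at 0.95 training precision) and a 3-fold CF-test (early stop 0.97).  Layer
gradient checks use random small shapes; the end-to-end check uses a 3-patch
batch with 8 sampled coordinates per tensor; brute-force equivalence uses 50
random instances.  These sizes keep a full verification run in minutes on one
CPU while exercising every code path.
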