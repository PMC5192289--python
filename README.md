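# nodulefpr

False-positive reduction for pulmonary nodule CAD: a from-scratch
convolutional classifier for CT regions of interest, with the full pipeline
around it — ROI patch extraction from LIDC-style annotations, training by
momentum SGD with a precision-triggered learning-rate decay, two evaluation
protocols, and a synthetic-data generator so everything is testable without
any image download.

## The problem

Candidate detectors in lung CAD pipelines flag many nonnodule structures
(vessels seen longitudinally, parenchymal texture) alongside true solitary
pulmonary nodules.  The false-positive-reduction stage is a binary classifier
that receives a small grayscale patch around each candidate and decides
nodule vs nonnodule, covering the three nodule presentations: solid,
semisolid, and ground-glass opacity (GGO).

## The model

A 32×32 single-channel patch `x ∈ [0,1]³²ˣ³²` passes through

    conv(8 @ 5×5, s=1) → maxpool(2×2, s=2) → conv(16 @ 5×5, s=1) → maxpool(2×2, s=2)
    → fc(150) → fc(100) → fc(50) → fc(2) → softmax

with `y = max(0, ωx + B)` at conv and hidden fc layers, `y = max(x)` per
pooling window, and valid (unpadded) convolutions, giving the activation
chain 1024 → 6272 → 1568 → 1600 → 400 → 150 → 100 → 50 → 2.  Training
minimizes softmax cross-entropy by backpropagation with classical momentum
(`v ← μv − ηg`, `w ← w + v`; defaults η₀ = 5·10⁻⁴, μ = 0.9), reshuffling
every epoch.  Optionally, once training accuracy reaches 0.85 the learning
rate decays by a factor 5/6 per epoch.  Evaluation reports accuracy,
sensitivity, F-measure (F1) and FP/exam under either k-fold cross-validation
("CF-test") or a fixed 85.7 % holdout scored after every epoch ("DD-test").
Every layer's backward pass is verified against central-difference gradients,
and the vectorized forward passes against nested-loop oracles.
See `docs/methods.md` for the full account.

## Worked example

Generate a learnable synthetic dataset (class imbalance mirroring the
LIDC-scale 40,772 : 21,720 ratio), train, and cross-validate:

```bash
nodulefpr synth --n-nodules 1305 --n-nonnodules 695 --separation high \
    --exams 20 --seed 11 --out patches
# wrote 2000 patches (1305 nodules) -> patches/manifest.csv

printf 'max_epochs: 30\ntarget_accuracy: 0.95\n' > train.yaml
nodulefpr train --data patches/manifest.csv --config train.yaml \
    --out model.ckpt --seed 3
# trained 16 epochs (stop: target_accuracy); final loss 0.1136,
# precision 0.9910; checkpoint -> model.ckpt, log -> model.log.csv

printf 'max_epochs: 30\ntarget_accuracy: 0.97\n' > eval.yaml
nodulefpr evaluate --data patches/manifest.csv --mode cf --k 3 \
    --config eval.yaml --seed 5 --report cf_report.json
# cf-3fold: accuracy 0.9855, sensitivity 0.9985, FP/exam 1.3500,
# F-measure 0.9890 -> cf_report.json
```

Reading the output: training stopped early because the training-set precision
crossed the 0.95 target after 16 epochs.  The 3-fold cross-validation pools
confusion counts over the three held-out thirds: 98.6 % of the 2000 patches
were classified correctly, 99.9 % of true nodules were kept (sensitivity),
and the 27 false positives spread over the 20 synthetic exams give 1.35
FP/exam.  On real data one would extract patches instead:

```bash
nodulefpr extract --annotations ann_xml/ --slices slices/ --mode 32 --out patches
```

where `slices/<case_id>/<slice_id>.npy|.dcm` holds the CT slices; DICOM input
is windowed to [−1000, 400] HU.  The same library surface is importable from
Python (`nodulefpr.network`, `.training`, `.evaluation`, ...).

## Layout

| path | content |
| ---- | ------- |
| `src/nodulefpr/tensor_core.py` | layer forward/backward primitives + numeric-gradient oracle |
| `src/nodulefpr/network.py` | architecture, initialization, forward, checkpoints |
| `src/nodulefpr/roi_extraction.py` | annotation parsing, patch cutting, manifests |
| `src/nodulefpr/training.py` | momentum SGD, schedules, training loop |
| `src/nodulefpr/evaluation.py` | splits, metrics, CF-/DD-test protocols |
| `src/nodulefpr/synthetic_data.py` | patch generator and annotation fixtures |
| `src/nodulefpr/cli.py` | `nodulefpr` command-line entry point |
| `docs/` | methods note, checkpoint byte layout |
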