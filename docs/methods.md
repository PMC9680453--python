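# Methods

## Model

Each subject contributes two short-axis stacks (one diastolic, one
systolic frame), each an ordered sequence of 8–25 slices, apex to base.
Every slice carries one of five ordered levels: `oap`(0), `ap`(1),
`mid`(2), `bs`(3), `obs`(4).

**Feature extraction (frozen).** A convolutional backbone maps each
grayscale slice (replicated to 3 channels, resized to the backbone's input
size, scaled per its preprocessing mode) to the global average pool of its
last convolutional output. Backbones are never trained here — transfer
learning in the fixed-feature-extractor setting — so feature extraction is
a pure, deterministic function and features are cached on disk keyed by a
content checksum. Four named ImageNet architectures are described with
their published pooled dimensions (EfficientNetB0 1280, MobileNet 1024,
NASNetMobile 1056, ResNet50V2 2048); since their pretrained weights are
not bundled, requesting them raises with an instruction to use
`weights="random"`, which substitutes a frozen, seeded random
convolutional trunk (3→16→32→64 channels, 3×3 stride-2, ReLU, GAP)
followed by a fixed random projection to the declared dimension. The
`TinyTest` backbone is that same trunk at 64×64 input with its native
64-d output; it is the default extractor for CPU-scale experiments. Random
frozen convolutional features are a standard cheap baseline; nothing in
the pipeline depends on feature semantics, only on dimension and
determinism.

**Sequence classifier (many-to-many).** Features are post-padded to
T = 25 time steps — the maximum slice count in the target data — with an
explicit validity mask. The recurrent encoder is one of four variants:
two stacked unidirectional LSTM or GRU layers of 128 units, or a single
bidirectional LSTM or GRU layer with 128 units per direction. A shared
dense head (256 ReLU units, dropout 0.5, softmax over 5 classes) is
applied at every time step. The CNN-alone baseline applies the same head
to each slice's features independently.

**Training.** Adam at its conventional defaults (lr 1e-3, β₁ 0.9,
β₂ 0.999), categorical cross-entropy averaged over valid steps only,
mini-batches of 2 sequences (32 images for the CNN-alone head), a fixed
number of epochs. The deployment epoch is the argmin of the validation
loss, earliest on ties — an automated stand-in for visual inspection of
the loss curve; the best-validation weights are snapshotted during
training so no retraining is needed. Everything is numpy float64 with
explicit backprop; the test suite checks all four recurrent variants
against central-difference gradients at ~1e-7 relative error, and
training is bit-deterministic for a fixed seed.

**Masking semantics.** At a masked time step, recurrent state passes
through unchanged and the emitted output is zero; the loss and its
gradient are computed over valid steps only. Consequently padded rows are
provably inert in both temporal directions — asserted by perturbation
tests (loss and valid-step probabilities move < 1e-6 under arbitrary
padding content).

## Evaluation

All valid test slices are pooled into one 5×5 confusion matrix (rows
true, columns predicted). From it: one-vs-rest precision/recall/F1 per
class (zero-denominator cases return 0 with a warning); accuracy =
trace/total; SOTD = Σ entries with |i−j| ≥ 2 ("tridiagonal" read as the
|i−j| ≤ 1 band under the fixed ordinal mapping). Weighted AUC is the
support-weighted mean of per-class one-vs-rest ROC AUCs (scikit-learn per
class); classes absent from the truth are excluded with a warning, and a
single-class truth is an error. The 5→3 merge sums rows/columns 1–3 into
an `in` class; merged error = 1 − trace/total of the 3×3 matrix, which can
never exceed the 5-class error because merging only removes confusions.
Argmax ties in prediction resolve to the lower ordinal.

## Synthetic phantoms

The generator encodes only the label-defining morphology, not MRI physics:

* `oap` — smoothed-noise background only (no pool, no ring);
* `ap`/`mid`/`bs` — dark myocardial annulus (intensity ≈ 35) enclosing a
  bright pool (≈ 215) on a textured background (≈ 75), cavity radius drawn
  per level: ap 6–10 px, mid 10–14 px, bs 13–18 px at 128×128, wall 4–7 px;
* `mid` additionally places 1–3 dark papillary blobs (radius 2–4 px)
  inside the pool;
* `obs` — a partial annulus (crescent spanning 90–162°) with no enclosed
  pool.

Systole scales the cavity by a per-subject factor drawn from 0.60–0.85
and thickens the wall correspondingly. Additive Gaussian noise (sd 8
intensity units) is applied and clipped to [0, 255]. These pixel-scale
values are fixed package defaults chosen once to give a learnable but
non-trivial task (adjacent levels overlap in geometry; the papillary cue
nearly vanishes after 8× downsampling in the backbone, so sequence context
genuinely helps); they are echoed into every dataset manifest. The
renderer emits its exact pool/blob/ring masks as a side channel, so tests
verify morphology without image analysis.

Label sequences are monotone apex→base (`oap* ap* mid* bs* obs*`), with
`ap`, `mid`, `bs` always present and each out-of-level cap present with
probability 0.85; slice counts are uniform on [8, 25]. Both phases of a
subject share one label sequence (recorded in the manifest). Real stacks
are ordered apex to base but their labels are not guaranteed strictly
monotone; the generator enforces monotonicity and this is a documented
idealization. Likewise the phantom has no motion, no off-axis geometry, no
intensity inhomogeneity, no arrhythmia — so green tests demonstrate the
pipeline's correctness and the cascade's ordinal advantage on data with a
clean sequence structure, not clinical-grade performance.

Datasets are byte-deterministic in (config, seed): per-subject seeds are
derived through `numpy.random.SeedSequence`.

## Curation

Three exclusion rules, applied per subject before anything downstream:
duplicate slice identifiers (two files parsing to the same
(phase, index)), inconsistent slice counts between phases, and
non-contiguous indices within a phase. "Identifier" is read as the
(subject, phase, slice index) file key; contiguity means consecutive
integers after sorting, agnostic to the index base. The generator can
plant exactly these violations for testing. Intensity rescaling is
per-image linear min–max to [0, 255] (constant images map to zero).
Subject-wise splitting uses largest-remainder rounding of the fractions
(0.591, 0.220, 0.189 by default; ties broken in train/val/test order), so
974 subjects yield (576, 214, 184). Selection of the two cardiac phase
frames from a full cine series is outside the core; a helper that proxies
systole by minimal supra-median bright area is provided as a clearly
labelled stand-in.

## Design choices where the design was open

* **Bidirectional arrangement.** Bidirectional variants are one layer of
  128 units per direction; two-layer variants are two stacked
  unidirectional 128-unit layers. At the 64-d working feature dimension
  this gives exact trainable-parameter parity for LSTM (264,709 each,
  head included — the extra first-layer input projection of the second
  direction exactly offsets the doubled head input) and ~4% for GRU. At
  feature dimensions ≥ 1024 the input projection dominates and the two
  arrangements diverge beyond 15%; parity is therefore asserted for the
  configuration the experiments actually run.
* **Padding** is post-padding with an explicit mask (keeps slice i at
  step i); loss is masked, not padded-label-weighted.
* **Per-backbone preprocessing**: `symmetric` ([−1, 1]) for MobileNet,
  NASNetMobile and ResNet50V2, `raw` (0–255 passthrough) for
  EfficientNetB0, `unit` ([0, 1]) for TinyTest; input 224×224 for the
  named backbones, declared in the spec object and logged.
* **Epoch selection** is automated argmin (earliest tie) rather than
  manual curve inspection.
* **Snapshot policy**: best-validation weights plus final weights only.

## Problem sizes

The package's reference experiment — used by the acceptance script and the
directional-claim test — is 60 phantom subjects (120 stacks, ~2,000
slices), default split fractions, TinyTest features, 15 training epochs,
all five variants; one full run takes about a minute on one CPU core. The
directional claim (every CNN-RNN variant's SOTD ≤ the CNN-alone head's,
all models above 5-class chance accuracy 0.2) is asserted on means over
three seeds. These sizes are the package's chosen reference conditions
for a CPU-scale reproduction of the cascade effect; magnitudes of the
scores at this scale are not comparable to results on real cine cohorts.

## Known limitations

* Random frozen features carry no ImageNet semantics; absolute scores are
  far below what pretrained backbones reach on real data.
* The unidirectional two-layer variants see no future context and at this
  scale often lag the bidirectional ones noticeably — the out-of-apical
  start of a stack has no preceding signal.
* The phantom's monotone labels make the sequence prior stronger than in
  real stacks; SOTD → 0 is easier here than clinically.
* No data augmentation, no backbone fine-tuning, no 3D convolutional
  baseline; single-slice-thickness geometry only.
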