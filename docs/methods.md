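# Methods

## Problem and model

`mlanet` detects and localizes myocardial infarction (MI) from segmented
12-lead ECG heartbeats.  A beat is a matrix `L ∈ R^{12×651}` (leads × time,
1000 Hz, values standardized to [−1, 1]).  The network has four parts:

1. **Multi-lead attention (MLA).**  Each lead receives a trainable weight
   through the clipped-linear *StepReLU* activation,

       StepReLU(x) = 0 (x < 0);  x (0 ≤ x ≤ 1);  1 (x > 1)
       M₁ = tanh(W₁L + b₁),  α₁ = StepReLU(M₁w₁),  X = α₁ ⊗ L,

   with `W₁ ∈ R^{12×12}`, `b₁ ∈ R^{12}` (added to every column), `w₁ ∈
   R^{651}`, and `⊗` scaling row *i* of `L` by `α₁ᵢ`.  Unlike a softmax,
   the weights do not compete: any subset of leads can be kept at full
   strength, and a weight of exactly 0 eliminates a lead (StepReLU's flat
   branch has zero gradient, so an eliminated lead stays eliminated).

2. **Spatial branch.**  The weighted beat, viewed as a one-channel
   12 × 651 image, passes through two stages of
   conv → ReLU → batch norm → max pool → dropout.  Each conv layer runs
   three kernel shapes in parallel — (3,3), (5,1), (7,1), 20 kernels per
   shape, stride 1 — whose SAME-padded outputs are concatenated into 60
   channels; the tall 5×1/7×1 kernels mix five or seven *leads* at one
   time instant.  Pooling is a (2,2) window with stride 1 (valid), so each
   spatial dimension shrinks by exactly one per stage.  The 60 final maps,
   flattened row-major to vectors x′ₙ of length (12−2)·(651−2) = 6490,
   are combined by a softmax attention,
   `α₂ = softmax(w₂ᵀ tanh(W₂X′ᵀ + b₂))`, `f_s = Σₙ α₂ₙ x′ₙ`.

3. **Temporal branch.**  A bidirectional GRU iterates over the 651 time
   steps of X (input: the 12-lead sample at one instant):

       z_t = σ(W_xz x_t + W_hz h_{t−1} + b_z)
       r_t = σ(W_xr x_t + W_hr h_{t−1} + b_r)
       h̃_t = tanh(W_xh x_t + W (r_t ∗ h_{t−1}))
       h_t = (1 − z_t) ∗ h_{t−1} + z_t ∗ h̃_t

   The candidate line carries no bias by default (`gru_candidate_bias`
   turns one on); the two directions have independent parameters and their
   states are concatenated per step into `H ∈ R^{651×2h}`.  After batch
   norm and dropout, a second softmax attention pools H into
   `f_t = Σ_t α₃ₜ H_t`.

4. **Fusion and classification.**  `F = [f_s, f_t]` is batch-normalized,
   dropped out, and fed to a single fully connected layer — sigmoid output
   for detection (MI vs healthy control), softmax over classes for
   localization (HC, AMI, ALMI, ASMI, IMI, ILMI).  Training minimizes the
   mean (binary/categorical) cross-entropy with Adam.

## Preprocessing

Per record: (1) per-lead min–max standardization onto [−1, 1] (a constant
lead maps to zero with a warning); (2) Daubechies-6 multilevel DWT — the
coarsest approximation band is zeroed (baseline drift) and detail bands are
soft-thresholded with the universal rule σ√(2 ln N), σ estimated from the
finest band's MAD/0.6745; the result is re-clipped to [−1, 1]; (3)
Pan–Tompkins QRS detection on lead II (5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds with
search-back, 200 ms refractory period), with fiducials refined to the raw
lead's local extremum within ±40 ms — clipping can flatten the apex into a
plateau, so the plateau's center sample is taken; (4) segmentation into
[p−250, p+400] windows (651 samples, inclusive, 0-based) across all 12
leads; windows that exit the record are skipped, then the first and last
surviving beats are dropped.  The stage order (standardize first, then
denoise, detect, segment) keeps every emitted beat inside [−1, 1].

The DWT level defaults to 9 (the coarsest band then sits below ~1 Hz at
1000 Hz) and is clamped to the deepest level free of boundary artifacts for
short records.  Records are assumed to be sampled at 1000 Hz; resampling is
out of scope.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| beat window | 250 + 1 + 400 samples | fixed segmentation contract |
| kernels per shape | 20 (60 channels/layer) | reference architecture |
| GRU hidden size `h` | 64 (configurable) | unspecified upstream; CPU-trainable yet expressive |
| attention width (`W₂`/`W₃` rows) | 64 | projection width of both attention layers |
| dropout | 0.3 | selected upstream by validation grid search |
| batch size / lr / epochs | 24 / 0.001 / 20 | reference training configuration |
| Adam β₁, β₂, ε | 0.9 / 0.999 / 1e−7 | framework-conventional defaults |
| BN momentum / ε | 0.99 / 1e−3 | EMAs are zero-debiased (below) |

## Numerical and design choices

* **Compute core.**  The network runs on a small in-repo reverse-mode
  autodiff engine over numpy (`mlanet.autodiff`).  Convolution is evaluated
  channels-last as one GEMM per kernel offset over shifted slices of the
  zero-padded input, with reusable scratch buffers; gradient buffers of
  interior nodes are freed as the backward sweep retires them, which keeps
  peak memory at roughly one live tape.  `tune_allocator()` raises glibc's
  mmap/trim thresholds so large transient activations reuse heap pages.
  Every primitive's gradient is pinned against central finite differences
  in the test suite, as is the end-to-end loss gradient on a reduced
  architecture.
* **SAME padding** for all conv shapes: the three parallel kernel shapes
  must produce identical spatial dimensions to be concatenated on the
  channel axis.  BN sits after the activation; pooling stride is literally
  1.  Max-pool gradient ties route to the first maximal window position.
* **StepReLU gradient** is the exact clip subgradient — 1 on [0, 1]
  (corners included, keeping at-bound leads trainable), 0 on the flat
  branches.  A straight-through variant (gradient 1 everywhere) is
  available behind `straight_through_mla`, default off.
* **MLA initialization** starts attention near-uniform: `W₁` is a damped
  Glorot draw, `w₁` small positive uniform, `b₁ = 0.1`, placing all initial
  scores near 0.5 inside the identity branch.  A zero-mean score init would
  park half the leads on the dead branch immediately; a large initial
  spread would encode an arbitrary lead ranking that short trainings cannot
  wash out — reported lead weights should reflect training, not the draw.
* **Batch norm** keeps zero-debiased exponential moving averages (EMA
  divided by 1 − momentumᵗ) during training — with momentum 0.99 a raw EMA
  would still be dominated by its zero initialization after a few dozen
  updates.  After training, `train()` additionally *recalibrates* the
  statistics: one pass of the final model over the training beats in
  batch-statistics mode (dropout off), replacing the EMAs with exact
  averaged moments.  EMAs describe a mixture of past models; when the
  network changes quickly — e.g. the MLA eliminating leads late in a short
  run — they lag badly and eval-mode predictions diverge from training
  behaviour.  The recalibrated statistics belong to the final model by
  construction, at any training scale.
* **Training loop.**  One seeded shuffle per epoch, then consecutive
  slices; the final-epoch model is returned (no early stopping); the
  validation split exists for hyperparameter selection (grid search over
  dropout {0.2, 0.3, 0.4}, lr {0.0008, 0.001}, batch {16, 24, 32}, epochs
  {10, 20, 30}; ties break toward fewer epochs, then smaller batches).
  A non-finite loss aborts with a diagnostic; inside grid search it marks
  the configuration as failed instead of aborting the search.
* **Cross-validation.**  Both schemes split into five near-equal parts and
  rotate test/validation (3:1:1).  *Intra-patient* partitions beats;
  *inter-patient* partitions patients (stratified per class so every part
  contains each class; requires ≥ 5 patients/class), and beats follow
  their patients — patient-disjointness is asserted in the test suite.
  Each fold trains from an independent initialization (seed + fold index).
  Fold summaries report the mean and the population standard deviation.
  Reported lead weights are the mean α₁ over each fold's test beats,
  averaged across folds.
* **Metrics.**  Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(FP+TN),
  in percent; zero denominators give NaN with a warning.  Multi-class
  reports are one-vs-rest per class; the per-class "accuracy" of such a
  report collapses to the shared multi-class fraction-correct, so both the
  overall accuracy and the one-vs-rest breakdown are exposed.
* **I/O.**  Records: CSV matrices or WFDB-style header/16-bit-signal pairs
  (written with gain 8000 ADU/mV; Frank channels vx/vy/vz and other extras
  are dropped on read; lead-name matching is case-insensitive).  Beats: a
  compressed `.npz` of float32 matrices plus a CSV manifest of labels and
  patient IDs.  MI-subtype labels are always an explicit input (a label
  table), never inferred from headers.

## Synthetic data: what it emulates, and what it does not

Each beat is a sum of Gaussian bumps (P, QRS, T) with per-lead gains of
physiological sign and magnitude (aVR and V1 predominantly negative).  MI
classes add an ST-segment offset (window: QRS center + 60 ms to T onset)
and scale the T amplitude, *only* on the leads anatomically facing the
injured wall (e.g. inferior MI → II, III, aVF; antero-septal → V1–V4).
Patients vary by amplitude gain ~ U(0.7, 1.3) and heart rate ~ U(55, 95)
bpm; records carry additive Gaussian noise and sinusoidal baseline wander.
A *pure-noise lead* option replaces chosen leads with band-limited
(< 40 Hz) noise emulating a detached-electrode artifact — deliberately
uninformative channels that survive wavelet denoising, used for
lead-weight sanity checks.

The generator does **not** model realistic ECG dynamics (no RR variability,
no morphology drift within a record, no pathological conduction patterns),
so passing tests demonstrate that the pipeline and the learning machinery
behave as specified on data with the assumed structure — they are not
evidence of clinical performance.  Published results on the PTB database
(very high detection accuracy intra-patient, lower inter-patient)
require the external data and full-scale training and are out of scope
here.

## Problem sizes used by the test suite

The end-to-end check trains the full architecture (60-channel convs,
`h = 32`) on 400 synthetic beats (200 per class, ST shift 0.3 mV, noise SD
0.05 mV, one artifact lead) with five-fold intra-patient cross-validation
at 3 epochs per fold, asserting ≥ 95 % mean test accuracy and that the
artifact lead's mean attention weight ends below every informative lead's.
Unit and property tests run on reduced shapes (e.g. 12 × 40 beats, 2–4
kernels per shape) where the contracts are size-independent.

## Known limitations

* CPU-only; a training step on the full architecture takes a few seconds
  per 24-beat batch, so full-scale (hundreds of thousands of beats ×
  20 epochs) training is impractical with this engine.
* Fixed 1000 Hz / 12-lead / 651-sample contract; no resampling, no
  arrhythmia-aware alignment.
* Lead weights are input-dependent; the reported per-lead scalar is an
  average over evaluation beats and inherits their distribution.
* Class imbalance is not reweighted.
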