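# Methods

## Problem and pipeline

In NSTEMI the culprit coronary artery (or combination of arteries) is not
readable from the ECG by eye; this package implements a four-stage pipeline
that attempts the 7-class assignment — CX, RCA, LAD, CX+LAD, RCA+LAD,
RCA+CX, RCA+CX+LAD — from the 12-lead signal alone:

1. **Spectrogram front end.** Each lead is transformed by a short-time
   Fourier transform (Hamming window of 10 samples, hop 5, FFT length 512
   at 500 Hz), converted to dB, and rendered as a 64×64×3 viridis RGB
   image.
2. **MI-MS ConvMixer.** A multi-input (one branch per lead), multi-scale
   (patch sizes 16 and 8 on the same images — 24 branches) ConvMixer.  Each
   branch applies a stride-P patch convolution into H channels followed by
   GeLU and BatchNorm, then D mixer blocks (depthwise K×K convolution →
   GeLU → BatchNorm, with a residual connection around that stage, then a
   pointwise 1×1 convolution → GeLU → BatchNorm), then global average
   pooling.  Branch outputs are concatenated and pass through a linear
   embedding layer `fc_embed` (1000 wide) and a 7-way softmax.
3. **ReliefF.** Importance weights for the 1000 embedding features
   (k = 10 neighbors, exponential rank decay with sigma = 20, empirical
   class priors, every sample used as an anchor, Manhattan distance on
   range-normalized features).
4. **WSSE.** Features in descending ReliefF order are split into k = 10
   contiguous near-equal subspaces; one RBF SVM (C = 1, gamma = 1/(p·var),
   feature standardization) is trained per subspace; subspaces vote with a
   mass equal to the non-negative sum of their features' ReliefF weights,
   ties resolved in favor of the most important subspace.  An
   integer-replication voting mode (subspace i of k casts k−i+1 copies) is
   available as an alternative reading of "more important subspaces repeat
   more".

Evaluation is stratified k-fold (default 10; the desk-scale preset uses 3)
with a four-arm ablation under one fold plan: (a) the end-to-end softmax
model, (b) `fc_embed` features → one SVM, (c) features → top-q
ReliefF-selected columns → SVM (q = 500), (d) features → WSSE.  ReliefF,
feature selection, the SVMs and the ensemble are fitted strictly inside
each training fold.

## Synthetic cohort

The real cohort this pipeline targets is not publicly available, so the
package ships a generator whose class structure mirrors it: 1321 records,
12 leads at 500 Hz, 10 s each, with per-class counts
180/185/252/183/173/156/192.  Each artery is tied to its conventional lead
territory — RCA → II, III, aVF; LAD → V1–V4; CX → I, aVL, V5, V6 — and a
combination class affects the union; aVR carries no class effect.  A
record is a sum of per-beat templates (Gaussian P and T waves, triangular
QRS) with lead-dependent amplitude scaling, plus the class signature: an
NSTEMI-like ST-segment *depression* of `st_shift_mv` (default 0.15 mV)
over the 80 ms window after each QRS offset on territory leads, and
T-wave inversion on each territory lead with probability 0.5.  Nuisance
terms are baseline wander (0.05 mV at 0.2–0.5 Hz) and white noise
(0.02 mV); heart rate is uniform in 55–95 bpm per record.  Records are
pure functions of `(label, config, seed)`; dataset generation derives
per-record seeds as `master_seed + index`.

What the generator does **not** emulate: torso/dipole physics, rhythm
disorders, morphology variability across patients (axis, bundle-branch
patterns), electrode noise bursts, or any overlap between class
signatures — territories are disjoint by construction, so the synthetic
task is *separable* in a way the clinical task is not.  A
territory-ST rule classifier recovers the true label on essentially all
records at default noise.  Passing tests therefore demonstrate that the
pipeline can find and exploit a planted, physiologically plausible ST
signal; they say nothing about clinical performance.

Amplitudes, wave widths and the 10 s duration are package choices; the
underlying cohort's signal statistics are not published.

## Numerical and design choices

* **dB rendering.** `20·log10(|X| + 1e-12)`.  The rendered image scales
  the window `[peak − 80 dB, peak]` to [0, 1] rather than min–max over the
  full range: the per-image minimum of an ε-floored dB matrix is a random
  noise notch (measured −84…−110 dB across records), so full-range
  normalization rescales every pixel by an artifact.  An 80 dB display
  range is the common spectrogram display convention.  The rendering is
  invariant to constant dB shifts; a constant matrix (silence) maps to the
  colormap's low end.  Resizing is anti-aliased bilinear — when shrinking
  ~1000 STFT frames to 64 columns, each output pixel must be a local
  average, not a single arbitrary frame, or the image encodes beat-phase
  jitter instead of signal content.
* **Hop.** The overlap of successive windows is unspecified upstream;
  hop = window/2 (50% overlap) is the default, configurable.
* **Input size.** 64 is the default; 100 is reachable via configuration
  (both sizes appear in the source material's description of the model).
* **Operation order.** BatchNorm is applied *after* GeLU, and the residual
  connection wraps only the depthwise stage, exactly as the model is
  printed.  A consequence: zeroing the depthwise kernel and neutralizing
  its BatchNorm reduces that stage to the identity, but the pointwise
  stage has no residual path and cannot be reduced this way.
* **Training.** SGD with momentum 0.9, initial learning rate 0.001,
  cross-entropy, plus L2 weight decay 1e-4 on convolution and fully
  connected weight matrices (the default of the reference SGDM trainer;
  biases and BatchNorm parameters are not decayed).  All arithmetic is
  float64; analytic gradients are validated against central differences to
  better than 1e-4 relative error.
* **Precise BN.** With small minibatches, momentum-averaged BatchNorm
  running statistics sit far from the statistics the weights were trained
  under.  After training (and before each validation evaluation) the
  running statistics are recomputed from full passes over the training
  data, combining batch moments as `var = E[var_b] + Var[mu_b]`.
* **Model width.** `hidden` defaults to 32 and the desk-scale preset uses
  16; the reference configuration's 750 channels are available via
  `model.hidden: 750`.  The reference description of depth and memory
  footprint is internally inconsistent (148 vs 81 layers; 158 KB is
  impossible at H = 750 in 32-bit parameters), so no "paper-faithful"
  preset is claimed; `depth` defaults to 4.
* **Feature tap.** The upstream description names the feature layer
  inconsistently (fc1 vs fc4); this package exposes a single named linear
  embedding `fc_embed` of width `embed_dim` (default 1000), un-activated,
  so features are unconstrained pre-softmax activations.
* **ReliefF variant.** The classical multi-class formulation with
  exponential rank weighting — the stated parameters (k, sigma, empirical
  priors) are exactly that variant's knobs.  m = n anchors keeps it
  deterministic.  Zero-range features receive weight 0; classes with fewer
  than k+1 members use all available neighbors; neighbor ties break by
  sample index.
* **WSSE votes.** Continuous vote mass (per-subspace ReliefF weight sum,
  floored at 0) is the default because it uses the computed weights
  directly; the replication mode is the alternative reading.  k = 10
  subspaces of 100 features each at p = 1000 is a package default, not an
  upstream value.
* **Folds.** Stratification keeps all 7 classes in every fold; plans are
  seeded and deterministic.  Metrics are one-vs-rest per class
  (sensitivity, specificity, precision, F-score) with pooled accuracy
  trace/total; division by zero yields 0 with a flag.
* **Desk-scale preset.** 35 records/class (245 records), hidden 16,
  depth 2, 10 epochs, minibatch 8, 3 folds.  The small minibatch matters:
  an epoch is only ~150 training samples, and batch 8 yields a few hundred
  SGD updates within the 10-epoch budget where the reference batch of 128
  would yield ~20 — too few to train from scratch.  Per-fold CV training
  uses the whole training fold (no inner validation split); the inner
  split and validation frequency exist for standalone training curves.
* **Seeding.** One master seed; per-stage seeds are derived by CRC-hashing
  the stage name, so any stage can be reproduced in isolation.

## Known limitations

* The synthetic task is separable by construction; accuracy numbers on it
  do not transfer to clinical data.
* T-wave inversion is nearly invisible to a magnitude STFT (|FFT(−x)| =
  |FFT(x)| within a frame), so the learnable class signal is carried
  almost entirely by the ST-level shift.
* Determinism of training is a same-platform contract: results are exact
  functions of the seed on a fixed BLAS/OS stack, not across stacks.
* The ConvMixer is a NumPy implementation designed for desk-scale
  experiments; it is CPU-bound and not intended for the full-width
  (H = 750) configuration on large cohorts.
* Confidence intervals for metrics are out of scope, as is any comparison
  against pretrained image classifiers.
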