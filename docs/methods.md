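# Methods

## Problem and model

Scalp EEG (sEEG) is attenuated by the skull and contaminated by artifacts;
intracranial EEG (iEEG) from foramen-ovale (FO) electrodes records interictal
epileptiform discharges (IEDs) almost cleanly, but requires an invasive
procedure. Historically only ~9–22% of iEEG-annotated IEDs are discernible on
the scalp. This package learns a mapping from simultaneous sEEG to iEEG so
that IED detection can run on the *estimated* intracranial signal.

Data are 64-sample, 12-channel segments at 200 Hz: X ∈ ℝ^{64×12} is a scalp
segment (12 fronto-temporal electrodes: Fp1, F3, F7, C3, T3, Fp2, F4, F8, C4,
T4, Fz, Cz), Y ∈ ℝ^{64×12} the simultaneous FO segment. A conditional GAN is
trained on pairs (X, Y):

* generator G: 1-D U-net over the time axis. Contracting path: per level one
  kernel-5 convolution → per-channel time normalization → ReLU → stride-2
  average pooling, feature widths 16, 32, 64; a kernel-5 bottleneck
  convolution (128 features at time length 8); expansive path: bilinear 2×
  upsampling → 1×1 feature-halving convolution → skip concatenation → two
  kernel-5 convolutions → time normalization; head: 1×1 convolution and a
  time-distributed dense map to 12 outputs per time step.
* discriminator D: scores the channel concatenation (X, Y) vs (X, G(X)) — a
  64×24 input — through three kernel-5 convolution blocks (widths 32, 64, 128),
  each ReLU → dropout(0.25) → stride-2 max pooling, then one dense sigmoid unit.
* objective: min_G max_D E[log D(X,Y)] + E[log(1 − D(X,G(X)))], with the
  generator loss regularized by λ·E‖Y − G(X)‖₂ (the Euclidean norm, not its
  square; a squared variant is config-exposed), λ = 100 by default.

The detector is a modified EEGNet (F1 = 8 temporal filters, depth multiplier
D = 2, F2 = 16 separable filters, temporal kernel 32 = half the segment
length): every batch-normalization stage is removed and every pooling stage is
max pooling. It maps a 64×12 segment to an IED probability; the decision
threshold is 0.5 (balanced classes make this canonical).

Total trainable parameters of the reference GAN: 204,157 (generator 147,868 +
discriminator 56,289), within the 0.25 × 10⁶ budget and ≥12× smaller than the
3.12 × 10⁶-parameter autoencoder comparator it is measured against.

## Preprocessing

Both modalities: zero-phase 4th-order Butterworth band-pass 1–70 Hz and a
zero-phase quality-30 IIR notch at 50 Hz (filter family unstated in the
source conventions; zero-phase preserves spike latency, on which peak-centred
segmentation depends). Scalp only: common average reference over all
available electrodes, then reduction to the 12 matched channels. The iEEG is
never re-referenced.

Segmentation: one IED window per annotated peak p, the half-open
[p − 32, p + 32) — "32 before and after" is read as a 64-sample total, since
the model consumes ℝ^{64×12} (the 65-sample inclusive reading is rejected).
Non-IED windows are drawn non-overlapping from stretches farther than a
64-sample guard interval from every peak (the guard width is our choice; it
guarantees zero overlap with any IED window). Class counts are equalized by
seeded random subsampling of the majority class.

## Evaluation protocols

* Intra-subject: stratified 70/10/20 train/validation/test split of a
  subject's balanced segments; one translator trained on the training part;
  all parts mapped through it; one detector trained on the translated
  train/validation parts (best-validation-accuracy checkpoint retained);
  ACC/SEN/SPC on the translated test part. No test labels reach any fitting
  step.
* Inter-subject: leave-one-subject-out. Training subjects are those with
  intra-subject accuracy ≥ 0.70 (the threshold formalizes "detected with high
  accuracy"; configurable). One translator G_n per training subject; each G_n
  maps every training subject's and the held-out subject's segments; one
  detector per G_n trained on that translator's pooled translated training
  data (the pooled-per-translator reading of the parallel-branch design);
  the N detectors' probabilities on the held-out subject are averaged
  (average voting) and thresholded at 0.5. Per-subject reports plus their
  unweighted mean.

## Training and numerical choices

Translator: alternating per-batch updates — one discriminator ascent step on
the adversarial value, one generator descent step on the combined objective.
The literal minimax generator update saturates when D wins early; the default
is the non-saturating heuristic (maximize log D on fakes), which shares the
minimax fixed points; the verbatim minimax mode is config-selectable.
Probabilities are clamped at 1e-7 inside logarithms; the norm in the L2 term
is guarded by 1e-12 under the square root. Segments are standardized per
channel with training-set statistics before entering either network; the
inverse transform is applied to G(X) so translated output and reported µV L2
are on the physical scale.

Optimizers: Adam. The translator uses lr 1e-3 with β₁ = 0.5 — the reduced
first-moment decay standard for adversarial training; at the short training
budgets this package targets (tens of epochs on a few hundred segments),
lr 2e-4 demonstrably under-converges. The detector uses plain Adam defaults
(lr 1e-3, β₁ = 0.9). Batch size 32, default 30 epochs for both networks.
Models and activations run in float32; gradients are verified against
float64 central finite differences in the test suite. All training is a pure
function of (data, config, seed): parameter initialization, batch order and
dropout each draw from independent child streams of a single seed sequence,
and runs are single-threaded.

The networks are implemented on a compact reverse-mode autodiff engine over
numpy written in-package (`iedgan.nn`), sized exactly to these models
(grouped 1-D convolution, pooling, bilinear upsampling, time normalization,
dropout, dense heads).

## Synthetic cohorts

The simulator emulates the clinical recording setting — 18 subjects by
default, 200 Hz, 20 scalp + 12 FO channels, 50–953 IEDs per subject (drawn
uniformly unless fixed) — with a deliberately simple forward model:

* IED template: a sharp spike (55–85 ms, seeded sharpness/asymmetry jitter)
  followed by a slow wave (300–400 ms, 0.35–0.5 relative amplitude); source
  amplitude 300 µV with lognormal (σ = 0.2) event-to-event variation.
* Source-to-sensor model: per subject a fixed non-negative, unit-norm,
  concentrated weight vector over the 12 FO contacts (contacts near the
  source dominate); the scalp sees the same source train through a fixed
  contact-to-scalp mixing matrix (spatial bumps around fronto-temporal anchor
  points in schematic 10-20 geometry) scaled by a skull attenuation scalar
  (default 0.45).
* Visibility: a configurable fraction of events (default 0.15, matching the
  9–22% clinical range) keeps the full scalp gain; the rest are suppressed by
  a further factor 0.15, putting them below the scalp noise floor. The peak
  annotations list every event — the iEEG is the annotation ground truth.
* Background: 1/f^α colored noise (α = 1), scalp RMS 1.4× the intracranial
  RMS; intracranial SNR set by `ieeg_snr_db` (default 26 dB re. the mean
  projected source amplitude); a 10 Hz posterior rhythm with a slow envelope
  and Poisson eye-blink-like frontal transients (default 3/min) on the scalp
  only. With these defaults the measured fraction of events whose scalp
  event-window SNR exceeds 1 converges to the configured visibility fraction,
  and every event's intracranial SNR exceeds its scalp SNR.
* Placement: uniform random onsets with ≥1 s refractory gap and a 2.5 s edge
  margin, so a 64-sample window always fits and windows never truncate.

Events, weights and each noise source draw from independent child streams of
`SeedSequence([seed, subject_index])`, so a `noise_scale=0` twin run
reproduces the identical event structure noise-free; tests use that twin as
an analytic oracle (e.g. scalp = attenuation × mixed iEEG exactly).

What the simulator does *not* model: biophysical head geometry (no BEM/FEM
lead fields), poly-spike morphologies, state-dependent background
(sleep/wake), correlated inter-channel noise, electrode drift. Passing the
synthetic benchmarks therefore shows that the pipeline recovers a linear,
stationary source-mixing regime with realistic SNR ordering — not that it
reaches any particular accuracy on clinical recordings.

## Benchmark problem sizes

The standard benchmark cohort is 6 subjects, 300 s each, 200 IEDs per
subject, visibility 0.15, with both networks trained for 30 epochs; the
inter-subject benchmark uses 4 such subjects at 10 epochs. These sizes keep a
full run in minutes on one CPU core while leaving the translated-vs-raw
contrast far from the decision boundary (cohort-mean held-out accuracy ≈ 0.90
translated vs ≈ 0.74 raw scalp; translated correlation ≈ 0.35 vs ≈ 0.10
baseline).

## Known limitations

* The exact layer counts of the original generator/discriminator figures are
  not recoverable from text; the implemented widths/depths are constrained by
  the published 0.25 × 10⁶ parameter total and are config-exposed.
* Whether the L2 regularizer intends the norm or its square is ambiguous in
  print; the norm is the default, the square a config option.
* Inter-subject detector training data (per-translator pooled vs per-subject)
  is ambiguous in the source description; the pooled-per-translator reading
  is implemented.
* EDF export writes plain EDF (not EDF+) with one-second records and 16-bit
  quantization against symmetric per-channel physical ranges; annotations
  travel in a CSV sidecar rather than EDF+ TAL blocks.
* Simulated subjects differ only in source weights, event schedules and noise
  draws — they share the contact-to-scalp mixing geometry. Cross-subject
  domain shift is therefore milder than in clinical cohorts: with pooled LOSO
  training data, inter-subject accuracy can match or slightly exceed the
  intra-subject figure on synthetic cohorts, unlike the ordering reported for
  real patients. Conclusions about inter-subject generalization on clinical
  data should not be drawn from the synthetic benchmark.
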