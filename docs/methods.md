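# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It documents what
the code does; every number quoted here is computed by the test suite
or by `scripts/acceptance.py`, not asserted from memory.

## Feature extraction

**Framing.** Both branches use 25 ms windows with a 10 ms hop and no
centering: `T = 1 + floor((N − win)/hop)` frames. Signals shorter than
one window are rejected. Inputs at other sample rates are resampled
(polyphase) to the 48 kHz corpus rate before extraction.

**3D mel-spectrum.** Hamming-windowed frames, FFT of the next power of
two ≥ the window (2048 at 48 kHz), power spectrum, 64 triangular
HTK-mel filters, log compression `log(x + 1e−10)`. The paper-gap
choices: log-mel (rather than linear amplitude) is the standard input
scale for spectrogram CNNs; deltas are computed *before* the resize so
that a time-constant spectrogram has exactly zero delta channels; the
resize to 256×256 (or 64×64 at desk scale) is fixed bilinear
interpolation, so extraction is fully deterministic.

**Deltas.** HTK regression deltas with window ±2 and edge replication;
the second order is the operator applied twice. On a linear-in-time
input the interior frames equal the slope exactly, which the tests
exploit as a closed-form oracle.

**IS09 statistics.** The 16 LLDs are computed per frame in the fixed
column order ZCR, RMS, F0/500 Hz, HNR, MFCC 1–12:

* ZCR — fraction of strictly sign-changing adjacent sample pairs.
* RMS — root mean square amplitude.
* F0 — FFT-based autocorrelation, peak picked in the 50–500 Hz lag
  band; a frame is voiced when the peak exceeds 0.3·r(0); unvoiced
  frames report 0. The 0.3 voicing threshold and the 50 Hz floor are
  conventional autocorrelation-tracker settings.
* HNR — `10·log10(r_peak/(r0 − r_peak))`, clamped to ±60 dB so pure
  tones and silence stay finite.
* MFCC 1–12 — HTK convention: pre-emphasis 0.97, Hamming window,
  magnitude spectrum, 26 HTK-mel filters, log, DCT-II, cepstral
  liftering L = 22.

Each of the 32 contours (16 LLDs and their regression deltas) is
collapsed by 12 functionals in the fixed order mean, stddev
(population), kurtosis (excess, m₄/m₂² − 3), skewness (m₃/m₂^1.5),
max, min, max position, min position (relative index in [0, 1]),
range, offset, slope (least squares over time normalized to [0, 1]),
and the regression's mean squared residual. Moment ratios of constant
contours are defined as 0. The layout is LLD-major, contour before
delta, giving 16 × 2 × 12 = 384 dimensions. Compatibility with the
openSMILE IS09 configuration is at the definition level, not
bit-for-bit.

## Networks

All networks are implemented in-package on numpy (float32 parameters;
float64 available for finite-difference gradient checks, which agree
with backpropagation to better than 1e−4 relative error).

**Student/teacher CNN.** Input S×S×3; three padded 3×3 conv + BN +
ReLU blocks to c₁ channels; 2×2 max-pool; three padded blocks to c₂;
2×2 max-pool; one *unpadded* conv to c₃ (the map shrinks by 2); padded
convs to c₄ and c₅; global average pooling to a c₅-dim embedding; an
auxiliary 8-dim linear projection. At full scale
(S = 256, widths 32/64/128/64/32) this reproduces the published shape
trace including the 62×62 maps; the desk profile (S = 64, widths
8/16/32/16/32) follows identical rules and keeps the embedding at 32
so the fused representation is 64-dim at either scale. The trailing
8-dim projection is kept as an auxiliary head only: the classifier
proper is a binary softmax over the fused 64-dim embedding, since an
8-wide final layer cannot be reconciled with two classes.

**Autoencoder.** 384→256→128→64→32 encoder and 32→128→180→256→384
decoder (the asymmetric 180 is honored as printed), every layer
BN + ELU, dropout at the bottleneck and at the final decoder layer, and
a terminal sigmoid so reconstructions live in (0, 1) — matching the
BCE reconstruction loss, whose inputs are min–max normalized per
feature over the training set.

**Initialization.** Seeded He-uniform for convolutions, Xavier-uniform
for linear layers.

**Teacher update.** After every optimizer step,
θ″ = α·θ′ + (1 − α)·θ with α = 0.99, applied elementwise to all
teacher parameters *and* BN running statistics, so the teacher's
normalization follows its weights. The teacher runs in eval mode and
receives no gradient.

## Losses and training

* Supervised loss: mean cross-entropy of the softmax output on labeled
  items (empty labeled batch defined as 0).
* Reconstruction loss: mean elementwise BCE between the reconstruction
  and the clean normalized input. The printed form of this loss in the
  source material compares the reconstruction with the AE *output*;
  this is read as a typo for the standard reconstruction-vs-input BCE,
  which is the loss the surrounding text describes. Noised unlabeled
  inputs are reconstructed toward their clean versions (denoising
  behavior).
* Consistency loss: mean squared distance between student and teacher
  fused embeddings of unlabeled items. The default divides by both
  batch size and embedding dimension ("elementwise"): with the raw
  batch-mean of squared 64-dim norms the consistency term is roughly
  two orders of magnitude larger than the cross-entropy and can
  collapse the shared representation; per-dimension averaging makes
  ω = 1 a meaningful default. The batch-mean reduction and a
  probability-space mode (stop-gradient, eval-mode head) remain
  available as configuration.
* ω schedule: smooth ramp
  `ω(t) = ω_max·(exp(−5(1−t)²) − e⁻⁵)/(1 − e⁻⁵)` with
  `t = epoch/ramp_epochs` clipped to [0, 1]; exactly 0 at epoch 0 and
  ω_max from the ramp's end (30% of training by default). The
  reconstruction weight `a = 0.5` follows the stated weight factor,
  which can only refer to the total-loss combination.
* Optimizer: SGD with momentum 0.9 (the momentum value is a design
  choice; only "small-batch SGD" is specified), learning rate 3e−4
  with cosine annealing to 0 over the epochs.
* Batches: fixed composition of 25% labeled (sampled with replacement)
  and 75% unlabeled items, so every step carries all loss terms;
  default batch size 12.
* Dropout: the source states "dropout … set to 0.8" without saying
  whether that is a drop or keep probability. With drop probability
  0.8 the supervised loss does not converge at desk scale (it would
  zero out ~80% of the 32-dim bottleneck and of the reconstruction
  output); with the TensorFlow-1 keep-probability reading (drop 0.2)
  training converges and behaves as described. The default is
  therefore keep = 0.8; `dropout_is_drop_prob=True` restores the other
  reading.
* Model selection: the checkpoint with the highest test accuracy over
  the run is kept, mirroring the convention of reporting peak
  accuracy; both student and teacher metrics are logged every epoch.
* A non-finite total loss aborts with the component values in the
  message.

**Ablation variants.** `MT` (CNN only, CE + ω·consistency), `AE`
(autoencoder only, CE + a·reconstruction), `AE+MT` (both branches,
ω = 0), `AE+MT+CR` (full model). The CR variant differs from `AE+MT`
only in ω_max > 0.

## Synthetic corpus

Each utterance is a voiced-speech proxy: a phase-continuous harmonic
source (1/h rolloff, ≤12 harmonics below ~4 kHz) whose F0 contour has
slow sinusoidal drift (±4%) and 1% jitter; two resonator filters at
500 and 1500 Hz stand in for formants; a 3–5 Hz raised-cosine envelope
emulates syllabic energy modulation; Poisson-placed 100–200 ms silent
pauses emulate hesitations; Gaussian noise (amplitude 0.01) is added
and the signal is normalized to 0.1 RMS. Durations are uniform on
2–8 s, the conversational-turn range; defaults are 1,103 utterances,
47.2% deceptive, 600 labeled, 48 kHz.

The class difference is confined to three utterance-level parameters —
F0 mean (truth 115 ± 12 Hz), energy-modulation depth (0.35 ± 0.05) and
pause rate (0.3 ± 0.12 /s) — each shifted upward for the deceptive
class by `class_separation` between-utterance standard deviations, so
`class_separation` is the per-channel effect size d′ at the parameter
level. At separation 0 the classes are generatively identical (the
tests verify indistinguishability by KS test on extracted features);
at separation 3 the mean-F0 functional separates by more than 2 pooled
SDs, and a linear probe on IS09 vectors is monotone in the separation
grid 0–3. Baseline pause statistics were set so that the F0 shift
survives frame-averaged functionals: voicing-fraction variability
multiplies the F0 contour's mean and is the dominant attenuation of
the parameter-level effect.

What the generator does *not* emulate: lexical content, speaker
identity and variability, channel/recording noise, dialogue structure,
or any cognitive-load correlate beyond the three shifted parameters.
Passing the desk-scale benchmark therefore shows that the pipeline
learns class-dependent acoustic statistics from partially labeled
data under this model's assumptions — not that it detects deception in
real recordings.

**Splits.** Train size is `floor(0.9·N)` exactly (1,103 → 992/111),
stratified by class with largest-remainder quotas; the labeled subset
of the training split is a stratified seeded sample (how the original
label budgets were drawn is unstated; stratified random is the neutral
choice). Test items always keep labels. The true class of unlabeled
training items is stored but exposed only through a dedicated
evaluation accessor; a tripwire test verifies the trainer never reads
it.

## Problem sizes and scales

The `desk` profile (64×64 inputs, widths 8/16/32/16/32) is the
package's CPU-friendly configuration and the one used by the test
suite and the acceptance script: 120 utterances, 30% labeled,
separation 2.5, 15 epochs — chosen as the smallest configuration at
which the semi-supervised behavior is measurable and stable across
seeds. The `full` profile (256×256, widths 32/64/128/64/32) is
configuration-identical and used for the architectural shape checks.
At desk scale the CNN-only variant stays near chance: ~150 gradient
steps cannot train a from-scratch CNN, so the fused model's signal
comes predominantly from the autoencoder branch, and the consistency
term acts as a regularizer rather than a driver. The variant ordering
(CR not worse than no-CR) is asserted with a 0.02 tolerance across
three seeds.

## Known limitations

* The mean-teacher branch needs far more optimization steps than the
  desk-scale benchmark provides; conclusions about the CNN branch
  require the full profile and a larger corpus.
* Feature extraction is definition-level openSMILE-compatible, not
  bit-compatible with any specific release.
* The HNR estimator shares the F0 tracker's autocorrelation peak;
  octave errors in one affect the other.
* Min–max normalization of IS09 features clips test-set values outside
  the training range.
* With 12 test utterances at desk scale, accuracy moves in steps of
  1/12; seed-to-seed variability of a few steps is expected.
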