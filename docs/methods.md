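# Methods

## Problem setting

Multiclass motor-imagery decoding from epoched scalp EEG: trials of
`N` channels × `T` samples with one of `M` imagery labels.  The
package targets small-sample regimes (tens of trials per class) and
recording conditions with varying SNR (wet vs dry electrodes), where no
single input representation is reliably best.  The design bet is that
three complementary representations of the same trial — raw time
series, variance-optimized spatial components, and instantaneous
phase — let a classifier weight whichever domain survives the noise of
a given subject or electrode type.

## Input domains

**Preprocessing.** A fourth-order zero-phase Butterworth IIR bandpass
(4–40 Hz by default; a 38 Hz lowpass suits the four-class public
benchmark) applied forward–backward (`sosfiltfilt`), an optional 60 Hz
notch (second-order IIR, Q = 30), then polyphase downsampling to
250 Hz.  "Fourth order" names the design order; the forward–backward
magnitude response is eighth order.  Order of operations: notch →
bandpass → downsample → domain transforms.

**Spatial domain (multiclass CSP).** Per trial, covariance is estimated
as `X Xᵀ / tr(X Xᵀ)` (trace normalization removes per-trial gain) and
averaged within class.  The average covariance (class-prior weighted) is
eigendecomposed to whiten; the whitened class covariances are then
jointly approximately diagonalized by Jacobi sweeps over index pairs,
each rotation angle minimizing the summed off-diagonal energy of the
2×2 subproblem across all classes (Cardoso–Souloumiac).  The composed
filters (rows of `W`) are ranked by the mutual-information
approximation `I ≈ −Σᵢ P(cᵢ) log vⱼᵢ − (3/16)(Σᵢ P(cᵢ)(vⱼᵢ² − 1))²`
with `vⱼᵢ = wⱼᵀ R_{cᵢ} wⱼ` (whitened variances, `Σᵢ P(cᵢ) vⱼᵢ = 1`).
A variant using `log √v` (halving the entropy term) exists behind
`log_sqrt=True`; it reorders nothing in practice because it is a
monotone rescaling of the first term only, but both forms are kept
because the literature is split.  By default all `L = N` filters are
retained — the spatial tensor keeps the input shape and no dimension
reduction occurs; ranking still controls filter order.  For M = 2 the
procedure reproduces classical CSP (generalized eigenvectors) to
machine precision, which the tests assert.  CSP is always fitted per
cross-validation fold on training trials only.

**Phase domain.** The analytic signal is built in the frequency domain
(zero negative frequencies, double positive ones — exact for the
discrete signal, O(T log T)); phase is the four-quadrant arctangent of
(ŝ, s), wrapped to (−π, π], with no unwrapping, padding or tapering —
the classifier sees edge-distorted phase as raw input.  The O(T²)
parity-split direct summation `ŝ(k) = (2/π) Σ_{k−n odd} s(n)/(k−n)` is
retained as an independent oracle: on band-limited signals the two
constructions agree within 0.1 rad on ≥95 % of interior samples (a
property test); on broadband 1/f input the truncated sum converges too
slowly for that bound, which is why the oracle is stated for
band-limited signals.

**Normalization.** Per-channel z-scoring per domain, statistics fitted
on the training fold only and frozen for test trials (the leakage-free
reading of "normalize each domain"); zero-variance channels clamp the
scale to 1e-12 with a logged warning.

## Cropped training

Domain transforms are applied to the full trial first and cropped
afterwards, so all crops of a trial share one spatial projection and
one analytic signal (and the transform cost is paid once, not per
crop).  Crops are 4-s windows every 0.1 s (11 per 5-s trial); offsets
round to whole samples, exactly at the standard rates.  Per-trial
predictions average the softmax rows of a trial's crops and take the
argmax (ties break to the lowest class index); per-crop scoring exists
behind a flag.

## Network

Per branch: temporal convolution (40 kernels, 1×25, valid) → spatial
convolution (40 kernels, N×1, mixing temporal maps and channels) →
batch normalization (momentum 0.1, ε 1e-5) → square → average pooling
(1×75, stride 1×15) → log(max(x, 1e-6)) → dropout 0.5 → FC to D = 40
features → softmax head of size M.  The square–pool–log stack makes
each branch a learned log-band-power detector.  The three D-vectors
concatenate into a final FC softmax ("multi") head.  For a 31×1000
input the post-convolution map is 40×1×976 and the pooled length is
⌊(976−75)/15⌋+1 = 61.  The two convolutions are composed into one
per-(output-map, channel) kernel and evaluated in the FFT domain, with
hand-derived gradients (finite-difference-checked); compute is float32
by default, float64 for gradient checking.  Weight init is Glorot
uniform; a seed fixes init, shuffling and dropout, making training
bit-reproducible.

Training: joint loss `Σ_h λ_h · CE_h` over the four heads (default
λ = (1,1,1,1) — every head trained, relative weighting even), Adam
(lr 1e-3, β 0.9/0.999), mini-batches of 32, 100 epochs at full scale,
LR × 0.5 after 10 stale epochs, and a maxnorm projection after every
step (radius 2.0 per convolutional filter/row, 0.5 per FC row; the
radii are config-exposed since the literature states none).  The
returned weights are the checkpoint with the lowest monitored loss.
Two monitoring protocols exist: `monitor_test_loss` (checkpoint on the
evaluation crops — the historical protocol for this architecture, which
leaks test information into model selection) and `monitor_val_loss`
(inner stratified trial-level split of the training crops, leakage-
free).  The default is `monitor_test_loss` for comparability; both are
recorded in the history.

Disabling two branches (`branches=("time",)`) reduces the model to a
standalone single-domain ShallowConvNet-style classifier.

## Evaluation

Stratified k-fold (default 10): per-class counts per fold differ by at
most one, and remainder trials are dealt to the currently smallest
folds so total fold sizes also differ by at most one.  Significance is
judged against the binomial chance-level upper confidence limit
`100·⌈n p₀ + z_{1−α/2} √(n p₀ (1−p₀))⌉ / n` (exact-binomial variant
behind a flag): 43.33 % for n = 90, M = 3; 30.21 % for n = 288, M = 4.
Paired comparisons use the paired t-test plus Cohen's d with pooled SD
of the two samples (paired-differences d behind a flag).

## Synthetic sessions

The generator emulates a three-class lower-limb imagery session: 31
channels (10-20 montage) at 500 Hz, 30 five-second trials per class.
Class signatures are amplitude-modulated (Hann envelope) band-limited
noise — random phase per trial — on motor-area channels: gait 11 Hz on
Cz/C1, sit 23 Hz on Cz/C2, rest 9 Hz on C3/C4, 6 µV each, all inside
the 4–40 Hz analysis band.  Background is spatially independent
1/f^α noise (α = 1), RMS 5 µV for the wet preset; the dry preset
multiplies background RMS by 3 while class signals stay identical —
emulating the lower SNR of gel-free electrodes as a pure noise-level
contrast.  Amplitudes were chosen so the planted effect is
unambiguous (band-power t-test at a signature channel separates
classes at p ≪ 0.01 over 30 trials).  Not emulated: volume conduction
(optional random mixing exists for CSP stress tests), EOG/EMG
artifacts, inter-subject variability, non-stationarity.  Passing
pipeline tests on this data therefore demonstrates correctness of the
machinery and recoverability of planted structure — not expected
accuracy on real recordings.

## Reduced-scale study conditions

Cross-validated network runs in the test suite use a reduced scale
sized for a single CPU: downsampling to 125 Hz (all signatures are
below 40 Hz, so nothing is lost), crop step 0.5 s (3 crops per 5-s
trial), 20 temporal/spatial filters, D = 20, 20 training epochs.  At
these settings a 10-fold CV of the full pipeline takes about two
minutes.  The fusion-behaviour check uses a session whose classes
share one band (15 ± 3 Hz, 5 µV, dry background) and differ only in
which motor channel carries it: there the phase head sits at chance
while time/spatial heads learn, and the fused head is asserted to stay
within 5 points of the best single head.

## Numerical choices and degenerate inputs

- Crop counting uses `⌊(trial − window)/step + 1e-9⌋ + 1`; the epsilon
  absorbs float division error (e.g. (5−4)/0.1).
- `log` activation clamps at 1e-6, so zero-variance crops yield finite
  activations and gradients (gradient is zeroed in the clamped region).
- Singular average covariances raise an error advising the ridge
  option (`fit_jad(..., ridge=...)`) rather than silently regularizing.
- Equal MI scores tie-break by original filter index (stable sort).
- `arctan2(0, 0) = 0`, so an all-zero signal has zero phase; the exact
  −π phase value is folded to +π to keep phases in (−π, π].
- Epoch windows are half-open `[cue + t_start, cue + t_end)` with
  0-based sample indices; lengths are `round((t_end − t_start)·fs)`.

## Known limitations

- The direct Hilbert summation is edge-truncated and O(T²); it is an
  oracle, not the production path.
- The 50 Hz stopband attenuation of the default bandpass is 7.1 %
  (amplitude) by the analytic forward–backward response — strong, but
  not arbitrarily small; applications needing deeper line-noise
  rejection should add the notch stage.
- GDF files are read through `mne` but the reader is exercised only on
  error paths in the test suite, since no GDF writer is available to
  build a fixture; BrainVision and EDF round-trips are fully tested.
- `monitor_test_loss` checkpointing leaks evaluation data into model
  selection; use `monitor_val_loss` for honest generalization
  estimates.
- Training is CPU-bound numpy; full-scale (40 filters, 250 Hz, 11
  crops/trial, 100 epochs, 10 folds) is hours, not minutes.
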