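# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `eegtfdx`, and what the synthetic-data tests
do and do not establish about real recordings.

## Pipeline model

Each EEG channel is treated as an independent realisation `x(t)` of a
non-stationary oscillatory process. The diagnostic chain is

    band-pass → decimate → segment → time-frequency transform
    → image rendering → CNN classification → 5-fold CV metrics

with one image per channel per subject, so a cohort of `S` subjects with
`C` channels yields `S × C` classifier examples (39 × 64 = 2496 at the
default cohort shape). Classification is binary with migraine (MD) as the
positive class; accuracy, sensitivity and specificity are the usual
confusion-matrix ratios × 100, fold-averaged arithmetically.

## Preprocessing

* **Filter**: 0.5–40 Hz windowed-sinc (Hamming) FIR, default 513 taps at
  512 Hz (≈1 s). Taps are symmetric, hence exactly linear-phase. The raw
  design leaves a few percent of DC leakage because the 0.5 Hz low edge is
  narrower than the achievable transition band at this length; the tap
  mean is subtracted, which nulls DC exactly, preserves symmetry and
  perturbs the passband by < 0.1 dB. Measured response: −0.004 dB at
  10 Hz, −2.3 dB at 1 Hz, −68 dB at 50 Hz.
* **Application**: zero phase is obtained by reflect-padding each channel
  by half the filter length and convolving in valid mode, i.e. the
  (n_taps−1)/2 group delay is compensated by shift rather than by
  forward–backward filtering, so the designed magnitude response applies
  unmodified. Edges carry the usual padding transient of ~half a filter
  length.
* **Decimation**: keep every second sample starting at index 0
  (512 → 256 Hz). No second anti-alias filter: the 40 Hz cutoff already
  bounds content at less than a third of the new Nyquist frequency.
* **Segmentation**: the first `duration` seconds of every channel
  (default: the whole recording, 10 s in the synthetic cohorts). Fixed
  length makes image geometry deterministic.

## Time-frequency transforms

* **Scalogram** (CWT): computed per scale in the frequency domain,
  `|ifft(fft(x) · √a · Ψ(aω))|`, zero-padded to the next power of two at
  least twice the signal length so the implied convolution is effectively
  linear. The bump wavelet `Ψ(ω) = exp(1 − 1/(1 − ((ω−μ)/σ)²))` on
  `|ω − μ| < σ` uses μ = 5 rad/sample, σ = 0.6 — the conventional
  defaults for this wavelet — giving centre frequency `f = μ·fs/(2πa)`.
  The scale grid is geometric, 12 voices per octave over 1–40 Hz. Edge
  effects are not masked (no cone-of-influence trimming); the classifier
  sees the full time plane. Magnitude (not power) is stored.
* **Spectrogram** (STFT): equal-length windows (default Hann, 1 s, 50%
  overlap — a COLA-valid combination), frames starting at sample 0,
  one-sided power `|X(t, f)|²` on the uniform grid 0…fs/2. A rectangular
  window is available for energy-accounting checks.
* Both transforms were validated against brute-force oracles: direct
  time-domain integration of the wavelet integral (wavelet recovered from
  its frequency bump by quadrature) and naive per-frame DFT sums. Ridge
  agreement is exact to one scale step / one bin on probe tones at 4, 6,
  10, 20 and 35 Hz; at-ridge coefficient agreement is ~0.1%.

## Image rendering

Each matrix is min–max normalised per image — after `log10(v + 1e−12)`
for scalograms (visual dynamic-range convention), linearly for
spectrograms — mapped through a fixed 256-entry lookup table with control
points blue → cyan → yellow → red at positions 0, ⅓, ⅔, 1, flipped so
frequency increases upward, and resampled to the target side by bilinear
interpolation. No axes, ticks or margins are drawn: decorations would
inject label-independent structure. Rendering is fully deterministic
(no RNG, no wall clock); re-runs produce bit-identical PNG bytes.

Per-image normalisation removes inter-subject amplitude scale and with it
any absolute-power class cue; the class signal must survive as *relative*
spectral shape. A `global_range` option normalises against a common range
instead when absolute power should be preserved.

## Classifiers

* **DCNN** (default, side 256): repeated blocks of 3×3 convolution →
  ReLU → 2×2/stride-2 max-pool (floor semantics), default three blocks
  with 8/16/32 filters, then a single fully connected layer to two
  logits and softmax. Cross-entropy loss.
* **Backbones**: AlexNet (input 227), ResNet50 (224), SqueezeNet 1.0
  (227) at their published topologies with two-way heads, randomly
  initialised (He) — the package bundles no pretrained weights, and
  `pretrained=True` raises rather than silently randomising.
* **Training**: Adam, defaults learning rate 1e−4, 12 epochs,
  mini-batches of 64, seeded shuffling; optional L2 weight decay
  (default 0, i.e. off). All layers are NumPy; training is bit-reproducible
  under a seed on a fixed BLAS. Prediction ties (exactly 0.5/0.5) resolve
  to HC, the negative class.

## Cross-validation design

Folds come from a seeded shuffle followed by contiguous chunking, sizes
differing by at most one (2496 items → 500/499/499/499/499). The library
default is image-level splitting, which mirrors the procedure the
headline literature numbers imply; note that image-level splitting lets
one subject's channels appear in both training and test folds and is
therefore optimistic whenever images carry subject-specific structure.
`groups=` (subject ids) assigns whole subjects to folds — the
leakage-free design — trading exact size balance for group integrity;
`stratify=True` additionally balances class counts.

The desk-scale (`--small`) profile and the acceptance runs use
subject-grouped, stratified folds: the null-calibration property (below)
is only interpretable without subject leakage.

## Synthetic cohort generator

Each channel is unit-variance Gaussian `1/f^β` noise (β = 1, synthesized
in the frequency domain), mixed with a single shared noise source at
weight 0.3 as a crude volume-conduction analog, plus deterministic
class-signature sinusoids with per-channel random phases:

| condition | components (Hz : amplitude) |
|---|---|
| R (rest) | 10 : 1.0, 6 : 0.4 |
| A (auditory) | 6 : 1.0, 10 : 0.6 |
| V (visual) | 4 : 1.0, 10 : 0.6 |

MD subjects have theta-band (4–8 Hz) component power multiplied and
alpha-band (8–12 Hz) power divided by `1 + class_separation × 0.5`; at
`class_separation = 0` the two class distributions are identical. SNR is
the per-channel ratio of summed sinusoid power to noise power, default
0 dB. Everything is reproducible from `(seed, subject_index, label)`.

The generator emulates the *statistical shape* of an interictal-migraine
cohort — group sizes, channel count, sampling rate, stimulus-entrainment
frequencies, a band-power group contrast. It does not emulate head-model
forward projection, artifacts (blinks, EMG), non-stationarity across the
recording, or the actual (unknown) migraine signature. Passing the
end-to-end tests therefore shows the pipeline *can recover a planted
band-power contrast through the full imaging-and-CNN chain and reports
chance when none exists*; it does not certify clinical accuracy on real
recordings, which additionally requires the external dataset and
backbone-scale training.

## Desk-scale profile and problem sizes

The `--small` profile keeps every stage's defaults except size: 10+10
subjects, 8 channels, 10 s recordings, side-64 images, the DCNN with its
standard 8/16/32 filter complement, 30 epochs of Adam at 3e−3 with
batches of 16. The filter widths matter: a thinned 4/8-filter variant
reaches 100% training accuracy but often overfits subject noise before
finding the band-power cue, while the standard complement recovers the
planted contrast reliably across seeds. A full 5-fold run takes about a
minute on one CPU.

## Null calibration and its interval

At `class_separation = 0`, mean CV accuracy should be consistent with
chance. With subject-grouped folds the independent unit is the subject —
a subject's 8 channel-images are strongly correlated (shared noise
source, shared label) and always share a fold — so the 95% binomial
interval around 50% is evaluated at n = 20 subjects (±21.9 percentage
points), not n = 160 images (±7.7). Observed null means across seeds
span roughly 40–52%, consistent with subject-level dispersion.

## Degenerate inputs and tie-breaks

Constant time-frequency matrices render as the colormap's zero colour
(no division by zero); zero signals give identically zero transforms;
metrics with zero denominators raise an explicit error rather than
returning 0; recordings containing NaN are refused at write and at
filter time; the grid runner records per-cell failures and continues,
never silently dropping a requested cell.

## Known limitations

* Backbone training at full image sizes is computationally impractical
  in pure NumPy; backbones are provided at contract fidelity (topology,
  input sides, deterministic init, forward/backward) and exercised at
  construction/prediction scale in the tests.
* EDF/BDF writing quantises to the container's 16/24-bit grid
  (round-trip error ≤ range/2¹⁵ and ≤ range/2²⁰ respectively) and
  requires integer-second recordings (1 s data records).
* The channel-correlation model (one shared source) is far simpler than
  real volume conduction; grouped CV keeps this from inflating scores,
  but the generator should not be used to study spatial methods.
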