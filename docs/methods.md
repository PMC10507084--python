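# Methods

`swemg` reproduces, end to end and on synthetic data, the computational
pipeline of a chin-worn high-density surface-EMG (HD-sEMG) system for
classifying swallowing activity: signal synthesis, denoising,
segmentation, CNN classification, electrode characterization statistics,
and electrode–skin impedance fitting.  This note records the models, the
parameters that matter, and the design decisions taken where the
pipeline's published description left choices open.

## The synthetic corpus

No public recordings of chin HD-sEMG during swallowing exist, so the
package ships a forward model whose defaults define the study
conditions: 5 subjects × 11 actions × 10 repetitions = 550 epochs, each
2 s of 16 channels at 1000 Hz.  The sampling rate is inferred: a 125 ms
window of 125 points implies 1 kHz, which also makes the published
16 × 31 × 125 input tensor exact.

**Electrode grid.** 24 circular contacts (5 mm diameter) along the two
arms of a V that follows the jawline, 12 contacts per arm at a 12 mm
pitch, apex at the chin point.  With a 30° arm half-angle the innermost
cross-arm pair is also exactly one pitch apart, so the nearest-neighbor
distance is uniformly 12 mm.  The 8 inner contacts of each arm are the
16 working electrodes (left arm = channels 0–7, right arm = 8–15); the
8 outer contacts are references.  The true patch geometry is known only
photographically, so the layout is parameterized rather than digitized.

**Source model.** Each action is a burst template: onset, duration, peak
amplitude, and a laterality index in [−1, 1].  The myoelectric source is
Gaussian white noise band-passed to 20–450 Hz (a standard surrogate for
interference-pattern sEMG), multiplied by a Hann envelope and scaled to
the template's peak.  Default templates spread peaks over 150–505 µV
(the published range of submental peaks across contraction levels) and
durations over 0.5–1.85 s, with head-turn actions at laterality ±0.8:
the classes are separable by design through amplitude, duration and
lateral asymmetry.

**Mixing.** For the default whole-muscle simulation the swallowing
muscle sheet is taken to lie directly beneath the working contacts:
every channel receives the source at unit gain (±5 % seeded per-channel
jitter), weighted by laterality (a −1 laterality silences all left-arm
channels).  When a point source position is given instead, channels
receive `exp(−d/λ)` of the source with `d` the contact-to-source
distance and `λ = 10 mm`; this one-parameter volume-conduction law
reproduces the distance ordering of crosstalk (a source 20 mm away leaks
`exp(−2) ≈ 13.5 %`).

**Noise.** Gaussian baseline noise at 1.7 µV RMS (the published at-rest
noise floor of the gel electrode), 50 Hz powerline hum with harmonics
(amplitude 10 µV at the fundamental, 1/k at harmonic k, common-mode
across channels up to a 5 % gain spread), and Poisson-arriving motion
artifacts: 150 ms half-sine transients of 200 µV (spectral content well
below 20 Hz, so the bandpass stage demonstrably removes them).
Inter-subject variability is a log-normal amplitude factor (σ = 0.08)
per subject and a 50 ms onset jitter per repetition.  Everything is
deterministic under a fixed seed.

What the generator does **not** emulate: motor-unit anatomy,
nonstationary firing statistics, electrode drying, skin-deformation
mechanics, or inter-electrode impedance mismatch.  Passing tests
therefore validate the pipeline's mechanics and its behavior under the
assumed statistical structure — not clinical performance on real
patients.

## Denoising chain

`bandpass → notch bank → wavelet shrinkage`, each stage zero-phase
(forward–backward application), never changing shape, rate or label.

* **Bandpass:** 4th-order Butterworth, 20–500 Hz.  At the default 1 kHz
  sampling rate the upper edge coincides with Nyquist, where a bandpass
  is ill-posed, so the stage degrades to the 20 Hz high-pass plus the
  anti-alias assumption; with faster sampling it is a true bandpass.
* **Notch bank:** second-order IIR notches (Q = 30) at 50·k Hz for
  k = 1..9 (all below Nyquist), applied with long reflective padding.
  A Q = 30 notch rings for ≈ 0.2 s, so line suppression is specified and
  measured over the epoch interior (central 1.5 s), where it exceeds
  20 dB; the first and last quarter second retain ring-in.
* **Wavelet stage:** per-channel Daubechies-4 decomposition at level 4;
  noise scale σ estimated from the finest detail band by the median
  absolute deviation rule; soft thresholding with the per-level
  SURE-optimal threshold capped at the universal threshold
  σ√(2 ln N); results averaged over ±2 circular shifts
  (translation-invariant denoising).  The fixed universal threshold is
  the textbook default but is the wrong tool here: surface EMG is
  broadband, so a 3.9 σ threshold shrinks genuine in-band coefficients
  and *lowers* the root-sum-square SNR on burst fixtures (measured:
  10 dB in → 4 dB out).  The SURE rule adapts the threshold down where
  signal dominates and improves SNR at both 10 dB (→ ≈ 12 dB) and 25 dB
  input; this is why it is the default, with `universal-soft` and
  `universal-hard` available in `FilterSpec`.

## Segmentation and the activity mask

A 125 ms window with 62.5 ms overlap over a 2 s epoch gives 31 segments
of 125 points.  The half-window step is fractional (62.5 samples);
segment i starts at `round(i·62.5)`, the only convention that tiles 2000
samples into exactly 31 full windows without resampling.  Boundary cases
are decided by that rounded-start rule, not by floating-point division.

A segment is *active* when its averaged amplitude — the mean absolute
value over all channels and points, the simplest reading of the
published rule — exceeds 30 % of the maximum over the epoch's segments.
The mask is annotation: the full 31-segment tensor is always passed to
the classifier.  An all-zero epoch is all-inactive rather than an error.

Model input is the per-recording z-score of the whole tensor.  A
recording-level scheme preserves the inter-channel amplitude ratios that
encode laterality; note it deliberately discards absolute amplitude, so
the classifier reads amplitude only through the burst-to-noise-floor
contrast that survives normalization.

## Classifier

The network treats the 16 × 31 × 125 tensor as a 16-channel image:
three convolutional stages, each a residual block
(conv–norm–ReLU–conv–norm with an identity shortcut, 1 × 1 projection
where widths change), max pooling after stages 1 and 2, then two fully
connected layers of 512 nodes and a softmax head of length 11.

The published description fixes only that skeleton; all remaining
choices are ours:

* **Widths 16/32/64, 3 × 3 kernels.**  At 550 recordings this small net
  reaches the same accuracy as wider ones and trains in minutes on one
  CPU core (the whole engine is NumPy with im2col convolutions; gradient
  correctness is finite-difference-checked in the test suite).
* **Pooling 2 × 5.**  The input plane is strongly anisotropic (31
  segments × 125 samples); pooling harder along the fast-time axis
  integrates rectified EMG energy — the physiologically meaningful
  quantity — and shrinks the flattened feature map.
* **Optimization.**  Adam at 2 × 10⁻³ with cosine decay, batch 16, up to
  40 epochs, early stopping on validation accuracy (patience 12),
  dropout 0.2 on the FC layers, decoupled weight decay 10⁻⁴ on weights.
* **Augmentation.**  Training batches are circularly shifted by up to
  ±4 segments (±0.25 s) per sample, emulating onset variability;
  prediction averages the softmax over ±2-segment shifts (deterministic
  test-time augmentation).  Both matter: without them the net memorizes
  the 330 training epochs and confuses adjacent burst durations.

**Split protocol.**  Recordings from all subjects are pooled
("scrambled"), shuffled within class, and cut 60/20/20 — at recording
granularity, never segment granularity, so overlapping windows of one
epoch cannot leak across partitions.  550 recordings give exactly
330/110/110 with every class in every partition.  The checkpoint with
the best validation accuracy is evaluated on the untouched test
partition; confusion rows are ground truth.

A non-neural fallback (multinomial logistic regression on standardized
per-channel log-RMS plus the active-segment fraction) ships for quick
sanity analyses and for cheap monotonicity checks (e.g. that a 10×
noise increase does not improve accuracy); it is not the classifier of
record.

## Electrode metrics

* `snr_db` = 20·log₁₀ of the ratio of root-sum-square amplitudes of a
  signal window and a noise window.  On whole recordings the noise
  window is the first 250 ms pre-onset baseline — the published
  definition fixes the formula but not the window, and a fixed pre-burst
  window makes the statistic reproducible.
* `crosstalk_rate` = 100 × (inactive-muscle amplitude)/(active-muscle
  amplitude), with amplitude = RMS over the contraction window (robust
  to single-sample spikes, unlike a peak).
* `energy_map` = per-contact RMS in grid order; the asymmetry index is
  (L−R)/(L+R) over half-grid sums (0/0 ↦ 0).  Spatial interpolation is a
  display concern, not part of the statistic.
* `amplitude_force_summary` reports per-level peak |amplitude| and SNR
  plus fold changes against the lowest level; applied to the published
  peaks 150/350/505 µV it reproduces the printed 2.3× and 3.4×, and to
  the printed SNRs 25/30/34 dB the 1.2× and 1.36×.

## Impedance model and fitting

Electrode–skin contact is the five-element lumped circuit

    Z(f) = R_e + R_s/(1 + j2πf·R_s·C_s) + R_d/(1 + j2πf·R_d·C_d)

with series electrode resistance R_e, the stratum-corneum/sweat-gland
pair (R_s, C_s) and the interface pair (charge-transfer resistance R_d,
interfacial capacitance C_d).  |Z| falls monotonically from
R_e+R_s+R_d at DC to R_e at high frequency for every positive parameter
set of this topology.

Fitting minimizes the summed squared *relative* error of the real and
imaginary parts (|Z| spans decades; absolute residuals would let the
low-frequency points dominate), over log-parameters so positivity is
structural, via Levenberg–Marquardt from a data-driven start (R_e from
the high-frequency magnitude, the DC excess split 80/20 between the
branches, corners from the curvature of log|Z|).  The two RC pairs are
exchangeable in the model, so results are canonicalized: the pair with
the lower corner frequency is reported as (R_d, C_d).  Approximate 95 %
confidence intervals come from the Gauss–Newton curvature in log space.

Default parameters place both corners inside the 1–1000 Hz measurement
band (interface pair: the published 22 kΩ and 95 nF, corner ≈ 76 Hz;
skin pair 10 kΩ/50 nF, corner ≈ 318 Hz; R_e = 1 kΩ), which makes all
five parameters identifiable from a 30-point spectrum: with 1 %
multiplicative noise the median recovery error is ≈ 1–3 % per parameter
over 50 seeds.  A physically tiny R_e (a few ohms, as for a printed
silver trace) would be invisible below 1 kHz; the default is chosen so
the recovery study exercises the full parameter vector.

## Problem sizes and runtime

The test suite and the acceptance script train the CNN once each on the
full 550-recording corpus (≈ 8–10 minutes on one CPU core) and run the
50-seed impedance recovery study (seconds).  Unit tests use reduced
corpora (2 subjects × 3 reps) and narrow networks so the whole
non-acceptance suite stays under a minute.

## Known limitations

* Synthetic separability is engineered; the ~0.9 test accuracy on this
  corpus says nothing about the 80 % reported for real swallowing data.
* The generator's bursts are amplitude-modulated filtered noise; real
  swallowing sEMG has richer nonstationarity, and the two viscosity
  classes that real data confuse most are here just neighbors on a
  duration/amplitude ladder.
* The EDF writer emits the plain 16-bit EDF layout (no EDF+
  annotations); label and subject ride in the patient/recording-id
  fields.
* Impedance fitting assumes the five-element topology; constant-phase
  elements and Warburg diffusion are out of scope.
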