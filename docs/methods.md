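# Methods

## Signal model and processing chain

Each acquisition is a pair of six-channel inertial recordings (tri-axial
accelerometer, device-native units; tri-axial gyroscope, deg/s) of one arm
performing: a single high-speed, wide-amplitude shoulder flexion (the
calibration movement), then three reach-to-target cycles. Parkinsonian
tremor, when present, adds a 3.5–7 Hz oscillation on top of the sub-2 Hz
voluntary movement.

The per-acquisition chain is:

1. **Ingestion.** The watch dialect is repaired on read: the header row is
   located by scanning the first 50 lines for a row containing all required
   column names; rows repeating an earlier timestamp are dropped keeping the
   first occurrence (order-preserving); the time origin is shifted to t = 0
   (device epochs differ; only relative time matters). The effective rate is
   (n−1)/span.
2. **Resampling** to a uniform grid `t₀ + k/fs` (default 100 Hz) by cubic
   spline. For a ~100 Hz clock, piecewise-linear interpolation commits
   worst-case errors of h²(2πf)²/8 ≈ 1.2% of amplitude on 5 Hz content
   (h = 10 ms gap), which is the same order as the tremor effects under
   study; the spline's h⁴ term is negligible below 20 Hz. On an
   already-uniform grid the operation is the identity. Upsampling beyond 10×
   the effective rate is refused.
3. **Axis harmonization.** The watch frame opposes the reference on
   `acc_z`, `gyr_x`, `gyr_y`; those channels are negated once (guarded
   against double application).
4. **Filtering.** 4th-order Butterworth low-pass at 20 Hz. The default is
   zero-phase (forward–backward `sosfiltfilt`, reflective padding of
   3·order samples): landmark positions drive synchronization, so phase lag
   is unacceptable. A causal single-pass mode exists for completeness; it is
   implemented spectrally with the exact analog transfer function
   H(j2πf) = 1/Bₙ(j f/f_c) rather than a bilinear digital design, because
   bilinear warping attenuates ~1.6× too strongly at 0.4·fs (0.0400 vs the
   textbook (1+(f/f_c)^8)^{−1/2} = 0.0624 at 40 Hz, fs 200) and the causal
   mode's contract here *is* the textbook magnitude curve. Edges are padded
   with end values for longer than the impulse-response decay, and the
   response is cosine-tapered over the top 10% of the band (where
   |H| < 2·10⁻³) to kill the ringing that truncating a non-bandlimited
   response at Nyquist would otherwise cause.
5. **Standardization** z = (x − μ)/σ with the sample (n−1) SD, making
   device-native units (g vs m/s²) irrelevant downstream. Optional min–max
   normalization to [−1, 1] is available but **not** applied before spectral
   features: its data-dependent gain would distort cross-subject power
   comparisons. Each recording carries a provenance string naming its
   transform chain, and the feature table refuses to mix provenances.

## Synchronization

The devices share no trigger; the constant inter-device lag is estimated
from landmarks of the calibration movement:

- Peaks with topographic prominence ≥ 2.5 SD (on internally standardized
  copies) and ≥ 0.25 s separation are detected per channel; valleys by the
  same procedure on the negated signal — 12 landmark streams.
- For each stream present in both devices, the span (last − first landmark
  index) is compared; the stream with minimal |span discrepancy| wins. A
  spurious extra landmark in one device inflates its span and disqualifies
  the stream. Ties break by a fixed channel order (acc_x … gyr_z, peak
  before valley).
- The delay is the offset between the winning stream's first landmarks
  (positive = events later in the moving/watch stream); the moving
  recording is shifted by that single delay and both are trimmed to the
  overlap (≥ 1 s required).

The 2.5 SD prominence default separates calibration-scale landmarks
(≈ 5 SD) from reach peaks (≲ 2 SD) and tremor oscillations (prominence
≲ 1.8 SD at the strongest simulated amplitude). A 1 SD threshold admits
tremor peaks, which are periodic and therefore phase-ambiguous as
landmarks; in jittered/noisy simulations that produced delay errors of tens
of samples, which motivated the higher default. Lower `sync.min_prominence`
if the calibration movement was gentle. An alternative reading in which the
span discrepancy itself is the shift is reachable via
`sync.span_as_delay: true`; a cross-correlation estimator is provided for
diagnostics only.

Delay recovery under the generator's conditions: exact for all constructed
lags −200…+200 samples on noise-free pairs; with independent white noise at
20 dB SNR per device, 100% of 200 seeded trials recover within 2 samples
(the suite asserts ≥ 95%).

## Features

Per channel: arithmetic mean and sample SD; the one-sided PSD of the
mean-removed signal (plain periodogram by default — no taper, full record —
matching the "squared magnitude of the Fourier transform" definition; Welch
with 2 s Hann segments and 50% overlap available for variance reduction),
scaled so the trapezoidal integral over [0, fs/2] equals the mean squared
deviation (Parseval closure, verified to < 1%). From the PSD:

- `PSD_c`: trapezoidal band integral over 3.5–7 Hz with linear
  interpolation at the band edges (units W/Hz·Hz, i.e. power);
- `ratio_c`: band power as a fraction of the 0–20 Hz movement-band power
  (∈ [0, 1]; the reciprocal orientation is also exposed, since a printed
  "ratio" can mean either direction and the band integral itself is the
  more robust classifier feature — all candidates are computed and labeled).

24 features per recording (6 channels × {mean, sd, PSD, ratio}).

## Screening

`value ≥ cutoff → positive` (boundary inclusive — a convention this package
fixes explicitly since either choice is defensible). Shipped default
cutoffs: `PSD_gyr_x ≥ 19.35` (PD screen), `PSD_acc_x ≥ 9.07` (rest tremor),
`PSD_acc_x ≥ 6.43` (action tremor); an alternative profile with a
19.71 W/Hz screen cutoff is included because both values circulate for this
feature. These are demonstration defaults on the originating device scale,
not clinical claims: features computed on standardized signals live on a
different scale, and the intended workflow is to re-derive operating points
from your own labeled data via `stats.roc_analysis`.

## Statistics

- **Bland–Altman** (device agreement, Eq: DIF = A − B, μ = (A+B)/2): bias =
  mean(DIF), limits of agreement bias ± 1.96·SD(DIF) (the classic
  multiplier), two-sided one-sample t-test of DIF against 0 (switchable to
  one-sided), OLS regression of DIF on μ with a two-sided slope test for
  proportional bias. Constant differences are flagged degenerate: the
  t-test is undefined (NaN), while the proportional-bias slope is reported
  as exactly 0 with p = 1. Reliability reuses the identical computation on
  (first, second) acquisitions.
- **Correlations / group comparisons** gate on Shapiro–Wilk normality at
  α = 0.05 applied to each variable (both must pass for the parametric
  branch): Pearson vs Spearman; Student's t vs Mann–Whitney U. Effect
  sizes: Cohen's d (pooled n−1-weighted SD) and the rank-biserial
  correlation r = 2U/(n₁n₂) − 1. Strength labels: weak < 0.4 ≤ moderate ≤
  0.7 < strong on |r|. p-values are raw; no multiplicity correction is
  applied, and outputs carry n so users can adjust.
- **ROC**: trapezoidal AUC (identical to the tie-corrected concordance
  probability, asserted to 1e−12 against a brute-force O(n²) oracle);
  operating cutoff maximizes Youden's J with ties broken toward higher
  sensitivity; `adequate` flags AUC > 0.7.
- **Sample size**: smallest integer n per group for which the equal-n
  two-sample t-test reaches the requested power, from the noncentral-t
  distribution (df = 2n−2, ncp = d·√(n/2)). The tail choice is a required
  explicit parameter because it moves the answer materially: d = 0.70,
  power 0.80, α = 0.05 gives 26/group one-tailed and 34/group two-tailed.

## Synthetic data

`simulate_pair` builds a ground signal per channel:
`movement_weight_c · (5·spike(t) + reach(t)) + tremor_amp·tremor_weight_c ·
sin(2π f_tremor t + φ_c) + noise`, with a raised-cosine calibration spike
(amplitude 5 SD units, 0.25 s wide at t = 0.5 s), three out-and-back
raised-cosine reach cycles at 0.5 Hz (band-limited < 2 Hz;
minimum-jerk-like — no recorded waveform templates exist, and only the band
structure matters to the pipeline), tremor loaded most heavily on the x
axes (flexor–extensor emphasis; per-channel random phase, constant
amplitude within a recording), and independent white sensor noise per
device. The IMU samples uniformly at 100 Hz; the watch at 99.5 Hz with
2 ms/interval Gaussian jitter, lagged by `delay` (default 0.3 s),
sign-flipped into the watch frame, and written to disk with a displaced
header (line 4) and 2% duplicated rows. All randomness flows from one seed;
identical specs are byte-identical on disk.

`make_cohort` (defaults 21 PD / 27 control, two repetitions × two devices)
draws PD tremor amplitudes from N(effect, effect/4) floored at 0.05 SD and
control amplitudes from |N(0, 0.02)|, tremor frequency uniform on 4–6 Hz,
delay uniform on 0.1–0.5 s. Per-recording seeds derive from the cohort seed
by hashing (subject, repetition), keeping every seed below 2³¹.

`simulate_shifted_pair` is a separate fixture generator for delay-recovery
checks: both "devices" sample the identical noise-free waveform on the same
uniform grid, the second cut with an exact k-sample offset from an extended
simulation (events are validated to sit at least the maximum lag from both
window edges), with optional independent per-device noise. The jittered
two-clock generator cannot produce sample-exact shifted copies by
construction, so this fixture is what "exact recovery" is measured against.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanically realistic limb dynamics,
amplitude-modulated or re-emergent tremor, essential-tremor waveforms,
gravity offsets and orientation drift, sensor saturation, temperature
drift, or non-constant (drifting) inter-device lag. The end-to-end AUC on
synthetic cohorts is an internal-consistency property of the pipeline under
a deliberately strong injected effect (0.8 SD tremor vs 0.3 SD noise), not
an estimate of clinical discrimination.

## Problem sizes and numerical choices

Default simulations are 10 s (12 s for the ±200-sample delay sweeps) at
100 Hz — long enough for three reach cycles plus calibration, and the
acceptance cohort is 48 subjects × 1–2 repetitions, chosen to mirror the
validation-study design this pipeline targets. The delay sweep covers every
integer lag in −200…+200; the noisy sweep uses 200 seeded trials at 20 dB
SNR. Degenerate inputs fail loudly and specifically: constant channels
(standardization, min–max), single-class labels (ROC), sub-second overlap
(alignment), bands outside spectral support, unknown config keys. The
feature table's provenance check is a hard error rather than a warning
because silently mixing transform chains is the easiest way to fabricate a
group difference.
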