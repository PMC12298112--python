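# tremorkit

Paired smartwatch/IMU analysis of parkinsonian tremor during a standardized
arm-reach task: signal ingestion and repair, inter-device synchronization,
tremor-band spectral features, cutoff-based screening, and the
measurement-properties statistics used to validate a consumer wearable
against a laboratory-grade inertial sensor.

## The problem

A smartwatch worn next to a reference IMU records the same arm movement, but
its exports are messy: the CSV header row lands on a random line, whole rows
are duplicated, the nominal 100 Hz clock jitters, the device starts logging
at a different moment, and its axis-sign convention opposes the reference
(`acc_z`, `gyr_x`, `gyr_y` negated). `tremorkit` repairs all of this,
resamples both streams to a uniform 100 Hz, low-pass filters (4th-order
Butterworth, 20 Hz — human movement lives below 20 Hz) and standardizes each
channel (z = (x − μ)/σ), and aligns the devices using the landmark structure
of a deliberate high-amplitude calibration movement performed at the start
of each acquisition: peaks and valleys are detected per channel, the
channel whose first-to-last landmark span agrees best between devices is
trusted, and the offset of its first landmarks is the inter-device delay.

Per channel c it then computes mean_c and sd_c, and from the one-sided power
spectral density `P_c(f)` (periodogram, Parseval-normalized so
∫P(f)df = Var[x]):

- `PSD_c` = ∫ over 3.5–7 Hz of P_c(f) df — power in the parkinsonian tremor
  band, the primary screening feature;
- `ratio_c` = P[3.5,7] / P[0,20] — the tremor band as a fraction of total
  movement power (both orientations available).

Screening is a cutoff comparison (`value ≥ cutoff → positive`) with
literature-derived defaults on `PSD_gyr_x` (19.35 W/Hz, PD screen) and
`PSD_acc_x` (9.07 rest tremor / 6.43 action tremor); those defaults apply to
features on the original device scale, so for your own processing chain you
re-derive cutoffs with the built-in ROC analysis (Youden-optimal threshold,
AUC > 0.7 adequacy criterion).

The statistics battery covers **agreement** (Bland–Altman: bias,
1.96·SD limits, one-sample t-test of the differences, proportional-bias
regression of differences on means), **validity** (Shapiro–Wilk-gated
Pearson/Spearman correlations; t-test/Mann–Whitney group comparisons with
Cohen's d or rank-biserial effect sizes), **reliability** (Bland–Altman on
repeated acquisitions), **accuracy** (ROC), and a priori **sample-size**
planning from the noncentral-t power function.

Because no public recordings exist for this protocol, the package ships a
first-class synthetic generator (`tremorkit.synth`) that emulates both
export dialects — calibration spike, three reach cycles, optional 3.5–7 Hz
tremor, inter-device lag, clock jitter, sign flips, duplicated rows,
displaced headers — with full ground truth, so the entire pipeline is
testable end to end.

## Worked example

```sh
tremorkit simulate --seed 1 --out demo          # 21 PD + 27 control subjects
tremorkit features demo/recordings --out demo   # ingest → sync → features
tremorkit validate demo/features.csv --out demo
```

prints

```
cohort written to demo/recordings
192 feature rows -> demo/features.csv
AUC 1.000, cutoff 0.155 (sens 1.00, spec 1.00)
report -> demo/validation.json
```

and `demo/validation.json` holds the full battery for `PSD_gyr_x`; with this
seed the device agreement is `bias = 0.00051` with limits of agreement
`[−0.0098, 0.0108]` and no proportional bias (`p = 0.946`) — the watch and
IMU pipelines agree to within ~1% of the feature scale — while the ROC
separates the simulated arms perfectly (AUC 1.0 at a 0.155 cutoff on
standardized-signal band power; the injected tremor effect, amplitude 0.8 SD
against 0.1 SD sensor noise, is deliberately strong). The same calls are
available as library functions:

```python
from tremorkit import SyntheticSpec, simulate_pair, process_pair_recordings

pair = simulate_pair(SyntheticSpec(tremor_amp=0.8, delay=0.3, seed=42))
result = process_pair_recordings(pair.imu, pair.watch)
result.aligned.delay_samples   # 32 (ground truth: 30 samples)
result.watch_features["PSD_gyr_x"]   # 0.512
```

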