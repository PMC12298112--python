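"""Synthetic paired-device recordings with known ground truth.

The generator emulates the arm-movement acquisition protocol as seen by two
co-mounted inertial sensors: a single high-speed, wide-amplitude shoulder
flexion shortly after recording onset (the calibration spike used for
synchronization), three consecutive reach-to-target cycles (smooth,
band-limited below 2 Hz), an optional parkinsonian tremor component — a
sinusoid in the 3.5–7 Hz band with per-channel random phase and constant
amplitude — and additive white sensor noise.

The laboratory IMU samples this ground signal uniformly at 100 Hz.  The
smartwatch stream reproduces every known defect of real logger exports: a
jittered, imprecise sampling rate; a start lag relative to the IMU; the
opposing axis-sign convention (acc_z, gyr_x, gyr_y negated); and, at file
level, a header row displaced into the body of the file plus duplicated
timestamp rows.

Reach movements are modelled as raised-cosine (minimum-jerk-like) pulses:
no recorded waveform templates exist to draw from, and only the band
structure — movement below 2 Hz, tremor at 3.5–7 Hz — matters to the
pipeline.  Amplitudes are in SD units of the unit-amplitude reach profile.
All randomness flows from the single ``seed``; identical specs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ingest import IMU_COLUMNS, WATCH_COLUMNS
from .recording import CHANNELS, RawRecording

#: Relative loading of the movement (spike + reach) on each channel.  The
#: reach is predominantly a sagittal-plane arm translation/rotation; every
#: channel sees the calibration spike.
MOVEMENT_WEIGHTS = {
    "acc_x": 1.0, "acc_y": 0.6, "acc_z": 0.8,
    "gyr_x": 0.9, "gyr_y": 0.7, "gyr_z": 0.5,
}

#: Relative loading of tremor on each channel: heaviest on the x axes
#: (flexor–extensor tremor), present but weaker elsewhere.
TREMOR_WEIGHTS = {
    "acc_x": 1.0, "acc_y": 0.4, "acc_z": 0.5,
    "gyr_x": 1.0, "gyr_y": 0.5, "gyr_z": 0.4,
}

#: Epoch offset written into watch CSV timestamps (ingestion re-zeroes it).
WATCH_EPOCH = 3600.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated acquisition (both devices).

    Amplitudes (``spike_amplitude``, ``tremor_amp``, ``noise_sd``) are in SD
    units of the unit reach profile; ``delay`` is the watch start lag in
    seconds (positive = events appear later in the watch stream).
    """

    fs_imu: float = 100.0
    fs_watch_mean: float = 99.5
    fs_watch_jitter_sd: float = 0.002   # seconds, per sampling interval
    duration: float = 10.0              # seconds
    spike_amplitude: float = 5.0
    spike_time: float = 0.5             # seconds, spike centre
    spike_width: float = 0.25           # seconds, full width of the transient
    n_reaches: int = 3
    reach_freq: float = 0.5             # Hz; one reach cycle = 1/reach_freq
    tremor_freq: float = 5.0            # Hz, inside the 3.5-7 Hz band
    tremor_amp: float = 0.0
    noise_sd: float = 0.1
    delay: float = 0.3                  # seconds
    axis_flip: bool = True              # watch uses the opposing convention
    dup_row_rate: float = 0.02          # duplicated-row probability per row
    header_offset: int = 4              # 1-based line of the watch header row
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.tremor_amp < 0:
            raise ParameterError("tremor_amp must be >= 0")
        if not 0 <= self.dup_row_rate < 0.5:
            raise ParameterError("dup_row_rate must lie in [0, 0.5)")
        if self.tremor_amp > 0 and not 3.5 <= self.tremor_freq <= 7.0:
            raise ParameterError(
                f"tremor_freq {self.tremor_freq} Hz outside the 3.5-7 Hz band"
            )
        if self.reach_freq >= 2.0:
            raise ParameterError("reach_freq must stay below 2 Hz")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    delay_s: float
    delay_samples: int        # at the IMU rate
    tremor_amp: float
    tremor_freq: float
    phases: dict[str, float]
    n_duplicate_rows: int = 0


@dataclass
class SimulatedPair:
    imu: RawRecording
    watch: RawRecording
    truth: GroundTruth


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth unit pulse supported on [center − width/2, center + width/2]."""
    u = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1 + np.cos(2 * np.pi * u[m]))
    return out


def _ground(spec: SyntheticSpec, phases: dict[str, float], t: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free ground signal of every channel at times ``t`` (seconds).

    Defined on the whole real line (pulses vanish outside their support), so
    the delayed watch stream can sample it at negative times.
    """
    spike = _raised_cosine(t, spec.spike_time, spec.spike_width)
    reach_start = spec.spike_time + spec.spike_width  # reaches follow the spike
    cycle = 1.0 / spec.reach_freq
    reach = np.zeros_like(t)
    for k in range(spec.n_reaches):
        c = reach_start + (k + 0.5) * cycle
        # out-and-back: positive lobe (reach) then negative lobe (return)
        reach += _raised_cosine(t, c - cycle / 4, cycle / 2)
        reach -= _raised_cosine(t, c + cycle / 4, cycle / 2)
    out = {}
    for c in CHANNELS:
        tremor = spec.tremor_amp * TREMOR_WEIGHTS[c] * np.sin(
            2 * np.pi * spec.tremor_freq * t + phases[c]
        )
        out[c] = MOVEMENT_WEIGHTS[c] * (spec.spike_amplitude * spike + reach) + tremor
    return out


def simulate_pair(spec: SyntheticSpec) -> SimulatedPair:
    """Simulate one acquisition on both devices.

    The IMU recording is uniform at ``fs_imu`` in the canonical frame.  The
    watch recording is jitter-sampled, lagged by ``delay``, and sign-flipped
    into the watch frame when ``axis_flip``.  Sensor noise is independent
    between devices.
    """
    rng = np.random.default_rng(spec.seed)
    phases = {c: float(rng.uniform(0, 2 * np.pi)) for c in CHANNELS}

    n_imu = int(np.floor(spec.duration * spec.fs_imu)) + 1
    t_imu = np.arange(n_imu) / spec.fs_imu
    g_imu = _ground(spec, phases, t_imu)
    imu = RawRecording(
        device_id="imu",
        timestamps=t_imu,
        channels={
            c: g_imu[c] + rng.normal(0, spec.noise_sd, n_imu) for c in CHANNELS
        },
        nominal_fs=spec.fs_imu,
        axis_convention="imu",
    )

    if spec.fs_watch_jitter_sd > 0:
        dt = 1.0 / spec.fs_watch_mean + rng.normal(
            0, spec.fs_watch_jitter_sd, int(spec.duration * spec.fs_watch_mean * 1.2)
        )
        dt = np.clip(dt, 1e-3, None)
        t_watch = np.concatenate(([0.0], np.cumsum(dt)))
        t_watch = t_watch[t_watch <= spec.duration]
    else:
        t_watch = np.arange(int(np.floor(spec.duration * spec.fs_watch_mean)) + 1) / spec.fs_watch_mean
    g_watch = _ground(spec, phases, t_watch - spec.delay)
    sign = {c: -1.0 if (spec.axis_flip and c in ("acc_z", "gyr_x", "gyr_y")) else 1.0
            for c in CHANNELS}
    watch = RawRecording(
        device_id="watch",
        timestamps=t_watch,
        channels={
            c: sign[c] * (g_watch[c] + rng.normal(0, spec.noise_sd, len(t_watch)))
            for c in CHANNELS
        },
        nominal_fs=100.0,
        axis_convention="watch" if spec.axis_flip else "imu",
    )

    truth = GroundTruth(
        delay_s=spec.delay,
        delay_samples=int(round(spec.delay * spec.fs_imu)),
        tremor_amp=spec.tremor_amp,
        tremor_freq=spec.tremor_freq,
        phases=phases,
    )
    return SimulatedPair(imu=imu, watch=watch, truth=truth)


def simulate_shifted_pair(
    spec: SyntheticSpec,
    lag_samples: int,
    independent_noise_sd: float = 0.0,
    margin_s: float = 2.5,
) -> tuple[RawRecording, RawRecording]:
    """Exact-lag fixture: two uniform-rate recordings of the same ground
    signal where the second is the first shifted by exactly ``lag_samples``.

    Both devices sample the identical noise-free waveform on the same 100 Hz
    grid (no jitter, no sign flip), so with ``independent_noise_sd = 0`` the
    moving recording is a sample-exact shifted copy — the ground truth for
    delay-recovery checks.  ``margin_s`` of extra waveform is generated on
    both sides so that all movement landmarks stay inside both windows for
    |lag| ≤ margin·fs.  Optional white noise is drawn independently per
    device (e.g. at 1/10 the signal RMS for a 20 dB SNR fixture).
    """
    fs = spec.fs_imu
    m = int(round(margin_s * fs))
    if abs(lag_samples) > m:
        raise ParameterError(f"|lag| {abs(lag_samples)} exceeds margin {m} samples")
    # every movement landmark must stay inside BOTH shifted windows, i.e. at
    # least margin_s from each edge of the reference window
    event_start = spec.spike_time - spec.spike_width / 2
    event_end = (spec.spike_time + spec.spike_width
                 + spec.n_reaches / spec.reach_freq)
    if event_start < margin_s or event_end > spec.duration - margin_s:
        raise ParameterError(
            f"movement events span [{event_start:.2f}, {event_end:.2f}] s but must "
            f"lie within [{margin_s}, {spec.duration - margin_s}] s for lags up to "
            f"{m} samples; move spike_time or lengthen duration"
        )
    rng = np.random.default_rng(spec.seed)
    phases = {c: float(rng.uniform(0, 2 * np.pi)) for c in CHANNELS}
    n = int(np.floor(spec.duration * fs)) + 1
    ext_spec = replace(spec, spike_time=spec.spike_time + margin_s)
    t_ext = np.arange(n + 2 * m) / fs
    g = _ground(ext_spec, phases, t_ext)
    t = np.arange(n) / fs

    def _cut(start: int, device: str) -> RawRecording:
        chans = {c: g[c][start : start + n].copy() for c in CHANNELS}
        if independent_noise_sd > 0:
            for c in CHANNELS:
                chans[c] = chans[c] + rng.normal(0, independent_noise_sd, n)
        return RawRecording(
            device_id=device, timestamps=t, channels=chans,
            nominal_fs=fs, axis_convention="imu",
        )

    ref = _cut(m, "imu")
    moving = _cut(m - lag_samples, "watch")
    return ref, moving


def write_imu_file(rec: RawRecording, path: str | Path) -> Path:
    """Write the clean IMU dialect: header on line 1, regular rows."""
    path = Path(path)
    df = pd.DataFrame({IMU_COLUMNS["t"]: rec.timestamps})
    for c in CHANNELS:
        df[IMU_COLUMNS[c]] = rec.channels[c]
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def write_watch_file(
    rec: RawRecording,
    path: str | Path,
    header_offset: int = 4,
    dup_row_rate: float = 0.02,
    seed: int = 0,
) -> tuple[Path, int]:
    """Write the defective watch dialect.

    ``header_offset`` is the 1-based line on which the header row lands;
    preceding lines are junk metadata.  Each data row is duplicated with
    probability ``dup_row_rate`` (identical timestamp — exactly the rows the
    ingest repair must drop).  Returns the path and the duplicate count.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    names = [WATCH_COLUMNS["t"]] + [WATCH_COLUMNS[c] for c in CHANNELS]
    junk = [f"# watchlogger export,segment {i},,,,,," for i in range(max(0, header_offset - 1))]
    lines = junk + [",".join(names)]
    n_dup = 0
    for i in range(len(rec)):
        vals = [f"{rec.timestamps[i] + WATCH_EPOCH:.6f}"] + [
            f"{rec.channels[c][i]:.9g}" for c in CHANNELS
        ]
        row = ",".join(vals)
        lines.append(row)
        if rng.uniform() < dup_row_rate:
            lines.append(row)
            n_dup += 1
    path.write_text("\n".join(lines) + "\n")
    return path, n_dup


def write_pair(pair: SimulatedPair, out_dir: str | Path, stem: str,
               spec: SyntheticSpec) -> dict[str, Path]:
    """Write one simulated pair as the two on-disk dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    imu_path = write_imu_file(pair.imu, out_dir / f"{stem}_imu.csv")
    watch_path, n_dup = write_watch_file(
        pair.watch, out_dir / f"{stem}_watch.csv",
        header_offset=spec.header_offset,
        dup_row_rate=spec.dup_row_rate,
        seed=spec.seed + 1,
    )
    pair.truth.n_duplicate_rows = n_dup
    return {"imu": imu_path, "watch": watch_path}


def _subject_seed(base_seed: int, subject: str, repetition: int) -> int:
    """Stable per-recording seed below 2**31, derived from the cohort seed."""
    h = hashlib.sha256(f"{base_seed}:{subject}:{repetition}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def make_cohort(
    n_pd: int = 21,
    n_ctrl: int = 27,
    effect: float = 0.8,
    seed: int = 0,
    out_dir: str | Path = "cohort",
    base_spec: SyntheticSpec = SyntheticSpec(),
    n_repetitions: int = 2,
) -> pd.DataFrame:
    """Generate a labeled cohort: per subject, ``n_repetitions`` acquisitions
    on both devices, written as CSV files, plus a manifest.

    The parkinsonian arm draws its tremor amplitude from a normal
    distribution centred at ``effect`` (SD = effect/4, floored at 0.05); the
    control arm draws near-zero amplitudes (|N(0, 0.02)|, below the band
    where the pipeline should ever flag tremor).  Tremor frequency is
    uniform on 4–6 Hz.  Deterministic under ``seed``.
    """
    if n_pd < 1 or n_ctrl < 1:
        raise ParameterError("both arms need at least one subject")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("pd", i) for i in range(n_pd)] + [("ctrl", i) for i in range(n_ctrl)]
    for group, i in groups:
        subject = f"{group}{i:03d}"
        if group == "pd":
            amp = float(max(0.05, rng.normal(effect, effect / 4)))
        else:
            amp = float(abs(rng.normal(0.0, 0.02)))
        freq = float(rng.uniform(4.0, 6.0))
        for rep in range(1, n_repetitions + 1):
            rec_seed = _subject_seed(seed, subject, rep)
            delay = float(rng.uniform(0.1, 0.5))
            spec = replace(
                base_spec, tremor_amp=amp, tremor_freq=freq,
                delay=delay, seed=rec_seed,
            )
            pair = simulate_pair(spec)
            paths = write_pair(pair, out_dir, f"{subject}_rep{rep}", spec)
            rows.append({
                "subject": subject,
                "group": group,
                "repetition": rep,
                "tremor_amp": amp,
                "tremor_freq": freq,
                "delay_s": delay,
                "delay_samples": pair.truth.delay_samples,
                "imu_file": paths["imu"].name,
                "watch_file": paths["watch"].name,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
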