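"""Inter-device synchronization from the calibration movement.

Both devices record the same arm, but start logging at different moments, so
a constant lag separates their streams.  The acquisition protocol begins with
a single high-speed, wide-amplitude shoulder flexion precisely so that a
sharp landmark exists in every channel.  Synchronization proceeds by
landmark bookkeeping:

1.  For each of the six channels, peaks and valleys (peaks of the negated
    signal) above a prominence threshold are located — 12 landmark streams.
2.  In each stream, the span from the first to the last landmark is measured
    in both recordings; the stream with the smallest span discrepancy between
    devices is the most trustworthy (a spurious extra landmark in one device
    inflates its span and disqualifies the stream).
3.  The delay is the offset between the first landmarks of the chosen stream,
    and that single delay shifts all channels.

Landmark detection runs on internally standardized copies so that the
prominence threshold is in SD units regardless of channel scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, ParameterError
from .preprocess import standardize
from .recording import CHANNELS, RawRecording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakSet:
    """Positions and prominences of detected landmarks of one polarity."""

    indices: np.ndarray
    prominences: np.ndarray
    polarity: str  # "peak" or "valley"

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class SyncParams:
    """Landmark-detection parameters.

    ``min_prominence`` is in SD units of the standardized signal.  The
    calibration flexion registers at roughly 5 SD while reach peaks and
    tremor oscillations stay below ~2 SD, so the 2.5 SD default admits only
    calibration-scale landmarks; lower it if the calibration movement was
    gentle.  ``min_distance_s`` suppresses landmark doublets closer than a
    quarter second.  ``span_as_delay`` switches to the literal reading in
    which the winning stream's span discrepancy itself is used as the shift.
    """

    min_prominence: float = 2.5
    min_distance_s: float = 0.25
    span_as_delay: bool = False


def find_peaks(x: np.ndarray, min_prominence: float, min_distance: int) -> PeakSet:
    """Strict local maxima with topographic prominence ≥ ``min_prominence``,
    greedily thinned (highest first) so survivors are ≥ ``min_distance``
    samples apart.  Valleys are found by calling this on ``−x``."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError(f"need at least 3 samples, got {len(x)}")
    idx, props = sps.find_peaks(
        x, prominence=min_prominence, distance=max(1, int(min_distance))
    )
    return PeakSet(indices=idx, prominences=props["prominences"], polarity="peak")


def find_valleys(x: np.ndarray, min_prominence: float, min_distance: int) -> PeakSet:
    ps = find_peaks(-np.asarray(x, dtype=float), min_prominence, min_distance)
    return PeakSet(indices=ps.indices, prominences=ps.prominences, polarity="valley")


@dataclass
class AlignedPair:
    """Two recordings on a common clock after delay correction."""

    ref: RawRecording
    moving: RawRecording
    delay_samples: int
    chosen_channel: str  # e.g. "acc_x:peak"
    span_discrepancy: int
    #: per-stream diagnostics: {stream: (span_ref, span_moving, discrepancy)}
    stream_table: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _landmark_streams(rec: RawRecording, params: SyncParams) -> dict[str, PeakSet]:
    """All 12 channel/polarity landmark streams of one recording."""
    dist = int(round(params.min_distance_s * rec.effective_fs))
    streams: dict[str, PeakSet] = {}
    for c in CHANNELS:
        try:
            z = standardize(rec.channels[c])
        except Exception:  # constant channel: no landmarks
            continue
        streams[f"{c}:peak"] = find_peaks(z, params.min_prominence, dist)
        streams[f"{c}:valley"] = find_valleys(z, params.min_prominence, dist)
    return streams


def estimate_delay(
    ref: RawRecording, moving: RawRecording, params: SyncParams = SyncParams()
) -> AlignedPair:
    """Estimate the lag of ``moving`` relative to ``ref``.

    ``delay_samples > 0`` means events occur later in ``moving``'s stream; the
    returned pair's recordings are NOT yet shifted (see :func:`align_pair`).

    Raises :class:`AlignmentError` when no channel produces landmarks in both
    recordings — usually a sign the prominence threshold is too high.
    """
    if abs(ref.effective_fs - moving.effective_fs) > 1e-6 * ref.effective_fs:
        raise AlignmentError(
            f"sampling rates differ ({ref.effective_fs:.3f} vs "
            f"{moving.effective_fs:.3f} Hz); resample both to a common rate first"
        )
    s_ref = _landmark_streams(ref, params)
    s_mov = _landmark_streams(moving, params)

    # fixed stream order for deterministic argmin tie-breaking
    order = [f"{c}:{pol}" for c in CHANNELS for pol in ("peak", "valley")]
    table: dict[str, tuple[int, int, int]] = {}
    best: tuple[int, int] | None = None  # (|discrepancy|, order index)
    best_stream = None
    for i, stream in enumerate(order):
        pr, pm = s_ref.get(stream), s_mov.get(stream)
        if pr is None or pm is None or len(pr) == 0 or len(pm) == 0:
            continue
        span_r = int(pr.indices[-1] - pr.indices[0])
        span_m = int(pm.indices[-1] - pm.indices[0])
        disc = span_r - span_m
        table[stream] = (span_r, span_m, disc)
        key = (abs(disc), i)
        if best is None or key < best:
            best, best_stream = key, stream

    if best_stream is None:
        raise AlignmentError(
            "no channel yields landmarks in both recordings; "
            "lower min_prominence or check the calibration movement"
        )
    span_r, span_m, disc = table[best_stream]
    if params.span_as_delay:
        delay = disc
    else:
        delay = int(
            s_mov[best_stream].indices[0] - s_ref[best_stream].indices[0]
        )
    if abs(delay) >= min(len(ref), len(moving)) / 2:
        raise AlignmentError(
            f"estimated delay {delay} samples exceeds half the recording length; "
            "landmark detection likely failed"
        )
    return AlignedPair(
        ref=ref,
        moving=moving,
        delay_samples=delay,
        chosen_channel=best_stream,
        span_discrepancy=disc,
        stream_table=table,
    )


def align_pair(
    ref: RawRecording, moving: RawRecording, delay_samples: int
) -> tuple[RawRecording, RawRecording]:
    """Shift ``moving`` by ``delay_samples`` and trim both recordings to their
    overlapping support; the outputs share one time grid and length."""
    n_ref, n_mov = len(ref), len(moving)
    if abs(delay_samples) >= min(n_ref, n_mov):
        raise AlignmentError(
            f"|delay| = {abs(delay_samples)} is not smaller than the recordings"
        )
    d = delay_samples
    # moving[k + d] lines up with ref[k]
    start_ref, start_mov = (0, d) if d >= 0 else (-d, 0)
    n = min(n_ref - start_ref, n_mov - start_mov)
    fs = ref.effective_fs
    if n < fs:  # require at least one second of overlap
        raise AlignmentError(f"aligned overlap of {n} samples is under one second")

    def _slice(rec: RawRecording, start: int, n: int) -> RawRecording:
        out = rec.copy()
        out.timestamps = ref.timestamps[start_ref : start_ref + n]
        out.channels = {c: rec.channels[c][start : start + n] for c in CHANNELS}
        return out

    return _slice(ref, start_ref, n), _slice(moving, start_mov, n)


def synchronize(
    ref: RawRecording, moving: RawRecording, params: SyncParams = SyncParams()
) -> AlignedPair:
    """Estimate the delay and return the trimmed, clock-shared pair."""
    est = estimate_delay(ref, moving, params)
    a_ref, a_mov = align_pair(ref, moving, est.delay_samples)
    est.ref, est.moving = a_ref, a_mov
    return est


def crosscorr_delay(ref: RawRecording, moving: RawRecording, channel: str = "acc_x") -> int:
    """Diagnostic-only estimator: lag of the cross-correlation maximum on one
    channel.  Never used by the default pipeline; provided for sanity checks
    against the landmark estimator."""
    a = standardize(ref.channels[channel])
    b = standardize(moving.channels[channel])
    cc = sps.correlate(b, a, mode="full")
    return int(np.argmax(cc) - (len(a) - 1))
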