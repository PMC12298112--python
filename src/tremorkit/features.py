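"""Spatiotemporal and spectral features per channel.

For each of the six channels the pipeline computes the mean and sample SD
(spatiotemporal) and, from the power spectral density, the power integrated
over the parkinsonian tremor band 3.5–7 Hz and a dimensionless ratio of that
band against the full human-movement range 0–20 Hz.  The band integral
(``PSD_<channel>``) is the primary screening feature; both ratio orientations
ship as secondary features because either orientation appears in practice.

The PSD is a one-sided density scaled so its integral over [0, fs/2] equals
the signal's mean squared deviation (Parseval).  The default estimator is the
plain periodogram of the mean-removed record — the squared magnitude of the
full-length Fourier transform — with Welch averaging (2 s Hann segments, 50%
overlap) available when variance reduction matters more than resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConsistencyError, DegenerateSignalError, ParameterError
from .recording import CHANNELS, RawRecording

TREMOR_BAND = (3.5, 7.0)
MOVEMENT_BAND = (0.0, 20.0)


@dataclass(frozen=True)
class PsdCurve:
    """One-sided power spectral density in W/Hz on a frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def total(self) -> float:
        """Trapezoidal integral over the full frequency support."""
        return float(np.trapezoid(self.power, self.freqs))


def psd(x: np.ndarray, fs: float, method: str = "periodogram") -> PsdCurve:
    """Estimate the one-sided PSD of ``x``.

    The mean is removed first; no taper is applied in periodogram mode.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ParameterError(f"signal too short for spectral analysis: {len(x)} samples")
    if method == "periodogram":
        f, p = sps.periodogram(x, fs=fs, window="boxcar", detrend="constant")
    elif method == "welch":
        nper = min(len(x), int(2 * fs))
        f, p = sps.welch(x, fs=fs, window="hann", nperseg=nper,
                         noverlap=nper // 2, detrend="constant")
    else:
        raise ParameterError(f"unknown PSD method {method!r}")
    return PsdCurve(freqs=f, power=p)


def band_power(curve: PsdCurve, f_lo: float = TREMOR_BAND[0],
               f_hi: float = TREMOR_BAND[1]) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi], with linear
    interpolation of the density at the band edges."""
    if not f_lo < f_hi:
        raise ParameterError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > curve.freqs[-1] or f_lo < curve.freqs[0]:
        raise ParameterError(
            f"band [{f_lo}, {f_hi}] outside frequency support "
            f"[{curve.freqs[0]}, {curve.freqs[-1]}]"
        )
    inside = (curve.freqs > f_lo) & (curve.freqs < f_hi)
    f = np.concatenate(([f_lo], curve.freqs[inside], [f_hi]))
    p = np.concatenate((
        [np.interp(f_lo, curve.freqs, curve.power)],
        curve.power[inside],
        [np.interp(f_hi, curve.freqs, curve.power)],
    ))
    return float(np.trapezoid(p, f))


def tremor_ratio(curve: PsdCurve, orientation: str = "band_over_total") -> float:
    """Fraction of 0–20 Hz movement power that falls in the 3.5–7 Hz tremor
    band (``band_over_total``, in [0, 1]) or its reciprocal
    (``total_over_band``)."""
    band = band_power(curve, *TREMOR_BAND)
    total = band_power(curve, MOVEMENT_BAND[0], min(MOVEMENT_BAND[1], curve.freqs[-1]))
    if total == 0:
        raise DegenerateSignalError("no power in 0-20 Hz; ratio undefined")
    if orientation == "band_over_total":
        return band / total
    if orientation == "total_over_band":
        if band == 0:
            raise DegenerateSignalError("no power in the tremor band; ratio undefined")
        return total / band
    raise ParameterError(f"unknown orientation {orientation!r}")


def spatiotemporal(rec: RawRecording) -> dict[str, float]:
    """Per-channel arithmetic mean and sample SD (n−1 denominator)."""
    out: dict[str, float] = {}
    for c in CHANNELS:
        x = rec.channels[c]
        out[f"mean_{c}"] = float(np.mean(x))
        out[f"sd_{c}"] = float(np.std(x, ddof=1))
    return out


def extract_features(rec: RawRecording, method: str = "periodogram") -> dict[str, float]:
    """All 24 features of one recording: mean_*, sd_*, PSD_* (tremor-band
    integral) and ratio_* (band fraction of 0–20 Hz power)."""
    feats = spatiotemporal(rec)
    fs = rec.effective_fs
    for c in CHANNELS:
        curve = psd(rec.channels[c], fs, method=method)
        feats[f"PSD_{c}"] = band_power(curve)
        feats[f"ratio_{c}"] = tremor_ratio(curve)
    return feats


FEATURE_COLUMNS = (
    [f"mean_{c}" for c in CHANNELS]
    + [f"sd_{c}" for c in CHANNELS]
    + [f"PSD_{c}" for c in CHANNELS]
    + [f"ratio_{c}" for c in CHANNELS]
)


def feature_table(
    recordings: Iterable[tuple[str, str, int, RawRecording]],
    method: str = "periodogram",
) -> pd.DataFrame:
    """Tidy table of features, one row per (subject, device, repetition).

    All recordings must share one transform provenance; mixing e.g. filtered
    with raw recordings silently distorts cross-row comparisons, so it is an
    error.
    """
    rows = []
    provenance: str | None = None
    for subject, device, repetition, rec in recordings:
        if provenance is None:
            provenance = rec.provenance
        elif rec.provenance != provenance:
            raise ConsistencyError(
                f"mixed transform provenance: {provenance!r} vs {rec.provenance!r}"
            )
        row = {"subject": subject, "device": device, "repetition": repetition}
        row.update(extract_features(rec, method=method))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject", "device", "repetition", *FEATURE_COLUMNS])
    df.attrs["provenance"] = provenance
    return df
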