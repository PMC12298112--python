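"""Canonical in-memory representation of one device's inertial recording.

A :class:`RawRecording` carries six synchronously sampled channels — tri-axial
acceleration and tri-axial angular velocity — on a shared timestamp vector.
Acceleration units are device-native (the pipeline standardizes amplitudes
before any cross-device comparison, so g vs m/s² never matters); angular
velocity is degrees per second.  Timestamps are seconds with the origin
shifted so the first sample sits at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: Channel names in canonical order.  This order also fixes deterministic
#: tie-breaking wherever channels compete (see sync module).
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Axis conventions.  ``watch`` differs from ``imu`` by the sign of acc_z,
#: gyr_x and gyr_y; ``canonical`` is the IMU frame after harmonization.
AXIS_CONVENTIONS = ("imu", "watch", "canonical")


@dataclass
class RawRecording:
    """One device's timestamped tri-axial accelerometer + gyroscope streams."""

    device_id: str
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    nominal_fs: float = 100.0
    axis_convention: str = "canonical"
    #: identifier of the transform chain applied so far ("raw", "filtered",
    #: "filtered+standardized", ...); consumed by the feature table to refuse
    #: mixing differently-processed recordings.
    provenance: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {c: np.asarray(v, dtype=float) for c, v in self.channels.items()}
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise DataError(f"recording is missing channels: {missing}")
        n = len(self.timestamps)
        if n < 2:
            raise DataError(f"recording needs at least 2 samples, got {n}")
        for c in CHANNELS:
            if len(self.channels[c]) != n:
                raise DataError(
                    f"channel {c!r} has {len(self.channels[c])} samples, timestamps have {n}"
                )
        if np.any(np.diff(self.timestamps) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.axis_convention not in AXIS_CONVENTIONS:
            raise DataError(f"unknown axis convention {self.axis_convention!r}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def effective_fs(self) -> float:
        """Sampling rate implied by the timestamps: (n−1) / span."""
        span = self.timestamps[-1] - self.timestamps[0]
        return (len(self) - 1) / span

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def copy(self, **overrides) -> "RawRecording":
        new = replace(
            self,
            timestamps=self.timestamps.copy(),
            channels={c: v.copy() for c, v in self.channels.items()},
            meta=dict(self.meta),
        )
        for k, v in overrides.items():
            setattr(new, k, v)
        return new

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.timestamps}
        data.update({c: self.channels[c] for c in CHANNELS})
        return pd.DataFrame(data)


def write_canonical_csv(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as canonical CSV (t, acc_x..gyr_z) plus a JSON
    metadata sidecar (``<path>.meta.json``) recording device, rate, and
    convention."""
    path = Path(path)
    rec.to_frame().to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "device_id": rec.device_id,
        "nominal_fs": rec.nominal_fs,
        "effective_fs": rec.effective_fs,
        "axis_convention": rec.axis_convention,
        "provenance": rec.provenance,
        "n_samples": len(rec),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar) + "\n")
    return path


def read_canonical_csv(path: str | Path, device_id: str | None = None) -> RawRecording:
    """Read a canonical CSV written by :func:`write_canonical_csv`.

    The sidecar is optional; without it the convention defaults to canonical.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = Path(str(path) + ".meta.json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RawRecording(
        device_id=device_id or meta.get("device_id", path.stem),
        timestamps=df["t"].to_numpy(),
        channels={c: df[c].to_numpy() for c in CHANNELS},
        nominal_fs=meta.get("nominal_fs", 100.0),
        axis_convention=meta.get("axis_convention", "canonical"),
        provenance=meta.get("provenance", "raw"),
    )
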