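"""Run configuration: flat dotted keys, YAML-backed, strictly validated.

A :class:`RunConfig` holds every tunable of the pipeline under dotted keys
(``filter.cutoff_hz``, ``sync.min_prominence`` ...).  Unknown keys are
rejected — a typo in a config file must fail loudly, not silently fall back
to a default.  Every CLI run writes the fully resolved config beside its
outputs so any result can be reproduced from the artifact directory alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError
from .preprocess import FilterSpec
from .sync import SyncParams

#: Every recognized key with its default.
DEFAULTS: dict[str, Any] = {
    "ingest.target_fs": 100.0,
    "ingest.watch_columns": None,     # optional {canonical: file column} map
    "ingest.imu_columns": None,
    "filter.enabled": True,
    "filter.cutoff_hz": 20.0,
    "filter.order": 4,
    "filter.mode": "zero_phase",
    "transforms.standardize": True,
    "transforms.normalize_range": None,  # e.g. [-1, 1]; None = skip
    "sync.min_prominence": 1.0,
    "sync.min_distance_s": 0.25,
    "sync.span_as_delay": False,
    "features.psd_method": "periodogram",
    "rules.profile": "default",
    "stats.feature": "PSD_gyr_x",
    "stats.positive_group": "pd",
    "simulate.n_pd": 21,
    "simulate.n_ctrl": 27,
    "simulate.effect": 0.8,
    "simulate.noise_sd": 0.1,
    "simulate.duration": 10.0,
    "simulate.delay": 0.3,
    "seed": 0,
    "log_level": "INFO",
}


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


class RunConfig:
    """Resolved configuration: defaults overlaid with file and CLI values."""

    def __init__(self, overrides: dict[str, Any] | None = None):
        values = dict(DEFAULTS)
        if overrides:
            flat = _flatten(overrides)
            unknown = sorted(set(flat) - set(DEFAULTS))
            if unknown:
                raise ParameterError(f"unknown config keys: {unknown}")
            values.update(flat)
        self.values = values

    @classmethod
    def from_file(cls, path: str | Path, extra: dict[str, Any] | None = None) -> "RunConfig":
        """Load a YAML config (flat dotted or nested keys); ``extra`` (CLI
        flags) wins over file values."""
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        merged = _flatten(loaded)
        merged.update(extra or {})
        return cls(merged)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def filter_spec(self) -> FilterSpec | None:
        if not self.values["filter.enabled"]:
            return None
        return FilterSpec(
            cutoff_hz=self.values["filter.cutoff_hz"],
            order=self.values["filter.order"],
            mode=self.values["filter.mode"],
        )

    def sync_params(self) -> SyncParams:
        return SyncParams(
            min_prominence=self.values["sync.min_prominence"],
            min_distance_s=self.values["sync.min_distance_s"],
            span_as_delay=self.values["sync.span_as_delay"],
        )

    def dump(self, path: str | Path) -> Path:
        """Write the resolved config as YAML beside the run's outputs."""
        from . import __version__

        path = Path(path)
        payload = {"tremorkit_version": __version__, **self.values}
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path
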