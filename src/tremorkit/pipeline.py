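"""End-to-end orchestration: ingest → preprocess → synchronize → features.

The canonical processing order for one paired acquisition is:

1.  parse both device exports (repairing the watch file's defects),
2.  resample each stream onto a uniform 100 Hz grid,
3.  harmonize the axis-sign conventions onto the canonical (IMU) frame,
4.  low-pass filter and standardize every channel,
5.  estimate the inter-device delay from the calibration-movement landmarks
    and trim both recordings to the overlapping support,
6.  extract the 24 features per recording.

Cohort-level helpers run this over a generated or recorded file tree and
assemble the tidy feature table consumed by the statistics battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import TremorkitError
from .features import FEATURE_COLUMNS, extract_features, feature_table
from .ingest import harmonize_axes, read_imu_csv, read_watch_csv, resample_uniform
from .preprocess import FilterSpec, preprocess_recording
from .recording import RawRecording
from .stats import bland_altman, correlate, group_compare, roc_analysis
from .sync import AlignedPair, SyncParams, synchronize

log = logging.getLogger(__name__)


@dataclass
class PairResult:
    """Everything the pipeline derives from one paired acquisition."""

    aligned: AlignedPair
    imu_features: dict[str, float]
    watch_features: dict[str, float]


def process_pair(
    imu_path: str | Path,
    watch_path: str | Path,
    target_fs: float = 100.0,
    filter_spec: FilterSpec | None = FilterSpec(),
    sync_params: SyncParams = SyncParams(),
    psd_method: str = "periodogram",
) -> PairResult:
    """Run the full per-acquisition pipeline on two export files."""
    imu = read_imu_csv(imu_path)
    watch = read_watch_csv(watch_path)
    return process_pair_recordings(
        imu, watch, target_fs=target_fs, filter_spec=filter_spec,
        sync_params=sync_params, psd_method=psd_method,
    )


def process_pair_recordings(
    imu: RawRecording,
    watch: RawRecording,
    target_fs: float = 100.0,
    filter_spec: FilterSpec | None = FilterSpec(),
    sync_params: SyncParams = SyncParams(),
    psd_method: str = "periodogram",
) -> PairResult:
    """Same as :func:`process_pair` but starting from parsed recordings."""
    imu = resample_uniform(imu, target_fs)
    watch = resample_uniform(watch, target_fs)
    if imu.axis_convention != "canonical":
        imu = harmonize_axes(imu)
    if watch.axis_convention != "canonical":
        watch = harmonize_axes(watch)
    imu = preprocess_recording(imu, filter_spec=filter_spec)
    watch = preprocess_recording(watch, filter_spec=filter_spec)
    aligned = synchronize(imu, watch, sync_params)
    return PairResult(
        aligned=aligned,
        imu_features=extract_features(aligned.ref, method=psd_method),
        watch_features=extract_features(aligned.moving, method=psd_method),
    )


def process_cohort(
    cohort_dir: str | Path,
    manifest: pd.DataFrame | None = None,
    **pair_kwargs,
) -> pd.DataFrame:
    """Process every acquisition of a cohort file tree into a feature table.

    ``manifest`` defaults to ``<cohort_dir>/manifest.csv``; its ``group``
    column (and any truth columns) are merged onto the output rows.
    """
    cohort_dir = Path(cohort_dir)
    if manifest is None:
        manifest = pd.read_csv(cohort_dir / "manifest.csv")
    entries = []
    for row in manifest.itertuples():
        try:
            res = process_pair(
                cohort_dir / row.imu_file, cohort_dir / row.watch_file, **pair_kwargs
            )
        except TremorkitError as exc:
            log.warning("skipping %s rep %s: %s", row.subject, row.repetition, exc)
            continue
        for device, feats in (("imu", res.imu_features), ("watch", res.watch_features)):
            entry = {
                "subject": row.subject, "device": device,
                "repetition": row.repetition, "group": row.group,
                "delay_samples_est": res.aligned.delay_samples,
            }
            entry.update(feats)
            entries.append(entry)
    cols = ["subject", "device", "repetition", "group", "delay_samples_est",
            *FEATURE_COLUMNS]
    return pd.DataFrame(entries, columns=cols)


def validate_features(
    table: pd.DataFrame,
    feature: str = "PSD_gyr_x",
    positive_group: str = "pd",
    device: str = "watch",
) -> dict:
    """The measurement-properties battery on one feature of a cohort table.

    Agreement and validity need both devices; reliability needs two
    repetitions; accuracy needs a ``group`` column.  Whatever the table
    supports is computed, the rest is reported as ``None``.
    """
    out: dict[str, object] = {"feature": feature, "device": device}
    sub = table[table["repetition"] == table["repetition"].min()]
    wide = sub.pivot_table(index="subject", columns="device", values=feature)

    if {"imu", "watch"} <= set(wide.columns) and wide.dropna().shape[0] >= 4:
        paired = wide.dropna()
        out["agreement"] = bland_altman(paired["imu"], paired["watch"])
        out["validity_corr"] = correlate(paired["imu"], paired["watch"])
    else:
        out["agreement"] = out["validity_corr"] = None
        log.warning("agreement skipped: need both devices with >= 4 subjects")

    dev = table[table["device"] == device]
    reps = sorted(dev["repetition"].unique())
    if len(reps) >= 2:
        rep_wide = dev.pivot_table(index="subject", columns="repetition", values=feature)
        paired = rep_wide[[reps[0], reps[1]]].dropna()
        out["reliability"] = bland_altman(paired[reps[0]], paired[reps[1]]) \
            if len(paired) >= 3 else None
    else:
        out["reliability"] = None

    first = dev[dev["repetition"] == dev["repetition"].min()]
    out["discriminative"] = out["accuracy"] = None
    if "group" in first.columns and first["group"].nunique() == 2:
        labels = (first["group"] == positive_group).astype(int)
        if labels.sum() >= 3 and (1 - labels).sum() >= 3:
            out["discriminative"] = group_compare(
                first.loc[labels == 1, feature], first.loc[labels == 0, feature]
            )
        else:
            log.warning("group comparison skipped: needs >= 3 subjects per arm")
        out["accuracy"] = roc_analysis(first[feature], labels)
    return out
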