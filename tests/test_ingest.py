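"""CSV dialect parsing, repairs, resampling, and axis harmonization."""

import numpy as np
import pytest

from tremorkit.errors import DataError, FormatError, ParameterError
from tremorkit.ingest import (
    IMU_COLUMNS,
    WATCH_COLUMNS,
    harmonize_axes,
    read_imu_csv,
    read_watch_csv,
    resample_uniform,
)
from tremorkit.recording import CHANNELS, RawRecording, read_canonical_csv, write_canonical_csv
from tremorkit.synth import SyntheticSpec, simulate_pair, write_imu_file, write_watch_file

from conftest import make_recording


def _watch_header():
    return [WATCH_COLUMNS["t"]] + [WATCH_COLUMNS[c] for c in CHANNELS]


def _write_watch(path, rows, header_line=1, junk="junk,row,,,,,,"):
    lines = [junk] * (header_line - 1) + [",".join(_watch_header())]
    lines += [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestWatchDialect:
    def test_header_relocated_into_body_is_found(self, tmp_path):
        rows = [[i / 100] + [0.1 * i] * 6 for i in range(500)]
        p = _write_watch(tmp_path / "w.csv", rows, header_line=4)
        rec = read_watch_csv(p)
        assert len(rec) == 500
        assert rec.axis_convention == "watch"

    def test_duplicate_timestamp_rows_dropped_keeping_first(self, tmp_path):
        rows = [[i / 100, i, i, i, i, i, i] for i in range(93)]
        # duplicate 7 earlier timestamps with DIFFERENT channel values: the
        # first occurrence must win
        for j in range(7):
            rows.insert(2 * j + 1, [rows[2 * j][0]] + [-999] * 6)
        assert len(rows) == 100
        p = _write_watch(tmp_path / "w.csv", rows)
        rec = read_watch_csv(p)
        assert len(rec) == 93
        assert not np.any(rec.channels["acc_x"] == -999)

    def test_dedup_preserves_input_order(self, tmp_path):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0]
        rows = [[i / 100, v, 0, 0, 0, 0, 0] for i, v in enumerate(vals)]
        rows.insert(2, list(rows[1]))  # duplicate of the 2nd row
        p = _write_watch(tmp_path / "w.csv", rows)
        rec = read_watch_csv(p)
        assert list(rec.channels["acc_x"]) == vals

    def test_effective_fs_from_jittered_timestamps(self, tmp_path):
        spec = SyntheticSpec(seed=5, dup_row_rate=0.0)
        pair = simulate_pair(spec)
        p, _ = write_watch_file(pair.watch, tmp_path / "w.csv", dup_row_rate=0.0)
        rec = read_watch_csv(p)
        # (n-1)/span of a ~99.5 Hz jittered clock
        assert rec.effective_fs == pytest.approx(99.5, abs=0.5)

    def test_missing_column_names_the_column(self, tmp_path):
        names = _watch_header()
        names.remove(WATCH_COLUMNS["gyr_z"])
        lines = [",".join(names)] + ["0.0" + ",1" * 6, "0.01" + ",1" * 6]
        (tmp_path / "w.csv").write_text("\n".join(lines))
        with pytest.raises(FormatError, match="gyroRotationZ"):
            read_watch_csv(tmp_path / "w.csv")

    def test_single_timestamp_is_data_error(self, tmp_path):
        rows = [[0.0, 1, 1, 1, 1, 1, 1], [0.0, 2, 2, 2, 2, 2, 2]]
        p = _write_watch(tmp_path / "w.csv", rows)
        with pytest.raises(DataError, match="timestamps"):
            read_watch_csv(p)


class TestImuDialect:
    def test_exact_100hz_file(self, tmp_path):
        rec = make_recording(n=1000)
        p = write_imu_file(rec, tmp_path / "imu.csv")
        out = read_imu_csv(p)
        assert len(out) == 1000
        assert out.effective_fs == pytest.approx(100.0, abs=1e-9)
        assert out.axis_convention == "imu"

    def test_empty_file_is_format_error(self, tmp_path):
        (tmp_path / "e.csv").write_text("")
        with pytest.raises(FormatError):
            read_imu_csv(tmp_path / "e.csv")

    def test_nan_cell_is_data_error_naming_position(self, tmp_path):
        names = [IMU_COLUMNS["t"]] + [IMU_COLUMNS[c] for c in CHANNELS]
        lines = [",".join(names)]
        for i in range(5):
            vals = [str(i / 100.0)] + ["1.0"] * 6
            if i == 3:
                vals[2] = ""  # AccY missing on row 3
            lines.append(",".join(vals))
        (tmp_path / "n.csv").write_text("\n".join(lines))
        with pytest.raises(DataError, match=r"row 3.*acc_y"):
            read_imu_csv(tmp_path / "n.csv")


class TestResample:
    def test_jittered_sine_recovered_on_uniform_grid(self):
        r = np.random.default_rng(0)
        t = np.cumsum(np.clip(1 / 99.5 + r.normal(0, 0.002, 995), 1e-3, None))
        t = np.concatenate(([0.0], t))
        rec = RawRecording(
            device_id="j", timestamps=t,
            channels={c: np.sin(2 * np.pi * 5 * t) for c in CHANNELS},
        )
        out = resample_uniform(rec, 100.0)
        expect = np.sin(2 * np.pi * 5 * out.timestamps)
        assert np.max(np.abs(out.channels["acc_x"] - expect)) < 0.01
        assert out.effective_fs == pytest.approx(100.0)

    def test_uniform_input_is_identity(self, noise_recording):
        out = resample_uniform(noise_recording, 100.0)
        assert len(out) == len(noise_recording)
        for c in CHANNELS:
            np.testing.assert_allclose(
                out.channels[c], noise_recording.channels[c], atol=1e-12
            )

    def test_output_grid_length(self):
        # exactly 10 s of span at the target rate -> 1001 grid points
        rec = make_recording(n=1001, fs=100.0)
        assert len(resample_uniform(rec, 100.0)) == 1001
        # non-integer span: floor(span * fs) + 1
        rec2 = make_recording(n=2000, fs=200.0)  # span 9.995 s
        assert len(resample_uniform(rec2, 100.0)) == int(np.floor(9.995 * 100)) + 1

    def test_band_limited_mean_preserved(self):
        t = np.arange(0, 10, 1 / 99.3)
        sig = 2.0 + np.sin(2 * np.pi * 18 * t)
        rec = RawRecording(
            device_id="m", timestamps=t, channels={c: sig for c in CHANNELS}
        )
        out = resample_uniform(rec, 100.0)
        assert np.mean(out.channels["acc_x"]) == pytest.approx(
            np.mean(sig), rel=0.01
        )

    def test_extrapolative_upsampling_refused(self, noise_recording):
        with pytest.raises(ParameterError, match="10x"):
            resample_uniform(noise_recording, 1001.0)


class TestHarmonizeAxes:
    def test_watch_sign_rule(self):
        rec = make_recording(n=10, convention="watch")
        for c, v in zip(CHANNELS, (1, 2, 3, 4, 5, 6)):
            rec.channels[c] = np.full(10, float(v))
        out = harmonize_axes(rec)
        got = [out.channels[c][0] for c in CHANNELS]
        assert got == [1, 2, -3, -4, -5, 6]
        assert out.axis_convention == "canonical"

    def test_imu_unchanged(self):
        rec = make_recording(n=10, convention="imu", seed=1)
        out = harmonize_axes(rec)
        for c in CHANNELS:
            np.testing.assert_array_equal(out.channels[c], rec.channels[c])
        assert out.axis_convention == "canonical"

    def test_double_application_is_guarded_noop(self, caplog):
        rec = make_recording(n=10, convention="watch", seed=2)
        once = harmonize_axes(rec)
        with caplog.at_level("WARNING"):
            twice = harmonize_axes(once)
        assert "no-op" in caplog.text
        for c in CHANNELS:
            np.testing.assert_array_equal(twice.channels[c], once.channels[c])

    def test_sign_map_is_involution(self):
        rec = make_recording(n=50, convention="watch", seed=3)
        once = harmonize_axes(rec)
        # re-applying the raw sign map (by relabeling as watch) restores input
        again = harmonize_axes(once.copy(axis_convention="watch"))
        for c in CHANNELS:
            np.testing.assert_array_equal(again.channels[c], rec.channels[c])


def test_canonical_roundtrip_preserves_values(tmp_path, noise_recording):
    p = write_canonical_csv(noise_recording, tmp_path / "c.csv")
    back = read_canonical_csv(p)
    for c in CHANNELS:
        np.testing.assert_allclose(
            back.channels[c], noise_recording.channels[c], rtol=1e-8
        )
    assert back.axis_convention == noise_recording.axis_convention
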