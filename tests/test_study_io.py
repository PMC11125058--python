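"""Raw-input parsing, manifest arithmetic, and image-dataset round trips."""
import numpy as np
import pandas as pd
import pytest

from metspecs.errors import FormatError, IntegrityError, RangeError, ReferenceError_
from metspecs.io import (
    read_image_dataset,
    read_imu,
    read_manifest,
    write_image_dataset,
)
from metspecs.types import (
    ActivitySegment,
    ParticipantProfile,
    SensorImage,
    StudyManifest,
)


def _write_head_csv(path, n=1280, rate=128.0):
    t = np.arange(n) / rate
    df = pd.DataFrame({
        "timestamp": t,
        "ax": np.sin(t), "ay": np.cos(t), "az": np.ones(n),
        "gx": t, "gy": -t, "gz": np.zeros(n),
    })
    df.to_csv(path, index=False)
    return df


class TestReadImu:
    def test_head_row_count_preserved(self, tmp_path):
        _write_head_csv(tmp_path / "101_head.csv")
        rec = read_imu(tmp_path / "101_head.csv", "head")
        assert rec.accel.shape == (1280, 3)
        assert rec.gyro.shape == (1280, 3)
        assert rec.accel_rate_hz == rec.gyro_rate_hz == 128.0
        assert rec.participant_id == "101"

    def test_missing_column_is_format_error(self, tmp_path):
        df = pd.DataFrame(np.zeros((10, 6)),
                          columns=["timestamp", "ax", "ay", "az", "gx", "gy"])
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError):
            read_imu(tmp_path / "bad.csv", "head")

    def test_hip_device_keeps_distinct_rates(self, tmp_path):
        pd.DataFrame({
            "timestamp": np.arange(90) / 90.0,
            "ax": np.zeros(90), "ay": np.zeros(90), "az": np.ones(90),
        }).to_csv(tmp_path / "a.csv", index=False)
        pd.DataFrame({
            "timestamp": np.arange(100) / 100.0,
            "gx": np.zeros(100), "gy": np.zeros(100), "gz": np.zeros(100),
        }).to_csv(tmp_path / "g.csv", index=False)
        rec = read_imu(tmp_path / "a.csv", "hip", gyro_path=tmp_path / "g.csv")
        assert rec.accel_rate_hz == 90.0 and rec.gyro_rate_hz == 100.0
        assert rec.accel.shape[0] == 90 and rec.gyro.shape[0] == 100

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        df = _write_head_csv(tmp_path / "x.csv", n=50)
        df.loc[10, "timestamp"] = df.loc[5, "timestamp"]
        df.to_csv(tmp_path / "x.csv", index=False)
        with pytest.raises(IntegrityError):
            read_imu(tmp_path / "x.csv", "head")


class TestManifestArithmetic:
    """Per-participant labelled minutes are the sum of segment durations."""

    @staticmethod
    def _manifest(pid, minutes):
        t = 0.0
        segs = []
        for i, mins in enumerate(minutes):
            segs.append(ActivitySegment(pid, f"a{i}", t, t + mins * 60.0))
            t += mins * 60.0 + 30.0
        return StudyManifest([ParticipantProfile(pid, 70.0)], segs)

    @pytest.mark.parametrize(
        "minutes,total",
        [
            # the study's first participant performed eight bouts
            ((6, 5.5, 6, 5.5, 5.5, 5, 5.5, 6), 45.0),
            # the fifth participant's computer bout was discarded: seven bouts
            ((6, 6, 6, 5.5, 5.5, 5.5, 6), 40.5),
        ],
    )
    def test_study_totals(self, minutes, total):
        m = self._manifest("101", minutes)
        assert m.total_minutes("101") == pytest.approx(total)

    def test_empty_segment_list(self):
        m = StudyManifest([ParticipantProfile("9", 70.0)], [])
        assert m.total_minutes("9") == 0.0

    def test_overlapping_segments_rejected(self):
        with pytest.raises(IntegrityError):
            StudyManifest(
                [ParticipantProfile("1", 70.0)],
                [ActivitySegment("1", "a", 0, 100),
                 ActivitySegment("1", "b", 50, 150)],
            )

    def test_unknown_participant_rejected(self):
        with pytest.raises(ReferenceError_):
            StudyManifest(
                [ParticipantProfile("1", 70.0)],
                [ActivitySegment("2", "a", 0, 100)],
            )


class TestImageDataset:
    @staticmethod
    def _windows(n, rng, h=64, w=6):
        return [
            SensorImage(
                matrix=rng.integers(0, 256, size=(h, w)),
                participant_id=f"{100 + i % 3}",
                activity_label="walking",
                window_start_s=float(10 * i),
                combo="acc_gyr",
                kind="sequential" if i % 2 == 0 else "random",
                body_mass_kg=70.5,
                mets=3.5,
                class_index=5,
                device="head",
            )
            for i in range(n)
        ]

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        windows = self._windows(36, rng)
        write_image_dataset(windows, tmp_path / "ds")
        back = read_image_dataset(tmp_path / "ds")
        assert len(back) == 36
        for a, b in zip(windows, back):
            assert np.array_equal(a.matrix, b.matrix)
            assert a.provenance == b.provenance
            assert (a.combo, a.kind, a.class_index) == (b.combo, b.kind, b.class_index)
            assert a.mets == pytest.approx(b.mets)
            assert a.body_mass_kg == pytest.approx(b.body_mass_kg)

    def test_out_of_range_value_rejected(self):
        m = np.zeros((8, 6), dtype=np.int64)
        m[0, 0] = 256
        with pytest.raises(RangeError):
            SensorImage(m, "1", "a", 0.0, "acc_gyr", "sequential")

    def test_full_height_window_geometry(self, tmp_path):
        rng = np.random.default_rng(4)
        windows = self._windows(1, rng, h=1280, w=6)
        write_image_dataset(windows, tmp_path / "ds")
        back = read_image_dataset(tmp_path / "ds")
        assert back[0].matrix.shape == (1280, 6)

    def test_count_mismatch_detected(self, tmp_path):
        rng = np.random.default_rng(5)
        write_image_dataset(self._windows(4, rng), tmp_path / "ds")
        (tmp_path / "ds" / "img_000003.png").unlink()
        with pytest.raises(IntegrityError):
            read_image_dataset(tmp_path / "ds")


def test_read_manifest_from_study_dir(small_study_dir):
    m = read_manifest(small_study_dir)
    assert len(m.profiles) == 3
    for pid in m.participant_ids:
        assert len(m.segments_of(pid)) == 6
        # six 150-s bouts -> 15 labelled minutes
        assert m.total_minutes(pid) == pytest.approx(15.0)
        assert m.device_files[pid].keys() >= {"head", "hip_accel", "hip_gyro"}
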