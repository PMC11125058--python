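"""Reading the study's raw inputs and persisting the windowed image dataset.

Documented CSV dialects (all plain text, header row first):

* IMU, head device — one file per participant:
  ``timestamp,ax,ay,az,gx,gy,gz`` (timestamp in seconds since recording
  start; accel in g, gyro in deg/s; both sensors at 128 Hz).
* IMU, hip device — two files because the accelerometer (90 Hz) and
  gyroscope (100 Hz) run at different rates:
  ``timestamp,ax,ay,az`` and ``timestamp,gx,gy,gz``.
* Calorimetry: ``participant_id,epoch_start_s,vo2_ml_min`` (30-s epochs).
* Annotations: ``participant_id,activity,start_s,stop_s,weight_bearing``.
* Participants: ``participant_id,body_mass_kg``.

A study directory bundles ``participants.csv``, ``annotations.csv``,
``calorimetry.csv`` and an ``imu/`` folder with per-participant device
files. The windowed image dataset is written as 8-bit grayscale PNGs plus a
``manifest.csv`` carrying full provenance; the round trip is bit-exact.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .types import (
    ActivitySegment,
    CalorimetryEpoch,
    DEVICE_RATES,
    ImuRecording,
    ParticipantProfile,
    SensorImage,
    StudyManifest,
)
from .windows import load_image, save_image

_HEAD_COLUMNS = ["timestamp", "ax", "ay", "az", "gx", "gy", "gz"]
_ACCEL_COLUMNS = ["timestamp", "ax", "ay", "az"]
_GYRO_COLUMNS = ["timestamp", "gx", "gy", "gz"]

MANIFEST_COLUMNS = [
    "file",
    "participant_id",
    "activity_label",
    "window_start_s",
    "combo",
    "kind",
    "class_index",
    "mets",
    "body_mass_kg",
    "device",
    "height",
    "width",
]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _check_monotone(ts: np.ndarray, path: str | Path) -> None:
    if ts.size > 1 and np.any(np.diff(ts) <= 0):
        raise IntegrityError(f"{path}: timestamps are not strictly increasing")


def read_imu(
    path: str | Path,
    device: str,
    gyro_path: str | Path | None = None,
    participant_id: str = "",
    accel_rate_hz: float | None = None,
    gyro_rate_hz: float | None = None,
) -> ImuRecording:
    """Read one device's raw IMU stream.

    For the head device, ``path`` holds all six channels. For the hip
    device, ``path`` holds the accelerometer block and ``gyro_path`` the
    gyroscope block (their rates differ). Sampling rates come from the
    device table (or explicit overrides), never inferred from timestamps.
    """
    if device not in DEVICE_RATES:
        raise FormatError(f"unknown device {device!r}")
    acc_rate, gyr_rate = DEVICE_RATES[device]
    acc_rate = accel_rate_hz if accel_rate_hz is not None else acc_rate
    gyr_rate = gyro_rate_hz if gyro_rate_hz is not None else gyr_rate

    if device == "head":
        df = _read_csv(path, _HEAD_COLUMNS)
        _check_monotone(df["timestamp"].to_numpy(float), path)
        accel = df[["ax", "ay", "az"]].to_numpy(float)
        gyro = df[["gx", "gy", "gz"]].to_numpy(float)
    else:
        if gyro_path is None:
            raise FormatError("hip device requires a separate gyro_path")
        da = _read_csv(path, _ACCEL_COLUMNS)
        dg = _read_csv(gyro_path, _GYRO_COLUMNS)
        _check_monotone(da["timestamp"].to_numpy(float), path)
        _check_monotone(dg["timestamp"].to_numpy(float), gyro_path)
        accel = da[["ax", "ay", "az"]].to_numpy(float)
        gyro = dg[["gx", "gy", "gz"]].to_numpy(float)

    return ImuRecording(
        participant_id=participant_id or Path(path).stem.split("_")[0],
        device=device,
        accel=accel,
        gyro=gyro,
        accel_rate_hz=acc_rate,
        gyro_rate_hz=gyr_rate,
    )


def read_participants(path: str | Path) -> list[ParticipantProfile]:
    df = _read_csv(path, ["participant_id", "body_mass_kg"])
    return [
        ParticipantProfile(str(r.participant_id), float(r.body_mass_kg))
        for r in df.itertuples()
    ]


def read_annotations(path: str | Path) -> list[ActivitySegment]:
    df = _read_csv(
        path, ["participant_id", "activity", "start_s", "stop_s", "weight_bearing"]
    )
    return [
        ActivitySegment(
            participant_id=str(r.participant_id),
            activity_label=str(r.activity),
            start_s=float(r.start_s),
            stop_s=float(r.stop_s),
            weight_bearing=bool(r.weight_bearing),
        )
        for r in df.itertuples()
    ]


def read_calorimetry(path: str | Path) -> list[CalorimetryEpoch]:
    df = _read_csv(path, ["participant_id", "epoch_start_s", "vo2_ml_min"])
    return [
        CalorimetryEpoch(
            participant_id=str(r.participant_id),
            epoch_start_s=float(r.epoch_start_s),
            vo2_ml_min=float(r.vo2_ml_min),
        )
        for r in df.itertuples()
    ]


def read_manifest(study_dir: str | Path) -> StudyManifest:
    """Read a study directory into a :class:`StudyManifest`.

    Validates segment/participant referential integrity and per-participant
    segment non-overlap (both raise from the manifest constructor).
    """
    study_dir = Path(study_dir)
    profiles = read_participants(study_dir / "participants.csv")
    segments = read_annotations(study_dir / "annotations.csv")
    device_files: dict[str, dict[str, str]] = {}
    imu_dir = study_dir / "imu"
    if imu_dir.is_dir():
        for p in profiles:
            pid = p.participant_id
            files = {}
            head = imu_dir / f"{pid}_head.csv"
            if head.exists():
                files["head"] = str(head)
            hip_a = imu_dir / f"{pid}_hip_accel.csv"
            hip_g = imu_dir / f"{pid}_hip_gyro.csv"
            if hip_a.exists():
                files["hip_accel"] = str(hip_a)
                files["hip_gyro"] = str(hip_g)
            device_files[pid] = files
    return StudyManifest(profiles=profiles, segments=segments, device_files=device_files)


def write_image_dataset(windows: list[SensorImage], out_dir: str | Path) -> Path:
    """Persist windows as grayscale PNGs plus a provenance manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"img_{i:06d}.png"
        save_image(w.matrix, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "participant_id": w.participant_id,
                "activity_label": w.activity_label,
                "window_start_s": w.window_start_s,
                "combo": w.combo,
                "kind": w.kind,
                "class_index": w.class_index,
                "mets": w.mets,
                "body_mass_kg": w.body_mass_kg,
                "device": w.device,
                "height": w.height,
                "width": w.width,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def read_image_dataset(out_dir: str | Path) -> list[SensorImage]:
    """Reload a written image dataset; bit-exact inverse of the writer."""
    out_dir = Path(out_dir)
    df = _read_csv(out_dir / "manifest.csv", MANIFEST_COLUMNS)
    n_png = len(list(out_dir.glob("img_*.png")))
    if n_png != len(df):
        raise IntegrityError(
            f"manifest lists {len(df)} images but {n_png} PNG files found"
        )
    out = []
    for r in df.itertuples():
        matrix = load_image(out_dir / str(r.file))
        if matrix.shape != (int(r.height), int(r.width)):
            raise IntegrityError(f"{r.file}: shape differs from manifest")
        out.append(
            SensorImage(
                matrix=matrix,
                participant_id=str(r.participant_id),
                activity_label=str(r.activity_label),
                window_start_s=float(r.window_start_s),
                combo=str(r.combo),
                kind=str(r.kind),
                class_index=int(r.class_index),
                mets=float(r.mets),
                body_mass_kg=float(r.body_mass_kg),
                device="" if pd.isna(r.device) else str(r.device),
            )
        )
    return out
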