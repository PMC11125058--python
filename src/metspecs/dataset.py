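"""End-to-end ingest: raw study directory -> labelled 10-s sensor images.

Per participant and device the pipeline is: slice each annotated segment
out of the recording, up-sample the hip accelerometer to the gyro rate,
clip gyroscopes to +/-400 deg/s, group channels into the requested sensor
combination, cut sequential (and optionally random) 10-s windows, rescale
each channel to 8-bit integers (bounds per window by default), and attach
the activity class and steady-state MET label derived from calorimetry.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as study_io
from .calorimetry import compute_labels, label_windows
from .errors import ConfigError
from .preprocessing import (
    ChannelMatrix,
    GYRO_CLIP_DPS,
    RescaleParams,
    clip_gyro,
    group_channels,
    rescale_floor,
    resample_to_rate,
)
from .types import (
    ActivitySegment,
    CalorimetryEpoch,
    HIP_ACCEL_TARGET_HZ,
    ImuRecording,
    SensorImage,
    StudyManifest,
)
from .windows import WINDOW_S, random_windows, sequential_windows


@dataclass
class IngestConfig:
    device: str = "head"
    combo: str = "acc_gyr"
    window_s: float = WINDOW_S
    step_s: float = WINDOW_S
    random_per_segment: int | None = None  # None -> match sequential count
    rescale_scope: str = "window"
    gyro_clip_dps: float = GYRO_CLIP_DPS
    seed: int = 0


def segment_channel_matrix(
    recording: ImuRecording,
    segment: ActivitySegment,
    combo: str,
    gyro_clip_dps: float = GYRO_CLIP_DPS,
) -> ChannelMatrix:
    """Raw (un-rescaled) grouped channels of one segment.

    Hip accelerometer is resampled to the gyro rate so the acc_gyr grouping
    aligns sample-for-sample; gyro channels are clipped.
    """
    acc_rate = recording.accel_rate_hz
    gyr_rate = recording.gyro_rate_hz
    a0 = int(round((segment.start_s - recording.start_time_s) * acc_rate))
    a1 = int(round((segment.stop_s - recording.start_time_s) * acc_rate))
    g0 = int(round((segment.start_s - recording.start_time_s) * gyr_rate))
    g1 = int(round((segment.stop_s - recording.start_time_s) * gyr_rate))
    acc = recording.accel[a0:a1]
    gyr = recording.gyro[g0:g1]

    if recording.device == "hip" and acc_rate != HIP_ACCEL_TARGET_HZ:
        acc = np.column_stack(
            [resample_to_rate(acc[:, j], acc_rate, HIP_ACCEL_TARGET_HZ)
             for j in range(3)]
        )
        acc_rate = HIP_ACCEL_TARGET_HZ
    gyr = clip_gyro(gyr, gyro_clip_dps)

    if combo == "acc":
        rate = acc_rate
    else:
        rate = gyr_rate
        if combo == "acc_gyr":
            if acc_rate != gyr_rate:
                raise ConfigError(
                    "acc_gyr grouping needs matching rates after resampling"
                )
            n = min(acc.shape[0], gyr.shape[0])  # rounding at segment edges
            acc, gyr = acc[:n], gyr[:n]
    return group_channels(acc, gyr, combo, rate)


def _window_rescale(scope_matrix: np.ndarray | None, scope: str):
    """Per-channel 8-bit rescale transform for window extraction."""
    if scope == "window":
        def transform(m: np.ndarray) -> np.ndarray:
            return np.column_stack(
                [rescale_floor(m[:, j]) for j in range(m.shape[1])]
            )
        return transform
    # segment/recording scope: bounds fixed from the wider extent
    lo = scope_matrix.min(axis=0)
    hi = scope_matrix.max(axis=0)

    def transform(m: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [
                rescale_floor(
                    m[:, j],
                    RescaleParams(x_min=lo[j], x_max=hi[j], scope=scope),
                )
                for j in range(m.shape[1])
            ]
        )
    return transform


def windows_for_segment(
    recording: ImuRecording,
    segment: ActivitySegment,
    cfg: IngestConfig,
    rng: np.random.Generator,
    body_mass_kg: float = float("nan"),
    recording_matrix: ChannelMatrix | None = None,
) -> list[SensorImage]:
    matrix = segment_channel_matrix(recording, segment, cfg.combo, cfg.gyro_clip_dps)
    if cfg.rescale_scope == "recording":
        if recording_matrix is None:
            raise ConfigError("recording-scope rescale needs the full matrix")
        transform = _window_rescale(recording_matrix.values, "recording")
    elif cfg.rescale_scope == "segment":
        transform = _window_rescale(matrix.values, "segment")
    else:
        transform = _window_rescale(None, "window")
    meta = dict(body_mass_kg=body_mass_kg, device=recording.device)
    out = sequential_windows(
        segment, matrix, cfg.window_s, cfg.step_s, transform=transform, **meta
    )
    n_rand = cfg.random_per_segment if cfg.random_per_segment is not None else len(out)
    if n_rand:
        out += random_windows(
            segment, matrix, n_rand, rng, cfg.window_s, transform=transform, **meta
        )
    return out


def load_recording(manifest: StudyManifest, participant_id: str,
                   device: str) -> ImuRecording:
    files = manifest.device_files.get(participant_id, {})
    if device == "head":
        return study_io.read_imu(files["head"], "head",
                                 participant_id=participant_id)
    return study_io.read_imu(
        files["hip_accel"], "hip", gyro_path=files["hip_gyro"],
        participant_id=participant_id,
    )


def ingest_study(
    study_dir: str | Path,
    cfg: IngestConfig | None = None,
    classes: list[str] | None = None,
) -> tuple[list[SensorImage], int]:
    """Full ingest of a study directory.

    Returns the labelled windows and the count of windows excluded for
    overlapping a segment boundary or falling in unannotated time.
    """
    cfg = cfg or IngestConfig()
    study_dir = Path(study_dir)
    manifest = study_io.read_manifest(study_dir)
    epochs = study_io.read_calorimetry(study_dir / "calorimetry.csv")
    labels = compute_labels(manifest, epochs, classes)
    rng = np.random.default_rng(cfg.seed)

    windows: list[SensorImage] = []
    for profile in manifest.profiles:
        pid = profile.participant_id
        recording = load_recording(manifest, pid, cfg.device)
        for segment in manifest.segments_of(pid):
            windows += windows_for_segment(
                recording, segment, cfg, rng, body_mass_kg=profile.body_mass_kg
            )
    labelled, excluded = label_windows(
        windows, labels, manifest.segments, cfg.window_s
    )
    return labelled, excluded


def to_arrays(
    windows: list[SensorImage],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, y, body_mass) model arrays.

    X is (N, T, C) uint8; y is (N, 2) with columns (class index, METs).
    """
    if not windows:
        raise ConfigError("no windows to stack")
    X = np.stack([w.matrix for w in windows])
    y = np.column_stack(
        [[w.class_index for w in windows], [w.mets for w in windows]]
    ).astype(float)
    mass = np.array([w.body_mass_kg for w in windows], dtype=float)
    return X, y, mass
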