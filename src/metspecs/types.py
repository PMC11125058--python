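"""Domain types shared across the pipeline.

The study records two wearable inertial devices per participant — a
head-mounted (eyeglass) unit sampling accelerometer and gyroscope at 128 Hz,
and a hip-worn unit sampling acceleration at 90 Hz and angular rate at
100 Hz — alongside indirect-calorimetry oxygen-uptake epochs and a manifest
of annotated activity segments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError, RangeError, ReferenceError_

#: (accel_hz, gyro_hz) per device position.
DEVICE_RATES: dict[str, tuple[float, float]] = {
    "head": (128.0, 128.0),
    "hip": (90.0, 100.0),
}

#: Hip accelerometer is up-sampled to the gyro rate before grouping.
HIP_ACCEL_TARGET_HZ = 100.0

ACCEL_CHANNELS = ("ax", "ay", "az")
GYRO_CHANNELS = ("gx", "gy", "gz")


@dataclass
class ImuRecording:
    """One device's timestamped 6-channel inertial stream.

    ``accel`` is an (n, 3) array in g; ``gyro`` an (m, 3) array in deg/s.
    The two blocks may have different lengths because the hip device samples
    them at different rates.
    """

    participant_id: str
    device: str
    accel: np.ndarray
    gyro: np.ndarray
    accel_rate_hz: float
    gyro_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.device not in DEVICE_RATES:
            raise ValueError(f"unknown device {self.device!r}")
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise IntegrityError("accel must be an (n, 3) array")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise IntegrityError("gyro must be an (m, 3) array")
        if self.accel_rate_hz <= 0 or self.gyro_rate_hz <= 0:
            raise IntegrityError("sampling rates must be strictly positive")

    @property
    def accel_duration_s(self) -> float:
        return self.accel.shape[0] / self.accel_rate_hz

    @property
    def gyro_duration_s(self) -> float:
        return self.gyro.shape[0] / self.gyro_rate_hz


@dataclass(frozen=True)
class ActivitySegment:
    """An annotated activity bout of one participant."""

    participant_id: str
    activity_label: str
    start_s: float
    stop_s: float
    weight_bearing: bool = True

    def __post_init__(self) -> None:
        if not self.stop_s > self.start_s:
            raise IntegrityError(
                f"segment stop ({self.stop_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    body_mass_kg: float

    def __post_init__(self) -> None:
        if not self.body_mass_kg > 0:
            raise ValueError("body_mass_kg must be positive")


@dataclass
class StudyManifest:
    """Participant table plus annotated segments plus device file paths."""

    profiles: list[ParticipantProfile]
    segments: list[ActivitySegment]
    device_files: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {p.participant_id for p in self.profiles}
        for seg in self.segments:
            if seg.participant_id not in ids:
                raise ReferenceError_(
                    f"segment references unknown participant {seg.participant_id!r}"
                )
        by_pid: dict[str, list[ActivitySegment]] = {}
        for seg in self.segments:
            by_pid.setdefault(seg.participant_id, []).append(seg)
        for pid, segs in by_pid.items():
            segs = sorted(segs, key=lambda s: s.start_s)
            for a, b in zip(segs, segs[1:]):
                if b.start_s < a.stop_s:
                    raise IntegrityError(
                        f"overlapping segments for participant {pid}: "
                        f"[{a.start_s}, {a.stop_s}) and [{b.start_s}, {b.stop_s})"
                    )

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.profiles]

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.participant_id == participant_id:
                return p
        raise ReferenceError_(f"unknown participant {participant_id!r}")

    def segments_of(self, participant_id: str) -> list[ActivitySegment]:
        return sorted(
            (s for s in self.segments if s.participant_id == participant_id),
            key=lambda s: s.start_s,
        )

    def total_minutes(self, participant_id: str) -> float:
        """Total labelled minutes: sum of segment durations."""
        return sum(s.duration_min for s in self.segments_of(participant_id))

    @property
    def total_minutes_by_participant(self) -> dict[str, float]:
        return {pid: self.total_minutes(pid) for pid in self.participant_ids}


@dataclass(frozen=True)
class CalorimetryEpoch:
    """A 30-s indirect-calorimetry epoch: mean VO2 in mL/min."""

    participant_id: str
    epoch_start_s: float
    vo2_ml_min: float
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.vo2_ml_min < 0:
            raise ValueError("vo2_ml_min must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def epoch_stop_s(self) -> float:
        return self.epoch_start_s + self.duration_s


@dataclass(frozen=True)
class SteadyStateLabel:
    """Per (participant, activity) ground truth: class index and METs."""

    participant_id: str
    activity_label: str
    class_index: int
    mets: float


@dataclass
class SensorImage:
    """One 10-s window encoded as an integer matrix in [0, 255].

    ``matrix`` is H x C where H = window seconds x sampling rate and C is the
    channel count of the sensor combination (6 for acc_gyr, 3 otherwise).
    """

    matrix: np.ndarray
    participant_id: str
    activity_label: str
    window_start_s: float
    combo: str
    kind: str  # "sequential" | "random"
    body_mass_kg: float = float("nan")
    mets: float = float("nan")
    class_index: int = -1
    device: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise RangeError("image matrix must be 2-D (time x channels)")
        if not np.issubdtype(m.dtype, np.integer):
            if not np.all(np.equal(np.mod(m, 1), 0)):
                raise RangeError("image matrix must be integer-valued")
            m = m.astype(np.int64)
        if m.size and (m.min() < 0 or m.max() > 255):
            raise RangeError(
                f"image values outside [0, 255]: min={m.min()}, max={m.max()}"
            )
        self.matrix = m.astype(np.uint8)
        if self.kind not in ("sequential", "random"):
            raise ValueError(f"unknown window kind {self.kind!r}")

    @property
    def height(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def provenance(self) -> tuple[str, str, float]:
        """(participant, activity, start) triple identifying the window."""
        return (self.participant_id, self.activity_label, round(self.window_start_s, 6))
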