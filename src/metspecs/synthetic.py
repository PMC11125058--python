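"""Synthetic study generator with known ground truth.

Emulates the study's four raw inputs — head- and hip-device IMU streams,
30-s calorimetry epochs, an annotation manifest, and a participant table —
for six structured activities (seated computer work, sweeping, stationary
cycling, walking, running, basketball). Signals are built from
activity-specific oscillations: each periodic activity contributes 1-3
harmonics of a movement cadence with device-specific amplitudes (hip
amplitudes exceed head amplitudes for gait), on top of gravity offsets and
Gaussian noise; basketball is broadband (band-passed noise bursts);
occasional gyro spikes beyond +/-400 deg/s exercise the clipping stage.

VO2 traces follow an exponential approach to each activity's target level
(base METs x a per-participant multiplier), so the steady-state MET value
implied by the generator's own parameters is known exactly and recorded in
an oracle file for round-trip testing.

The generator mimics the character of real inertial and metabolic data —
periodicity, gravity, inter-participant variability — not real biomechanics:
no posture changes, sensor drift, or within-activity pace variation.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, sosfilt

from .calorimetry import ML_O2_PER_KG_MIN_PER_MET, WEIGHT_BEARING_EXTRA_KG
from .errors import ConfigError
from .types import CalorimetryEpoch, DEVICE_RATES


@dataclass(frozen=True)
class ActivityProfile:
    """Signal and metabolic signature of one synthetic activity.

    ``fundamental_hz`` is the dominant movement cadence; 0 means static and
    None means broadband. Amplitude dicts are keyed by device position.
    """

    label: str
    fundamental_hz: float | None
    accel_amp_g: dict[str, float]
    gyro_amp_dps: dict[str, float]
    base_mets: float
    weight_bearing: bool = True
    n_harmonics: int = 3
    gyro_spike_per_min: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.accel_amp_g.values()):
            raise ConfigError("accel amplitudes must be non-negative")
        if any(v < 0 for v in self.gyro_amp_dps.values()):
            raise ConfigError("gyro amplitudes must be non-negative")
        if self.base_mets < 1.0:
            raise ConfigError("base_mets must be >= 1 (resting level)")


#: The six study activities with separable signatures. Amplitudes are chosen
#: so the hip sees gait harder than the head, cycling is leg-dominant (weak
#: at the head), and basketball is broadband and vigorous.
DEFAULT_PROFILES: tuple[ActivityProfile, ...] = (
    ActivityProfile(
        "basketball", None,
        {"head": 0.60, "hip": 1.00}, {"head": 120.0, "hip": 220.0},
        base_mets=6.5, gyro_spike_per_min=4.0,
    ),
    ActivityProfile(
        "computer", 0.0,
        {"head": 0.01, "hip": 0.005}, {"head": 2.0, "hip": 1.0},
        base_mets=1.3,
    ),
    ActivityProfile(
        "cycling", 1.2,
        {"head": 0.04, "hip": 0.30}, {"head": 8.0, "hip": 60.0},
        base_mets=5.0, weight_bearing=False,
    ),
    ActivityProfile(
        "running", 2.8,
        {"head": 0.70, "hip": 1.40}, {"head": 90.0, "hip": 260.0},
        base_mets=8.3, gyro_spike_per_min=2.0,
    ),
    ActivityProfile(
        "sweeping", 1.0,
        {"head": 0.12, "hip": 0.25}, {"head": 35.0, "hip": 55.0},
        base_mets=3.3,
    ),
    ActivityProfile(
        "walking", 1.8,
        {"head": 0.20, "hip": 0.45}, {"head": 30.0, "hip": 95.0},
        base_mets=3.5,
    ),
)

#: order in which activities are performed in a session
PROTOCOL_ORDER = ("computer", "sweeping", "cycling", "walking", "running",
                  "basketball")

#: gravity offsets (g) per accel channel; the z axis carries ~1 g
_ACCEL_OFFSET = np.array([0.05, -0.03, 1.0])

RESTING_METS = 1.0


@dataclass
class SyntheticStudyConfig:
    n_participants: int = 6
    activity_duration_s: float = 360.0
    gap_s: float = 20.0
    mass_range_kg: tuple[float, float] = (55.0, 100.0)
    met_multiplier_sd: float = 0.08
    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 2.0
    vo2_ramp_tau_s: float = 30.0
    vo2_noise_frac: float = 0.02
    epoch_s: float = 30.0
    profiles: tuple[ActivityProfile, ...] = DEFAULT_PROFILES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activity_duration_s < 60.0:
            raise ConfigError("activity durations must be >= 60 s")
        if self.n_participants < 1:
            raise ConfigError("need at least one participant")

    def profile(self, label: str) -> ActivityProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise ConfigError(f"no profile named {label!r}")


def synthesize_imu(
    profile: ActivityProfile,
    device: str,
    duration_s: float,
    rng: np.random.Generator,
    accel_noise_g: float = 0.02,
    gyro_noise_dps: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (accel (n, 3) in g, gyro (m, 3) in deg/s) for one activity."""
    acc_rate, gyr_rate = DEVICE_RATES[device]
    nyquist = min(acc_rate, gyr_rate) / 2.0
    f0 = profile.fundamental_hz
    if f0 is not None and f0 >= nyquist:
        raise ConfigError(
            f"fundamental {f0} Hz >= Nyquist {nyquist} Hz of device {device}"
        )
    n_acc = int(round(duration_s * acc_rate))
    n_gyr = int(round(duration_s * gyr_rate))
    a_amp = profile.accel_amp_g[device]
    g_amp = profile.gyro_amp_dps[device]

    accel = _ACCEL_OFFSET + rng.normal(0.0, accel_noise_g, size=(n_acc, 3))
    gyro = rng.normal(0.0, gyro_noise_dps, size=(n_gyr, 3))
    if f0 is None:  # broadband: band-passed noise bursts
        accel += _broadband(rng, n_acc, acc_rate, a_amp, 3)
        gyro += _broadband(rng, n_gyr, gyr_rate, g_amp, 3)
    elif f0 > 0:
        t_acc = np.arange(n_acc) / acc_rate
        t_gyr = np.arange(n_gyr) / gyr_rate
        for ch in range(3):
            for h in range(1, profile.n_harmonics + 1):
                phase = rng.uniform(0.0, 2 * np.pi)
                accel[:, ch] += (a_amp / h) * np.sin(
                    2 * np.pi * h * f0 * t_acc + phase
                )
                gyro[:, ch] += (g_amp / h) * np.sin(
                    2 * np.pi * h * f0 * t_gyr + phase + rng.uniform(0, 2 * np.pi)
                )
    _inject_gyro_spikes(gyro, profile.gyro_spike_per_min, duration_s, gyr_rate, rng)
    return accel, gyro


def _broadband(rng, n, rate, amp, n_ch, lo=0.5, hi=8.0):
    hi = min(hi, 0.45 * rate)
    sos = butter(2, [lo, hi], btype="band", fs=rate, output="sos")
    x = sosfilt(sos, rng.normal(0.0, 1.0, size=(n, n_ch)), axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    rms[rms == 0] = 1.0
    return x / rms * amp


def _inject_gyro_spikes(gyro, per_min, duration_s, rate, rng) -> None:
    n_spikes = rng.poisson(per_min * duration_s / 60.0)
    for _ in range(n_spikes):
        i = rng.integers(0, gyro.shape[0])
        ch = rng.integers(0, 3)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        width = int(rng.integers(2, 6))
        gyro[i : i + width, ch] += sign * rng.uniform(450.0, 900.0)


def synthesize_calorimetry(
    profile: ActivityProfile,
    participant_id: str,
    body_mass_kg: float,
    met_multiplier: float,
    duration_s: float,
    start_s: float,
    prev_mets: float,
    rng: np.random.Generator,
    ramp_tau_s: float = 30.0,
    noise_frac: float = 0.02,
    epoch_s: float = 30.0,
) -> tuple[list[CalorimetryEpoch], float]:
    """30-s VO2 epochs for one activity plus the implied steady-state METs.

    The instantaneous MET level decays exponentially from ``prev_mets``
    toward the target (base METs x participant multiplier); each epoch's VO2
    is the exact time average of that trajectory over the epoch, converted
    with the same mass convention the labelling pipeline inverts.
    """
    target = profile.base_mets * met_multiplier
    mass = body_mass_kg + (
        WEIGHT_BEARING_EXTRA_KG if profile.weight_bearing else 0.0
    )
    n_epochs = int(np.floor(duration_s / epoch_s))
    epochs = []
    for k in range(n_epochs):
        t0, t1 = k * epoch_s, (k + 1) * epoch_s
        if ramp_tau_s > 0:
            decay = (
                ramp_tau_s
                * (np.exp(-t0 / ramp_tau_s) - np.exp(-t1 / ramp_tau_s))
                / (t1 - t0)
            )
            met_avg = target + (prev_mets - target) * decay
        else:
            met_avg = target
        vo2 = met_avg * ML_O2_PER_KG_MIN_PER_MET * mass
        vo2 *= 1.0 + rng.normal(0.0, noise_frac) if noise_frac > 0 else 1.0
        epochs.append(
            CalorimetryEpoch(
                participant_id=participant_id,
                epoch_start_s=start_s + t0,
                vo2_ml_min=max(float(vo2), 0.0),
                duration_s=epoch_s,
            )
        )
    return epochs, target


def synthesize_study(config: SyntheticStudyConfig, out_dir: str | Path) -> Path:
    """Write a complete study directory consumable by the ingest pipeline.

    Layout: ``participants.csv``, ``annotations.csv``, ``calorimetry.csv``,
    ``imu/<pid>_head.csv``, ``imu/<pid>_hip_accel.csv``,
    ``imu/<pid>_hip_gyro.csv``, plus ``oracle.csv`` (true class and target
    steady-state METs per segment) and ``meta.yaml`` (the config, seed
    included). Deterministic given the seed.
    """
    out_dir = Path(out_dir)
    (out_dir / "imu").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    class_index = {lab: i for i, lab in
                   enumerate(sorted(PROTOCOL_ORDER))}
    participants, annotations, cal_rows, oracle_rows = [], [], [], []
    for p in range(config.n_participants):
        pid = str(101 + p)
        mass = round(float(rng.uniform(*config.mass_range_kg)), 1)
        multiplier = float(
            np.clip(1.0 + rng.normal(0.0, config.met_multiplier_sd), 0.7, 1.3)
        )
        participants.append({"participant_id": pid, "body_mass_kg": mass})

        # schedule segments
        t = 0.0
        segments = []
        for label in PROTOCOL_ORDER:
            segments.append((label, t, t + config.activity_duration_s))
            t += config.activity_duration_s + config.gap_s
        total_s = t - config.gap_s

        # IMU streams: rest-level noise everywhere, activity signals in place
        streams = {}
        for device in ("head", "hip"):
            acc_rate, gyr_rate = DEVICE_RATES[device]
            n_acc = int(round(total_s * acc_rate))
            n_gyr = int(round(total_s * gyr_rate))
            accel = _ACCEL_OFFSET + rng.normal(
                0.0, config.accel_noise_g, size=(n_acc, 3)
            )
            gyro = rng.normal(0.0, config.gyro_noise_dps, size=(n_gyr, 3))
            for label, s0, s1 in segments:
                prof = config.profile(label)
                a, g = synthesize_imu(
                    prof, device, s1 - s0, rng,
                    config.accel_noise_g, config.gyro_noise_dps,
                )
                ia, ig = int(round(s0 * acc_rate)), int(round(s0 * gyr_rate))
                accel[ia : ia + a.shape[0]] = a
                gyro[ig : ig + g.shape[0]] = g
            streams[device] = (accel, gyro)

        prev = RESTING_METS
        for label, s0, s1 in segments:
            prof = config.profile(label)
            annotations.append(
                {
                    "participant_id": pid, "activity": label,
                    "start_s": s0, "stop_s": s1,
                    "weight_bearing": prof.weight_bearing,
                }
            )
            epochs, target = synthesize_calorimetry(
                prof, pid, mass, multiplier, s1 - s0, s0, prev, rng,
                config.vo2_ramp_tau_s, config.vo2_noise_frac, config.epoch_s,
            )
            cal_rows += [
                {
                    "participant_id": e.participant_id,
                    "epoch_start_s": e.epoch_start_s,
                    "vo2_ml_min": round(e.vo2_ml_min, 3),
                }
                for e in epochs
            ]
            oracle_rows.append(
                {
                    "participant_id": pid, "activity": label,
                    "class_index": class_index[label],
                    "true_mets": round(target, 6),
                }
            )
            prev = target

        _write_imu_files(out_dir / "imu", pid, streams)

    pd.DataFrame(participants).to_csv(out_dir / "participants.csv", index=False)
    pd.DataFrame(annotations).to_csv(out_dir / "annotations.csv", index=False)
    pd.DataFrame(cal_rows).to_csv(out_dir / "calorimetry.csv", index=False)
    pd.DataFrame(oracle_rows).to_csv(out_dir / "oracle.csv", index=False)
    meta = asdict(config)
    meta["profiles"] = [asdict(p) for p in config.profiles]
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return out_dir


def _write_imu_files(imu_dir: Path, pid: str, streams: dict) -> None:
    acc_rate_h, gyr_rate_h = DEVICE_RATES["head"]
    accel, gyro = streams["head"]
    head = pd.DataFrame(
        {
            "timestamp": np.round(np.arange(accel.shape[0]) / acc_rate_h, 6),
            "ax": accel[:, 0], "ay": accel[:, 1], "az": accel[:, 2],
            "gx": gyro[:, 0], "gy": gyro[:, 1], "gz": gyro[:, 2],
        }
    )
    head.to_csv(imu_dir / f"{pid}_head.csv", index=False, float_format="%.5f")

    acc_rate, gyr_rate = DEVICE_RATES["hip"]
    accel, gyro = streams["hip"]
    pd.DataFrame(
        {
            "timestamp": np.round(np.arange(accel.shape[0]) / acc_rate, 6),
            "ax": accel[:, 0], "ay": accel[:, 1], "az": accel[:, 2],
        }
    ).to_csv(imu_dir / f"{pid}_hip_accel.csv", index=False, float_format="%.5f")
    pd.DataFrame(
        {
            "timestamp": np.round(np.arange(gyro.shape[0]) / gyr_rate, 6),
            "gx": gyro[:, 0], "gy": gyro[:, 1], "gz": gyro[:, 2],
        }
    ).to_csv(imu_dir / f"{pid}_hip_gyro.csv", index=False, float_format="%.5f")


def read_oracle(study_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(study_dir) / "oracle.csv",
                       dtype={"participant_id": str})
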