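"""Signal conditioning: resampling, gyro clipping, 8-bit rescaling, grouping.

The pipeline brings every channel to analysis form before imaging:

* the hip accelerometer (90 Hz) is up-sampled to the gyro rate (100 Hz) with
  a polyphase anti-aliasing resampler;
* gyroscope channels of both devices are clipped to +/-400 deg/s to remove
  extreme outliers (no other filtering is applied);
* each channel is mapped to integers in [0, 255] by the min-max rescale

      x_scaled = floor(NM + (x - x_min) / (x_max - x_min) * NMa)

  with NM = 0 and NMa = 255, the fractional part removed by floor;
* rescaled accelerometer and gyroscope channels are grouped into the three
  sensor combinations acc_gyr (6 columns), acc (3), gyr (3).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .errors import AlignmentError, ConfigError, DataError
from .types import ACCEL_CHANNELS, GYRO_CHANNELS

GYRO_CLIP_DPS = 400.0

COMBO_CHANNELS = {
    "acc_gyr": ACCEL_CHANNELS + GYRO_CHANNELS,
    "acc": ACCEL_CHANNELS,
    "gyr": GYRO_CHANNELS,
}

#: Min/max scope choices for :func:`rescale_floor` bounds.
RESCALE_SCOPES = ("window", "segment", "recording")


@dataclass
class RescaleParams:
    """Parameters of the 8-bit min-max rescale.

    ``nm``/``nma`` are the new minimum/maximum of the output range; ``x_min``
    and ``x_max`` are the input bounds actually used, computed over the
    configured ``scope`` (per 10-s window by default).
    """

    nm: float = 0.0
    nma: float = 255.0
    x_min: float | None = None
    x_max: float | None = None
    scope: str = "window"

    def __post_init__(self) -> None:
        if not self.nma > self.nm:
            raise ConfigError("nma must exceed nm")
        if self.scope not in RESCALE_SCOPES:
            raise ConfigError(f"unknown rescale scope {self.scope!r}")
        if (
            self.x_min is not None
            and self.x_max is not None
            and self.x_max < self.x_min
        ):
            raise ConfigError("x_max must be >= x_min")


@dataclass
class ChannelMatrix:
    """A T x C matrix of grouped channels with fixed column order."""

    values: np.ndarray
    channel_order: tuple[str, ...]
    sampling_rate_hz: float
    combo: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.combo not in COMBO_CHANNELS:
            raise ConfigError(f"unknown combo {self.combo!r}")
        expected = COMBO_CHANNELS[self.combo]
        if tuple(self.channel_order) != expected:
            raise ConfigError(
                f"channel order {self.channel_order} != expected {expected}"
            )
        if self.values.ndim != 2 or self.values.shape[1] != len(expected):
            raise AlignmentError(
                f"{self.combo} requires {len(expected)} columns, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def resample_to_rate(
    x: np.ndarray, source_hz: float, target_hz: float
) -> np.ndarray:
    """Resample a uniformly sampled series to ``target_hz``.

    Uses rational-rate polyphase resampling with anti-aliasing; output length
    is ``round(n * target_hz / source_hz)`` up to the resampler's ceiling
    convention, so the duration is preserved to within one output sample.
    """
    x = np.asarray(x, dtype=float)
    if source_hz <= 0 or target_hz <= 0:
        raise ConfigError("sampling rates must be positive")
    if x.size == 0:
        return x.copy()
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in input to resample_to_rate")
    ratio = Fraction(target_hz / source_hz).limit_denominator(10_000)
    if ratio == 1:
        return x.copy()
    # sharp kaiser anti-aliasing filter (passband ripple < 1e-6) and linear
    # edge extension to suppress boundary transients
    return resample_poly(
        x, ratio.numerator, ratio.denominator,
        window=("kaiser", 14.0), padtype="line",
    )


def clip_gyro(x: np.ndarray, bound: float = GYRO_CLIP_DPS) -> np.ndarray:
    """Clip angular-rate samples to [-bound, +bound] deg/s."""
    if bound <= 0:
        raise ConfigError("clip bound must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in input to clip_gyro")
    return np.clip(x, -bound, bound)


def rescale_floor(
    x: np.ndarray, params: RescaleParams | None = None
) -> np.ndarray:
    """Rescale one channel to integers in [nm, nma] and floor.

    Follows the printed min-max form literally (the new maximum multiplies
    the normalised signal; with nm = 0 this coincides with the conventional
    nm + (...) * (nma - nm)). A constant channel maps entirely to ``nm`` with
    a warning, guarding the zero division.
    """
    p = params or RescaleParams()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in input to rescale_floor")
    x_min = float(np.min(x)) if p.x_min is None else float(p.x_min)
    x_max = float(np.max(x)) if p.x_max is None else float(p.x_max)
    if x_max == x_min:
        warnings.warn(
            "constant channel in rescale_floor: mapping all samples to nm",
            stacklevel=2,
        )
        return np.full(x.shape, int(np.floor(p.nm)), dtype=np.int64)
    scaled = p.nm + (x - x_min) / (x_max - x_min) * p.nma
    out = np.floor(scaled).astype(np.int64)
    # guard against floating-point overshoot at the extremes
    return np.clip(out, int(np.floor(p.nm)), int(np.floor(p.nma)))


def group_channels(
    acc: np.ndarray, gyro: np.ndarray, combo: str, sampling_rate_hz: float
) -> ChannelMatrix:
    """Group rescaled accel/gyro channels into one sensor combination.

    ``acc`` and ``gyro`` are (T, 3) arrays in column order ax, ay, az and
    gx, gy, gz. For ``acc_gyr`` both must have equal length (the hip
    accelerometer is expected to be resampled to the gyro rate first).
    """
    if combo not in COMBO_CHANNELS:
        raise ConfigError(f"unknown combo {combo!r}")
    acc = np.asarray(acc)
    gyro = np.asarray(gyro)
    if combo == "acc":
        values = acc
    elif combo == "gyr":
        values = gyro
    else:
        if acc.shape[0] != gyro.shape[0]:
            raise AlignmentError(
                f"accel length {acc.shape[0]} != gyro length {gyro.shape[0]}"
            )
        values = np.concatenate([acc, gyro], axis=1)
    return ChannelMatrix(
        values=values,
        channel_order=COMBO_CHANNELS[combo],
        sampling_rate_hz=sampling_rate_hz,
        combo=combo,
    )
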