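"""10-s windowing of grouped channel matrices and grayscale-image codec.

Sequential windows are aligned to the activity-segment start and advance by a
fixed step (default: the window length, i.e. non-overlapping). Random windows
draw their start uniformly inside the segment and act as augmentation; test
sets use sequential windows only. Each window is stored as an 8-bit
single-channel (grayscale) PNG whose height is the sample count and whose
width is the channel count.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError, RangeError
from .preprocessing import ChannelMatrix
from .types import ActivitySegment, SensorImage

WINDOW_S = 10.0


def n_sequential_windows(duration_s: float, window_s: float = WINDOW_S,
                         step_s: float = WINDOW_S) -> int:
    """Number of full windows: floor((duration - window)/step) + 1, or 0."""
    if step_s <= 0:
        raise ConfigError("step_s must be positive")
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / step_s)) + 1


def _extract(matrix: ChannelMatrix, offset_s: float, window_s: float) -> np.ndarray:
    rate = matrix.sampling_rate_hz
    i0 = int(round(offset_s * rate))
    n = int(round(window_s * rate))
    return matrix.values[i0:i0 + n]


def _make_image(
    seg: ActivitySegment,
    matrix: ChannelMatrix,
    offset_s: float,
    window_s: float,
    kind: str,
    transform=None,
    **meta,
) -> SensorImage:
    values = _extract(matrix, offset_s, window_s)
    if transform is not None:
        values = transform(values)
    return SensorImage(
        matrix=values,
        participant_id=seg.participant_id,
        activity_label=seg.activity_label,
        window_start_s=seg.start_s + offset_s,
        combo=matrix.combo,
        kind=kind,
        **meta,
    )


def sequential_windows(
    segment: ActivitySegment,
    matrix: ChannelMatrix,
    window_s: float = WINDOW_S,
    step_s: float = WINDOW_S,
    transform=None,
    **meta,
) -> list[SensorImage]:
    """Cut fixed-stride windows aligned with the segment start.

    ``matrix`` must cover the segment from its start; the trailing partial
    window is discarded. ``transform`` (e.g. the window-scope 8-bit rescale)
    is applied to each extracted raw window before image construction. Extra
    keyword arguments (body_mass_kg, device, ...) are forwarded into every
    :class:`SensorImage`.
    """
    duration = min(segment.duration_s, matrix.duration_s)
    count = n_sequential_windows(duration, window_s, step_s)
    return [
        _make_image(segment, matrix, i * step_s, window_s, "sequential",
                    transform, **meta)
        for i in range(count)
    ]


def random_windows(
    segment: ActivitySegment,
    matrix: ChannelMatrix,
    n: int,
    rng: np.random.Generator,
    window_s: float = WINDOW_S,
    transform=None,
    **meta,
) -> list[SensorImage]:
    """Draw ``n`` windows with starts uniform in [0, duration - window].

    Starts are drawn in continuous time then snapped to the nearest sample.
    Reproducible given a seeded ``rng``.
    """
    duration = min(segment.duration_s, matrix.duration_s)
    if duration < window_s:
        warnings.warn(
            f"segment {segment.activity_label!r} shorter than the window; "
            "no random windows produced",
            stacklevel=2,
        )
        return []
    rate = matrix.sampling_rate_hz
    max_offset = duration - window_s
    out = []
    for _ in range(n):
        offset = float(rng.uniform(0.0, max_offset))
        offset = round(offset * rate) / rate  # snap to the sample grid
        offset = min(offset, max_offset)
        out.append(
            _make_image(segment, matrix, offset, window_s, "random",
                        transform, **meta)
        )
    return out


def encode_image(matrix: np.ndarray) -> Image.Image:
    """Encode an integer [0, 255] matrix as an 8-bit grayscale image."""
    m = np.asarray(matrix)
    if not np.issubdtype(m.dtype, np.integer):
        if m.size and not np.all(np.equal(np.mod(m, 1), 0)):
            raise RangeError("image matrix must be integer-valued")
        m = m.astype(np.int64)
    if m.size and (m.min() < 0 or m.max() > 255):
        raise RangeError("image values outside [0, 255]")
    return Image.fromarray(m.astype(np.uint8), mode="L")


def decode_image(img: Image.Image) -> np.ndarray:
    return np.asarray(img, dtype=np.uint8)


def save_image(matrix: np.ndarray, path: str | Path) -> None:
    encode_image(matrix).save(Path(path), format="PNG")


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as img:
        return decode_image(img.convert("L"))
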