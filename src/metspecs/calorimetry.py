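"""Indirect-calorimetry ground truth: VO2 -> METs and steady-state labels.

Oxygen uptake is exported as 30-s epochs (mL/min). Relative VO2 divides by
body mass; for weight-bearing activities 2 kg are added to the mass for the
worn calorimeter unit and harness. METs are relative VO2 over
3.5 mL/kg/min. The steady-state energy expenditure of an activity discards
the activity's final 30-s epoch and averages the four epochs immediately
preceding it. Each 10-s window that lies fully inside an annotated segment
inherits that activity's (class, MET) label; windows overlapping a segment
boundary (activity transitions) are excluded.
"""
from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, MetspecsError, ReferenceError_
from .types import (
    ActivitySegment,
    CalorimetryEpoch,
    SensorImage,
    StudyManifest,
    SteadyStateLabel,
)

ML_O2_PER_KG_MIN_PER_MET = 3.5
WEIGHT_BEARING_EXTRA_KG = 2.0

#: epochs averaged for steady state (the ones preceding the dropped final epoch)
STEADY_STATE_EPOCHS = 4


def relative_vo2(
    vo2_ml_min: float, body_mass_kg: float, weight_bearing: bool
) -> float:
    """Relative VO2 in mL/kg/min; +2 kg of worn-equipment mass if weight-bearing."""
    if body_mass_kg <= 0:
        raise MetspecsError("body_mass_kg must be positive")
    mass = body_mass_kg + (WEIGHT_BEARING_EXTRA_KG if weight_bearing else 0.0)
    return vo2_ml_min / mass


def vo2_to_mets(rel_vo2: float) -> float:
    """METs = relative VO2 / 3.5 mL/kg/min."""
    if rel_vo2 < 0:
        raise MetspecsError("relative VO2 must be non-negative")
    return rel_vo2 / ML_O2_PER_KG_MIN_PER_MET


def steady_state_mets(met_epochs: Sequence[float]) -> float:
    """Steady-state METs from an activity's ordered 30-s MET epochs.

    Drops the final epoch and returns the mean of the four epochs immediately
    preceding it; needs at least five epochs.
    """
    n = len(met_epochs)
    if n < STEADY_STATE_EPOCHS + 1:
        raise InsufficientDataError(
            f"steady state needs >= {STEADY_STATE_EPOCHS + 1} epochs, got {n}"
        )
    window = met_epochs[n - 1 - STEADY_STATE_EPOCHS : n - 1]
    return float(np.mean(window))


def epochs_in_segment(
    epochs: Iterable[CalorimetryEpoch], segment: ActivitySegment
) -> list[CalorimetryEpoch]:
    """Epochs whose full 30-s span lies inside the segment, in time order."""
    inside = [
        e
        for e in epochs
        if e.participant_id == segment.participant_id
        and e.epoch_start_s >= segment.start_s
        and e.epoch_stop_s <= segment.stop_s
    ]
    return sorted(inside, key=lambda e: e.epoch_start_s)


def class_order(labels: Iterable[str]) -> list[str]:
    """Deterministic class ordering: alphabetical over the label set."""
    return sorted(set(labels))


def compute_labels(
    manifest: StudyManifest,
    epochs: Sequence[CalorimetryEpoch],
    classes: Sequence[str] | None = None,
) -> list[SteadyStateLabel]:
    """One steady-state (class, MET) label per (participant, activity)."""
    classes = list(classes) if classes is not None else class_order(
        s.activity_label for s in manifest.segments
    )
    index = {label: i for i, label in enumerate(classes)}
    out = []
    for seg in manifest.segments:
        if seg.activity_label not in index:
            raise ReferenceError_(
                f"activity {seg.activity_label!r} not in class set {classes}"
            )
        seg_epochs = epochs_in_segment(epochs, seg)
        if len(seg_epochs) < STEADY_STATE_EPOCHS + 1:
            raise InsufficientDataError(
                f"activity {seg.activity_label!r} of participant "
                f"{seg.participant_id}: only {len(seg_epochs)} epochs inside "
                f"the segment, need {STEADY_STATE_EPOCHS + 1}"
            )
        mass = manifest.profile(seg.participant_id).body_mass_kg
        mets = steady_state_mets(
            [
                vo2_to_mets(relative_vo2(e.vo2_ml_min, mass, seg.weight_bearing))
                for e in seg_epochs
            ]
        )
        out.append(
            SteadyStateLabel(
                participant_id=seg.participant_id,
                activity_label=seg.activity_label,
                class_index=index[seg.activity_label],
                mets=mets,
            )
        )
    return out


def label_windows(
    windows: Iterable[SensorImage],
    labels: Sequence[SteadyStateLabel],
    segments: Sequence[ActivitySegment],
    window_s: float = 10.0,
) -> tuple[list[SensorImage], int]:
    """Attach (class, MET) labels to windows fully inside one segment.

    Returns the labelled windows and the count of excluded windows (those
    overlapping a segment boundary or lying in an unannotated gap —
    activity transitions are not analysed).
    """
    by_key = {(l.participant_id, l.activity_label): l for l in labels}
    labelled: list[SensorImage] = []
    excluded = 0
    for w in windows:
        seg = _covering_segment(w, segments, window_s)
        if seg is None:
            excluded += 1
            continue
        key = (seg.participant_id, seg.activity_label)
        if key not in by_key:
            raise ReferenceError_(f"no steady-state label for {key}")
        lab = by_key[key]
        w.activity_label = seg.activity_label
        w.class_index = lab.class_index
        w.mets = lab.mets
        labelled.append(w)
    return labelled, excluded


def _covering_segment(
    w: SensorImage, segments: Sequence[ActivitySegment], window_s: float
) -> ActivitySegment | None:
    start, stop = w.window_start_s, w.window_start_s + window_s
    eps = 1e-9
    for seg in segments:
        if (
            seg.participant_id == w.participant_id
            and start >= seg.start_s - eps
            and stop <= seg.stop_s + eps
        ):
            return seg
    return None
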