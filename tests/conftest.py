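"""Shared fixtures: a small synthetic study on disk and in-memory windows."""
from __future__ import annotations

import pytest

from metspecs.bench import make_mini_windows
from metspecs.dataset import IngestConfig, ingest_study
from metspecs.synthetic import SyntheticStudyConfig, synthesize_study

__all__ = ["make_mini_windows"]


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    """Three participants, 150-s bouts: enough epochs for steady state."""
    cfg = SyntheticStudyConfig(n_participants=3, activity_duration_s=150.0, seed=7)
    return synthesize_study(cfg, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def small_windows(small_study_dir):
    """Labelled hip-device acc_gyr windows of the small study."""
    cfg = IngestConfig(device="hip", combo="acc_gyr", random_per_segment=3, seed=7)
    windows, excluded = ingest_study(small_study_dir, cfg)
    return windows


@pytest.fixture(scope="session")
def mini_windows():
    return make_mini_windows()
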