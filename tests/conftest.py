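"""Shared fixtures: tiny rendered series and lightweight tracking stubs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@dataclass
class StubInstance:
    """Minimal detection stand-in for graph-tracking unit tests."""

    time: float
    centroid: tuple = (0.0, 0.0)
    truth_id: int | None = None
    area: float = 100.0
    frame_id: int = 0
    # assigned by build_graph
    vid: tuple | None = None
    frame_index: int | None = None


@pytest.fixture
def stub(request):
    return StubInstance


@pytest.fixture(scope="session")
def short_series():
    """One simulated day of trap frames with truth (session-cached)."""
    from chronotrap.pipeline import simulate_series

    return simulate_series(duration_h=24.0, seed=7)


@pytest.fixture(scope="session")
def short_detections(short_series):
    from chronotrap.pipeline import assign_truth, detect_series

    dets = detect_series(short_series.frames, short_series.frame_times)
    assign_truth(dets, short_series.tracks)
    return dets


@pytest.fixture(scope="session")
def trained_matcher(short_series, short_detections):
    """Matcher head trained on the short series' truth-annotated pairs."""
    from chronotrap.matching import NccDescriptor
    from chronotrap.pipeline import harvest_pairs
    from chronotrap.matching import LogisticMatchHead

    backend = NccDescriptor()
    X, y = harvest_pairs(short_detections, short_series.frames, backend, seed=7,
                         max_pairs=1500)
    head = LogisticMatchHead()
    head.fit(X, y, seed=7)
    return head, backend, X, y
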