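"""Shared fixtures: small hand-built logs and a simulated cohort."""

from __future__ import annotations

from datetime import datetime

import pandas as pd
import pytest

from timeoutmi import simulate, weblog


def _ts(text: str) -> datetime:
    return datetime.fromisoformat(text)


@pytest.fixture
def simple_events() -> list[weblog.PageViewEvent]:
    """Three views for one participant across two visits, one timed out."""
    return [
        weblog.PageViewEvent("A", 1, _ts("2010-01-04T09:00:00"),
                             _ts("2010-01-04T09:01:30"), "introduction",
                             "getting-ready-to-quit"),
        weblog.PageViewEvent("A", 1, _ts("2010-01-04T09:02:00"),
                             _ts("2010-01-04T09:32:00"), "core-content",
                             "quitting"),
        weblog.PageViewEvent("A", 2, _ts("2010-01-05T10:00:00"),
                             _ts("2010-01-05T10:00:00"), "testimonial",
                             "staying-quit"),
    ]


@pytest.fixture
def two_participant_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": ["A", "B"],
            "arm": [1, 0],
            "stratum": [1, 2],
            "age": [40, 50],
        }
    )


@pytest.fixture(scope="session")
def default_cohort() -> simulate.Cohort:
    """Q2-calibrated synthetic cohort, session-cached (read-only)."""
    config = simulate.SimulationConfig(n_participants=600, seed=20240901)
    return simulate.generate_cohort(config)


@pytest.fixture(scope="session")
def default_records(default_cohort) -> list[weblog.ViewingRecord]:
    events = weblog.events_from_frame(default_cohort.events)
    return weblog.compute_durations(events, default_cohort.config.timeout_min)
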