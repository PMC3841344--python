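"""Parse page-navigation event logs into per-page viewing durations.

A *page view* is one open-to-close interval on a single intervention
webpage. Views whose elapsed open-to-close time reaches the inactivity
time-out threshold carry no usable duration: the close stamp is the
forced logout, not the moment the participant stopped reading. Those
views are flagged ``timed_out`` and their duration is treated as
missing, to be multiply imputed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT_MIN = 30.0

EVENT_COLUMNS = [
    "participant_id",
    "visit_index",
    "open_time",
    "close_time",
    "page_type",
    "content_section",
]

RECORD_COLUMNS = [
    "participant_id",
    "position",
    "duration_min",
    "timed_out",
    "page_type",
    "content_section",
]


@dataclass(frozen=True)
class PageViewEvent:
    """One raw navigation event: a timestamp pair plus page metadata."""

    participant_id: str
    visit_index: int
    open_time: datetime
    close_time: Optional[datetime]  # None: no close stamp was logged
    page_type: str
    content_section: str


@dataclass(frozen=True)
class ViewingRecord:
    """A page view reduced to a duration (minutes) or a missing flag.

    ``position`` is the 1-based order of the view within the
    participant's full history, counted across visits. ``timed_out``
    is true iff ``duration_min`` is None.
    """

    participant_id: str
    position: int
    duration_min: Optional[float]
    timed_out: bool
    page_type: str
    content_section: str

    def __post_init__(self) -> None:
        if self.timed_out != (self.duration_min is None):
            raise ValueError(
                "timed_out must be true exactly when duration_min is absent"
            )


class DuplicateEventError(ValueError):
    """Two events share the same (participant_id, open_time)."""


def read_events(path) -> tuple[list[PageViewEvent], list[dict]]:
    """Read a comma-separated event log.

    Expects a header row with columns ``participant_id, visit_index,
    open_time, close_time, page_type, content_section``; timestamps are
    ISO-8601 at second resolution and ``close_time`` may be empty.

    Returns ``(events, rejections)``. Rows whose close precedes their
    open are rejected individually (and logged); a duplicate
    (participant, open_time) pair rejects the whole file.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event log is missing columns: {missing}")

    dup = frame.duplicated(subset=["participant_id", "open_time"])
    if dup.any():
        first = frame.loc[dup.idxmax()]
        raise DuplicateEventError(
            "duplicate (participant_id, open_time) pair: "
            f"({first['participant_id']}, {first['open_time']})"
        )

    open_times = pd.to_datetime(frame["open_time"], format="ISO8601")
    close_times = pd.to_datetime(frame["close_time"], format="ISO8601")

    events: list[PageViewEvent] = []
    rejections: list[dict] = []
    for i in range(len(frame)):
        row = frame.iloc[i]
        open_t = open_times.iloc[i].to_pydatetime()
        close_t = None if pd.isna(close_times.iloc[i]) else close_times.iloc[i].to_pydatetime()
        if close_t is not None and close_t < open_t:
            msg = (
                f"close_time precedes open_time for participant "
                f"{row['participant_id']} at {row['open_time']}"
            )
            logger.error("rejected event: %s", msg)
            rejections.append({"row": i, "reason": msg})
            continue
        events.append(
            PageViewEvent(
                participant_id=str(row["participant_id"]),
                visit_index=int(row["visit_index"]),
                open_time=open_t,
                close_time=close_t,
                page_type=str(row["page_type"]),
                content_section=str(row["content_section"]),
            )
        )
    return events, rejections


def events_from_frame(frame: pd.DataFrame) -> list[PageViewEvent]:
    """Build events from an in-memory event-log frame (no rejection logic).

    Intended for simulated cohorts where validity is guaranteed by
    construction; file input should go through :func:`read_events`.
    """
    open_times = pd.to_datetime(frame["open_time"], format="ISO8601")
    close_times = pd.to_datetime(frame["close_time"], format="ISO8601")
    events = []
    for i, row in enumerate(frame.itertuples(index=False)):
        close = close_times.iloc[i]
        events.append(
            PageViewEvent(
                participant_id=str(row.participant_id),
                visit_index=int(row.visit_index),
                open_time=open_times.iloc[i].to_pydatetime(),
                close_time=None if pd.isna(close) else close.to_pydatetime(),
                page_type=str(row.page_type),
                content_section=str(row.content_section),
            )
        )
    return events


def compute_durations(
    events: Sequence[PageViewEvent],
    timeout_min: float = DEFAULT_TIMEOUT_MIN,
) -> list[ViewingRecord]:
    """Convert navigation events into ViewingRecords.

    Elapsed open-to-close time below ``timeout_min`` becomes the
    duration in (fractional) minutes; elapsed time at or beyond the
    threshold marks the view timed-out with an absent duration. A view
    with no close stamp at all (e.g. the browser was killed) is also
    treated as timed-out; this case is logged prominently because the
    logging mechanism itself does not describe it.

    Positions are assigned 1-based per participant across all visits,
    in (visit_index, open_time) order.
    """
    if timeout_min <= 0:
        raise ValueError("timeout_min must be positive")

    by_participant: dict[str, list[PageViewEvent]] = {}
    for ev in events:
        by_participant.setdefault(ev.participant_id, []).append(ev)

    records: list[ViewingRecord] = []
    for pid, evs in by_participant.items():
        evs = sorted(evs, key=lambda e: (e.visit_index, e.open_time))
        for pos, ev in enumerate(evs, start=1):
            if ev.close_time is None:
                logger.warning(
                    "participant %s position %d has no close stamp; "
                    "treating the view as timed-out (duration missing)",
                    pid,
                    pos,
                )
                elapsed = None
            else:
                elapsed = (ev.close_time - ev.open_time).total_seconds() / 60.0
            timed_out = elapsed is None or elapsed >= timeout_min
            records.append(
                ViewingRecord(
                    participant_id=pid,
                    position=pos,
                    duration_min=None if timed_out else elapsed,
                    timed_out=timed_out,
                    page_type=ev.page_type,
                    content_section=ev.content_section,
                )
            )
    return records


def records_to_frame(records: Iterable[ViewingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "position": r.position,
                "duration_min": np.nan if r.duration_min is None else r.duration_min,
                "timed_out": r.timed_out,
                "page_type": r.page_type,
                "content_section": r.content_section,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[ViewingRecord]:
    records = []
    for row in frame.itertuples(index=False):
        timed_out = bool(row.timed_out)
        records.append(
            ViewingRecord(
                participant_id=str(row.participant_id),
                position=int(row.position),
                duration_min=None if timed_out else float(row.duration_min),
                timed_out=timed_out,
                page_type=str(row.page_type),
                content_section=str(row.content_section),
            )
        )
    return records


def write_records(records: Iterable[ViewingRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path) -> list[ViewingRecord]:
    return frame_to_records(pd.read_csv(path, dtype={"participant_id": str}))


def summarize_views(records: Sequence[ViewingRecord]) -> dict:
    """Summary counts and observed-duration quartiles.

    Median and IQR cover non-timed-out durations only; percentages are
    reported to two decimals (half-up). If every view timed out the
    median is flagged unavailable (None).
    """
    from .reporting import percent

    if not records:
        raise ValueError("record list is empty")

    n_views = len(records)
    n_timed_out = sum(r.timed_out for r in records)
    participants = {r.participant_id for r in records}
    participants_with_timeout = {r.participant_id for r in records if r.timed_out}
    observed = np.array(
        [r.duration_min for r in records if not r.timed_out], dtype=float
    )

    if observed.size:
        q1, med, q3 = np.percentile(observed, [25, 50, 75])
    else:
        q1 = med = q3 = None

    return {
        "n_participants": len(participants),
        "n_views": n_views,
        "n_timed_out": n_timed_out,
        "pct_timed_out": percent(n_timed_out, n_views),
        "n_participants_with_timeout": len(participants_with_timeout),
        "pct_participants_with_timeout": percent(
            len(participants_with_timeout), len(participants)
        ),
        "median_observed_min": med,
        "iqr_low_min": q1,
        "iqr_high_min": q3,
    }
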