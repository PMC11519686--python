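"""Interruption calendar and lagged intervention design matrix.

Eleven dated interruptions — eight COVID-19 vaccine rollout phases and three
pandemic-related events — are encoded as binary indicator columns on the
weekly grid.  Each indicator switches on a configurable number of weeks
after the event date (default 4, one month, so that an outcome asking about
the past 30 days can respond to the event).

Coding rules:

* **Vaccine rollout** phases form a single chronological sequence of
  mutually exclusive segments: a phase's column is 1 from its lagged onset
  up to (exclusive) the lagged onset of the next rollout phase; the last
  phase extends to the end of the series.
* **Pandemic-related events** are lasting shocks coded as permanent steps
  (1 from lagged onset to the series end).  Pulse and segment codings are
  available as options.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .weekly import DEFAULT_N_WEEKS, DEFAULT_START, week_index

logger = logging.getLogger(__name__)

VACCINE_ROLLOUT = "vaccine_rollout"
PANDEMIC_EVENT = "pandemic_event"


@dataclass(frozen=True)
class InterruptionEvent:
    """A dated interruption of the weekly series."""

    id: int
    date: dt.date
    label: str
    category: str  # vaccine_rollout | pandemic_event

    def __post_init__(self):
        if self.category not in (VACCINE_ROLLOUT, PANDEMIC_EVENT):
            raise ValueError(f"unknown event category: {self.category!r}")


def default_calendar() -> list[InterruptionEvent]:
    """The built-in 11-event interruption calendar, January 2020 – June 2022.

    Events 1, 2 and 7 are pandemic-related events; events 3–6 and 8–11 are
    successive phases of the US COVID-19 vaccine rollout.
    """
    raw = [
        (1, "2020-01-10", "SARS-CoV-2 identified and announced", PANDEMIC_EVENT),
        (2, "2020-03-13", "National emergency declaration", PANDEMIC_EVENT),
        (3, "2020-12-11", "Phase 1: healthcare workers and at-risk groups", VACCINE_ROLLOUT),
        (4, "2021-03-02", "Prioritization for educational/childcare workers", VACCINE_ROLLOUT),
        (5, "2021-04-19", "Phase 2: all individuals aged 16+", VACCINE_ROLLOUT),
        (6, "2021-05-10", "Authorization for adolescents aged 12-15", VACCINE_ROLLOUT),
        (7, "2021-07-30", "CDC guidance on Delta-variant breakthrough infections", PANDEMIC_EVENT),
        (8, "2021-09-22", "First booster for at-risk populations", VACCINE_ROLLOUT),
        (9, "2021-10-29", "Authorization for children aged 5-11", VACCINE_ROLLOUT),
        (10, "2021-11-21", "Booster for all US adults", VACCINE_ROLLOUT),
        (11, "2022-06-18", "Authorization for children aged 6 months to 5 years", VACCINE_ROLLOUT),
    ]
    return [
        InterruptionEvent(i, dt.date.fromisoformat(d), lab, cat) for i, d, lab, cat in raw
    ]


def load_calendar(path) -> list[InterruptionEvent]:
    """Load a calendar override from a YAML/JSON file.

    The file holds a list of mappings with keys id, date, label, category.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    events = [
        InterruptionEvent(
            id=int(e["id"]),
            date=dt.date.fromisoformat(str(e["date"])),
            label=str(e.get("label", f"event {e['id']}")),
            category=str(e["category"]),
        )
        for e in entries
    ]
    return validate_calendar(events)


def validate_calendar(events: list[InterruptionEvent]) -> list[InterruptionEvent]:
    events = sorted(events, key=lambda e: (e.date, e.id))
    ids = [e.id for e in events]
    if len(set(ids)) != len(ids):
        raise ValueError("event ids must be unique")
    if ids != sorted(ids):
        raise ValueError("event dates must be increasing with id")
    return events


def lagged_onset(
    event: InterruptionEvent,
    start_date: dt.date = DEFAULT_START,
    lag_weeks: int = 4,
) -> int:
    """0-based week index at which ``event``'s indicator switches on.

    The week containing the event date, plus ``lag_weeks`` whole weeks.
    May exceed the series length (the caller then gets an all-zero column).
    """
    if lag_weeks < 0:
        raise ValueError("lag_weeks must be non-negative")
    return week_index(event.date, start_date) + lag_weeks


@dataclass
class DesignMatrix:
    """Weeks x events binary indicator matrix :math:`I_k(t)`."""

    matrix: np.ndarray  # (n_weeks, n_events) of {0, 1}
    events: list[InterruptionEvent]
    lag_weeks: int
    start_date: dt.date
    coding: dict[int, str] = field(default_factory=dict)  # event id -> segment|step|pulse

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if set(np.unique(self.matrix)) - {0.0, 1.0}:
            raise ValueError("design matrix entries must be binary")
        if self.matrix.shape[1] != len(self.events):
            raise ValueError("one column per event required")

    @property
    def n_weeks(self) -> int:
        return self.matrix.shape[0]

    @property
    def column_names(self) -> list[str]:
        return [f"evt{e.id:02d}" for e in self.events]

    def column(self, event_id: int) -> np.ndarray:
        for j, e in enumerate(self.events):
            if e.id == event_id:
                return self.matrix[:, j]
        raise KeyError(f"no event with id {event_id}")

    def to_frame(self) -> pd.DataFrame:
        starts = [
            (self.start_date + dt.timedelta(weeks=t)).isoformat()
            for t in range(self.n_weeks)
        ]
        out = pd.DataFrame(self.matrix.astype(int), columns=self.column_names)
        out.insert(0, "week_start_date", starts)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_design_matrix(
    events: list[InterruptionEvent] | None = None,
    n_weeks: int = DEFAULT_N_WEEKS,
    start_date: dt.date = DEFAULT_START,
    lag_weeks: int = 4,
    pandemic_coding: str = "step",
) -> DesignMatrix:
    """Build the lagged binary design matrix for a weekly grid.

    Rollout phases are coded as mutually exclusive consecutive segments in
    chronological order; pandemic-related events as permanent steps by
    default (``pandemic_coding`` may be "step", "pulse" or "segment").
    Events whose lagged onset falls beyond the series end produce an
    all-zero column and a logged warning.
    """
    if events is None:
        events = default_calendar()
    events = validate_calendar(events)
    if pandemic_coding not in ("step", "pulse", "segment"):
        raise ValueError(f"unknown pandemic_coding: {pandemic_coding!r}")

    rollout = [e for e in events if e.category == VACCINE_ROLLOUT]
    if len({e.date for e in rollout}) != len(rollout):
        raise ValueError(
            "duplicate dates among vaccine_rollout events: segmentation undefined"
        )

    onsets = {e.id: lagged_onset(e, start_date, lag_weeks) for e in events}
    matrix = np.zeros((n_weeks, len(events)))
    coding: dict[int, str] = {}
    col_of = {e.id: j for j, e in enumerate(events)}

    # rollout phases: one chronological sequence of on-off segments
    for i, e in enumerate(rollout):
        on = onsets[e.id]
        off = onsets[rollout[i + 1].id] if i + 1 < len(rollout) else n_weeks
        coding[e.id] = "segment"
        if on >= n_weeks:
            logger.warning(
                "event %d (%s) lagged onset week %d is beyond the %d-week series; "
                "column is all zeros",
                e.id, e.label, on, n_weeks,
            )
            continue
        matrix[max(on, 0):min(off, n_weeks), col_of[e.id]] = 1.0

    # pandemic-related events
    pandemic = [e for e in events if e.category == PANDEMIC_EVENT]
    for i, e in enumerate(pandemic):
        on = onsets[e.id]
        coding[e.id] = pandemic_coding
        if on >= n_weeks:
            logger.warning(
                "event %d (%s) lagged onset week %d is beyond the %d-week series; "
                "column is all zeros",
                e.id, e.label, on, n_weeks,
            )
            continue
        if pandemic_coding == "pulse":
            if on >= 0:
                matrix[on, col_of[e.id]] = 1.0
        elif pandemic_coding == "segment":
            off = onsets[pandemic[i + 1].id] if i + 1 < len(pandemic) else n_weeks
            matrix[max(on, 0):min(off, n_weeks), col_of[e.id]] = 1.0
        else:  # permanent step
            matrix[max(on, 0):, col_of[e.id]] = 1.0

    return DesignMatrix(
        matrix=matrix,
        events=events,
        lag_weeks=lag_weeks,
        start_date=start_date,
        coding=coding,
    )
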