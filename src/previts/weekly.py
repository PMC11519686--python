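"""Weekly prevalence series container.

The unit of analysis throughout the package is a gap-free weekly series of
prevalence values in percentage points, anchored to a calendar of week-start
dates (ISO weeks, Monday-based).  Missing weeks are explicit NaNs, never
silent gaps.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Monday of ISO week 2019-W01, the first week of the default study window.
DEFAULT_START = dt.date(2018, 12, 31)

#: Number of ISO weeks from 2019-W01 through 2023-W08 inclusive.
DEFAULT_N_WEEKS = 217


def iso_week_start(date: dt.date) -> dt.date:
    """Monday of the ISO week containing ``date``."""
    return date - dt.timedelta(days=date.weekday())


def week_index(date: dt.date, start: dt.date) -> int:
    """0-based index of the week containing ``date`` in a weekly grid
    whose week 0 starts on the Monday of the week containing ``start``.

    Negative for dates before the grid start.
    """
    anchor = iso_week_start(start)
    return (iso_week_start(date) - anchor).days // 7


@dataclass
class WeeklySeries:
    """Ordered weekly prevalence values with calendar anchoring.

    Parameters
    ----------
    values
        Prevalence per week in percentage points (NaN = missing week).
    start_date
        Date inside the first week; snapped to the ISO week Monday.
    n_effective
        Optional per-week effective denominator (respondent count or
        weight sum), retained for reporting only.
    label
        Stratum or scenario label ("total" for the full population).
    enforce_bounds
        Require values in [0, 100].  True for survey-derived prevalence;
        model-generated series (whose Gaussian noise is unbounded) switch
        it off.
    """

    values: np.ndarray
    start_date: dt.date = DEFAULT_START
    n_effective: np.ndarray | None = None
    label: str = "total"
    enforce_bounds: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("WeeklySeries values must be one-dimensional")
        self.start_date = iso_week_start(self.start_date)
        finite = self.values[np.isfinite(self.values)]
        if self.enforce_bounds and finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("prevalence values must lie in [0, 100]")
        if self.n_effective is not None:
            self.n_effective = np.asarray(self.n_effective, dtype=float)
            if self.n_effective.shape != self.values.shape:
                raise ValueError("n_effective must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_weeks(self) -> int:
        return self.values.size

    @property
    def week_starts(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(weeks=int(t)) for t in range(len(self))]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "week_start_date": [d.isoformat() for d in self.week_starts],
                "prevalence_pct": self.values,
            }
        )
        out["n_effective"] = self.n_effective if self.n_effective is not None else np.nan
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "total") -> "WeeklySeries":
        dates = [dt.date.fromisoformat(str(d)[:10]) for d in frame["week_start_date"]]
        if len(dates) < 1:
            raise ValueError("empty weekly series")
        deltas = {(b - a).days for a, b in zip(dates, dates[1:])}
        if deltas - {7}:
            raise ValueError(
                "weekly calendar must be strictly increasing and gap-free "
                "(use NaN rows for missing weeks)"
            )
        n_eff = frame["n_effective"].to_numpy(float) if "n_effective" in frame else None
        return cls(
            values=frame["prevalence_pct"].to_numpy(float),
            start_date=dates[0],
            n_effective=n_eff,
            label=label,
            enforce_bounds=False,
        )

    @classmethod
    def read_csv(cls, path, label: str = "total") -> "WeeklySeries":
        return cls.from_frame(pd.read_csv(path), label=label)
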