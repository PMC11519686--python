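"""Binary outcome derivation and survey-weighted weekly prevalence.

The outcome is the BRFSS core mentally-unhealthy-days item ("for how many
days during the past 30 days was your mental health not good?").  Responses
are binarized at a >=15-day cutoff — the dichotomization that tracks a
PHQ-4 anxiety/depression screen at its clinical threshold — and aggregated
to survey-weighted weekly prevalence

    z_t = 100 * sum_i w_i y_i / sum_i w_i

over complete cases (don't-know/refused responses dropped).  Stratified
series use the study's standard groupings (age, sex, race/ethnicity,
household income, physical health, raising children).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .simulate import CODE_DONT_KNOW, CODE_NONE, CODE_REFUSED
from .weekly import WeeklySeries, iso_week_start, week_index

_LEGAL_DAYS = set(range(31)) | {CODE_DONT_KNOW, CODE_NONE, CODE_REFUSED}


def binarize_days(days: int, cutoff: int = 15) -> float:
    """Binarize one mentally-unhealthy-days response.

    Returns 1.0 for ``cutoff``..30 days, 0.0 for fewer, and NaN (missing)
    for the don't-know/refused codes 77/99.  Code 88 means zero days and
    maps to 0.  Any other value is rejected.
    """
    if not 1 <= cutoff <= 30:
        raise ValueError("cutoff must lie in 1..30")
    days = int(days)
    if days not in _LEGAL_DAYS:
        raise ValueError(f"illegal mentally-unhealthy-days value: {days}")
    if days in (CODE_DONT_KNOW, CODE_REFUSED):
        return float("nan")
    if days == CODE_NONE:
        return 0.0
    return 1.0 if days >= cutoff else 0.0


def binarize_column(days: pd.Series, cutoff: int = 15) -> pd.Series:
    """Vectorized :func:`binarize_days` over a microdata column."""
    if not 1 <= cutoff <= 30:
        raise ValueError("cutoff must lie in 1..30")
    d = pd.to_numeric(days, errors="raise").astype(int)
    illegal = ~d.isin(sorted(_LEGAL_DAYS))
    if illegal.any():
        bad = d[illegal]
        raise ValueError(
            f"illegal mentally-unhealthy-days values at records "
            f"{list(bad.index[:5])}: {list(bad.iloc[:5])}"
        )
    out = pd.Series(np.nan, index=d.index, dtype=float)
    out[d.isin([CODE_DONT_KNOW, CODE_REFUSED])] = np.nan
    real = ~d.isin([CODE_DONT_KNOW, CODE_REFUSED])
    zero = d == CODE_NONE
    out[real & zero] = 0.0
    out[real & ~zero] = (d[real & ~zero] >= cutoff).astype(float)
    return out


def _week_of(dates: pd.Series, start: dt.date) -> np.ndarray:
    return np.array(
        [week_index(dt.date.fromisoformat(str(s)[:10]), start) for s in dates]
    )


def weighted_weekly_prevalence(
    records: pd.DataFrame,
    cutoff: int = 15,
    stratum: dict[str, str] | None = None,
    start_date: dt.date | None = None,
    n_weeks: int | None = None,
    label: str = "total",
) -> WeeklySeries:
    """Survey-weighted weekly prevalence from microdata, in percentage points.

    ``stratum`` is an optional {column: level} filter applied before
    aggregation.  The weekly grid runs from ``start_date`` (default: week
    of the earliest interview) over ``n_weeks`` (default: through the week
    of the latest interview).  Weeks with no complete cases are NaN with a
    zero denominator.
    """
    df = records
    if stratum:
        for col, level in stratum.items():
            df = df[df[col] == level]
        if df.empty:
            raise ValueError(f"no records left after stratum filter {stratum}")
    if df.empty:
        raise ValueError("no records to aggregate")
    w = pd.to_numeric(df["weight"], errors="raise")
    if (w <= 0).any():
        bad = df.index[w <= 0][:5]
        raise ValueError(f"non-positive survey weights at records {list(bad)}")

    y = binarize_column(df["ment14d_days"], cutoff=cutoff)
    dates = [dt.date.fromisoformat(str(s)[:10]) for s in df["interview_date"]]
    if start_date is None:
        start_date = iso_week_start(min(dates))
    weeks = np.array([week_index(d, start_date) for d in dates])
    if n_weeks is None:
        n_weeks = int(weeks.max()) + 1

    num = np.zeros(n_weeks)
    den = np.zeros(n_weeks)
    n_eff = np.zeros(n_weeks)
    complete = y.notna().to_numpy()
    in_range = (weeks >= 0) & (weeks < n_weeks)
    sel = complete & in_range
    np.add.at(num, weeks[sel], (w.to_numpy() * y.to_numpy())[sel])
    np.add.at(den, weeks[sel], w.to_numpy()[sel])
    np.add.at(n_eff, weeks[sel], 1.0)

    values = np.full(n_weeks, np.nan)
    nonzero = den > 0
    values[nonzero] = 100.0 * num[nonzero] / den[nonzero]
    return WeeklySeries(
        values=values, start_date=start_date, n_effective=n_eff, label=label
    )


#: the stratification scheme: variable -> (derived column builder, levels)
STRATA_LEVELS: dict[str, list[str]] = {
    "age_group": ["18-64", "65+"],
    "sex": ["female", "male"],
    "race_ethnicity": ["hispanic", "nh_white", "nh_black", "nh_other_poc"],
    "income_band": ["<25k", "25-50k", ">=50k", "refused"],
    "phys_days_band": ["0-13", "14-30"],
    "raising_children": ["yes", "no", "refused"],
}


def _with_phys_band(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    phys = pd.to_numeric(df["phys_days"], errors="coerce")
    df["phys_days_band"] = np.where(phys <= 13, "0-13", "14-30")
    return df


def stratify(
    records: pd.DataFrame,
    cutoff: int = 15,
    start_date: dt.date | None = None,
    n_weeks: int | None = None,
    variables: list[str] | None = None,
) -> dict[str, WeeklySeries]:
    """One weekly series per level of each stratification variable.

    Returns a mapping ``"variable:level" -> WeeklySeries``; records whose
    level is not a recognized grouping are routed to an explicit
    ``"variable:unclassified"`` series rather than silently dropped.  A
    level with no records yields an all-missing series.
    """
    df = _with_phys_band(records)
    if start_date is None:
        dates = [dt.date.fromisoformat(str(s)[:10]) for s in df["interview_date"]]
        start_date = iso_week_start(min(dates))
    if n_weeks is None:
        dates = [dt.date.fromisoformat(str(s)[:10]) for s in df["interview_date"]]
        n_weeks = max(week_index(d, start_date) for d in dates) + 1

    out: dict[str, WeeklySeries] = {}
    for var in variables or list(STRATA_LEVELS):
        levels = STRATA_LEVELS[var]
        known = df[var].isin(levels)
        for level in levels:
            key = f"{var}:{level}"
            sub = df[df[var] == level]
            if sub.empty:
                out[key] = WeeklySeries(
                    values=np.full(n_weeks, np.nan),
                    start_date=start_date,
                    n_effective=np.zeros(n_weeks),
                    label=key,
                )
            else:
                out[key] = weighted_weekly_prevalence(
                    sub, cutoff=cutoff, start_date=start_date,
                    n_weeks=n_weeks, label=key,
                )
        if (~known).any():
            key = f"{var}:unclassified"
            out[key] = weighted_weekly_prevalence(
                df[~known], cutoff=cutoff, start_date=start_date,
                n_weeks=n_weeks, label=key,
            )
    return out
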