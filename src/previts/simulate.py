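"""Seeded synthetic weekly-prevalence series and survey microdata.

The generator emulates the statistical structure the downstream analysis
assumes: a weekly prevalence series (default 217 weeks, ISO 2019-W01
through 2023-W08) with a small linear drift, ARIMA-type noise (integrated
MA(1) by default), and lagged step intervention effects; plus BRFSS-style
respondent microdata whose survey-weighted binarized aggregation tracks a
target weekly series.

Generation model for the series::

    z_t = baseline + drift * t + sum_k delta_k * I_k(t) + u_t

where ``I_k`` is the lagged intervention design and ``u_t`` is ARMA(1,1)
noise, optionally integrated once (``d=1``).  Everything is deterministic
given the scenario seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .interventions import DesignMatrix, InterruptionEvent, build_design_matrix, default_calendar, lagged_onset
from .weekly import DEFAULT_N_WEEKS, DEFAULT_START, WeeklySeries

#: number of pre-sample draws discarded so that d=0 ARMA noise starts
#: (numerically) in its stationary regime
_BURN_IN = 300


@dataclass
class Scenario:
    """Parameters of one synthetic weekly-prevalence series.

    Units are percentage points throughout; ``drift`` is percentage points
    per week.  ``effects`` maps interruption-event ids to step effect sizes
    delta_k.  ``d`` selects white/ARMA noise (0) or once-integrated noise
    (1, the default, mirroring an ARIMA(0,1,1) outcome process).
    """

    n_weeks: int = DEFAULT_N_WEEKS
    start_date: dt.date = DEFAULT_START
    baseline: float = 12.0
    drift: float = 0.0
    ma_theta: float = 0.5
    ar_phi: float = 0.0
    innovation_sd: float = 1.0
    d: int = 1
    effects: dict[int, float] = field(default_factory=dict)
    lag_weeks: int = 4
    seed: int = 0
    calendar: list[InterruptionEvent] = field(default_factory=default_calendar)
    pandemic_coding: str = "step"

    def __post_init__(self):
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be at least 2")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be non-negative")
        if self.lag_weeks < 0:
            raise ValueError("lag_weeks must be non-negative")
        if self.d not in (0, 1):
            raise ValueError("d must be 0 or 1")
        ids = {e.id for e in self.calendar}
        unknown = set(self.effects) - ids
        if unknown:
            raise ValueError(f"effects reference unknown event ids: {sorted(unknown)}")

    def design(self) -> DesignMatrix:
        return build_design_matrix(
            self.calendar,
            n_weeks=self.n_weeks,
            start_date=self.start_date,
            lag_weeks=self.lag_weeks,
            pandemic_coding=self.pandemic_coding,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["start_date"] = self.start_date.isoformat()
        out["calendar"] = [
            {"id": e.id, "date": e.date.isoformat(), "label": e.label, "category": e.category}
            for e in self.calendar
        ]
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        data = dict(data)
        if "start_date" in data:
            data["start_date"] = dt.date.fromisoformat(data["start_date"])
        if "calendar" in data:
            data["calendar"] = [
                InterruptionEvent(
                    id=int(e["id"]),
                    date=dt.date.fromisoformat(e["date"]),
                    label=e.get("label", ""),
                    category=e["category"],
                )
                for e in data["calendar"]
            ]
        if "effects" in data and data["effects"]:
            data["effects"] = {int(k): float(v) for k, v in data["effects"].items()}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _arma_noise(rng: np.random.Generator, scenario: Scenario) -> np.ndarray:
    """ARMA(1,1) innovations path of length n_weeks (stationary start)."""
    phi, theta, sd = scenario.ar_phi, scenario.ma_theta, scenario.innovation_sd
    if sd == 0:
        return np.zeros(scenario.n_weeks)
    n = scenario.n_weeks + _BURN_IN
    e = rng.normal(0.0, sd, n + 1)
    u = np.empty(n)
    prev_u = 0.0
    for t in range(n):
        u[t] = phi * prev_u + e[t + 1] + theta * e[t]
        prev_u = u[t]
    return u[_BURN_IN:]


def simulate_weekly_series(scenario: Scenario) -> WeeklySeries:
    """Simulate one weekly prevalence series from a :class:`Scenario`.

    Raises if a nonzero effect is attached to an event whose lagged onset
    falls outside the simulated date range (the effect could never enter
    the series).
    """
    design = scenario.design()
    for event in scenario.calendar:
        if scenario.effects.get(event.id, 0.0) != 0.0:
            onset = lagged_onset(event, scenario.start_date, scenario.lag_weeks)
            if onset >= scenario.n_weeks or onset < 0:
                raise ValueError(
                    f"effect on event {event.id} ({event.date.isoformat()}) lies "
                    f"outside the simulated range of {scenario.n_weeks} weeks "
                    f"starting {scenario.start_date.isoformat()}"
                )

    delta = np.array([scenario.effects.get(e.id, 0.0) for e in design.events])
    t = np.arange(1, scenario.n_weeks + 1, dtype=float)
    rng = np.random.default_rng(scenario.seed)
    u = _arma_noise(rng, scenario)
    if scenario.d == 1:
        u = np.cumsum(u)
    z = scenario.baseline + scenario.drift * t + design.matrix @ delta + u
    return WeeklySeries(
        values=z, start_date=scenario.start_date, label="simulated",
        enforce_bounds=False,
    )


def theoretical_moments(scenario: Scenario) -> dict[str, float]:
    """Closed-form mean/variance/lag-1 autocovariance of the d=0 noise.

    Supports ARMA(p<=1, q<=1).  For ARMA(1,1),

        gamma_0 = sigma^2 (1 + theta^2 + 2 phi theta) / (1 - phi^2)
        gamma_1 = sigma^2 (1 + phi theta)(phi + theta) / (1 - phi^2)

    which reduce to the familiar MA(1) and AR(1) formulas when phi or theta
    vanish.
    """
    if scenario.d != 0:
        raise ValueError("theoretical moments are defined for d=0 noise only")
    phi, theta, s2 = scenario.ar_phi, scenario.ma_theta, scenario.innovation_sd ** 2
    if abs(phi) >= 1:
        raise ValueError(f"non-stationary AR coefficient phi={phi}: unsupported configuration")
    gamma0 = s2 * (1 + theta ** 2 + 2 * phi * theta) / (1 - phi ** 2)
    gamma1 = s2 * (1 + phi * theta) * (phi + theta) / (1 - phi ** 2)
    return {"mean": 0.0, "variance": gamma0, "autocov_lag1": gamma1}


# ---------------------------------------------------------------------------
# survey microdata
# ---------------------------------------------------------------------------

#: BRFSS-dialect special codes on the mentally-unhealthy-days item
CODE_NONE = 88       # "none" -> zero days
CODE_DONT_KNOW = 77
CODE_REFUSED = 99

# marginal composition used for the demographic attributes that are not the
# designated prevalence-shifting variable (plausible US-adult-survey shares)
_DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {"18-64": 0.77, "65+": 0.23},
    "sex": {"female": 0.51, "male": 0.49},
    "race_ethnicity": {
        "hispanic": 0.17, "nh_white": 0.61, "nh_black": 0.12, "nh_other_poc": 0.10,
    },
    "income_band": {"<25k": 0.16, "25-50k": 0.19, ">=50k": 0.44, "refused": 0.21},
    "raising_children": {"yes": 0.33, "no": 0.64, "refused": 0.03},
}


@dataclass
class MicrodataScenario:
    """Parameters of synthetic BRFSS-style respondent microdata.

    ``strata_mix`` gives, for one designated stratification variable
    (default ``sex``), each level's population share and its additive
    prevalence shift (percentage points); shifts are centred at
    construction so the share-weighted mean shift is zero and the weekly
    expectation matches the target series.  ``weight_lognorm_sigma``
    parameterizes the log-normal survey-weight law.
    """

    respondents_per_week: int = 500
    strata_variable: str = "sex"
    strata_mix: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (0.51, 0.0), "male": (0.49, 0.0)}
    )
    weight_lognorm_mu: float = 0.0
    weight_lognorm_sigma: float = 0.5
    missing_rate: float = 0.02
    zero_inflation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.respondents_per_week < 1:
            raise ValueError("respondents_per_week must be at least 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        shares = np.array([s for s, _ in self.strata_mix.values()], dtype=float)
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("strata_mix shares must sum to 1")
        # centre shifts so the mixture expectation equals the target
        shifts = np.array([d for _, d in self.strata_mix.values()], dtype=float)
        mean_shift = float(shares @ shifts)
        self.strata_mix = {
            lvl: (float(s), float(d) - mean_shift)
            for lvl, (s, d) in self.strata_mix.items()
        }


MICRODATA_COLUMNS = [
    "record_id", "interview_date", "ment14d_days", "weight",
    "age_group", "sex", "race_ethnicity", "income_band",
    "phys_days", "raising_children",
]


def simulate_microdata(
    mscenario: MicrodataScenario,
    target: WeeklySeries,
    cutoff: int = 15,
) -> pd.DataFrame:
    """Simulate respondent-level microdata tracking a target weekly series.

    For each week, draws ``respondents_per_week`` records with log-normal
    survey weights, stratum labels, interview dates inside the week, and a
    mentally-unhealthy-days response whose exceedance probability
    ``P(days >= cutoff)`` equals the week's target prevalence (shifted per
    stratum).  Special codes 77/99 appear at ``missing_rate``; zero days are
    coded 88.  Deterministic given the scenario seed.
    """
    rng = np.random.default_rng(mscenario.seed)
    m = mscenario.respondents_per_week
    levels = list(mscenario.strata_mix)
    shares = np.array([mscenario.strata_mix[l][0] for l in levels])
    shifts = np.array([mscenario.strata_mix[l][1] for l in levels])

    rows = []
    record_id = 0
    for t, (week_start, z) in enumerate(zip(target.week_starts, target.values)):
        if not np.isfinite(z):
            continue
        p = z / 100.0
        stratum_idx = rng.choice(len(levels), size=m, p=shares)
        p_i = np.clip(p + shifts[stratum_idx] / 100.0, 0.0, 1.0)
        exceed = rng.random(m) < p_i
        days = np.empty(m, dtype=int)
        # days >= cutoff, uniform over the exceedance range
        days[exceed] = rng.integers(cutoff, 31, size=int(exceed.sum()))
        # days < cutoff: zero-inflated low counts
        n_low = int((~exceed).sum())
        zero = rng.random(n_low) < mscenario.zero_inflation
        low = np.where(
            zero, CODE_NONE, rng.integers(max(1, min(cutoff - 1, 1)), cutoff, size=n_low)
        )
        days[~exceed] = low
        # special codes overwrite at missing_rate
        miss = rng.random(m) < mscenario.missing_rate
        special = rng.choice([CODE_DONT_KNOW, CODE_REFUSED], size=m)
        days = np.where(miss, special, days)

        weights = rng.lognormal(
            mscenario.weight_lognorm_mu, mscenario.weight_lognorm_sigma, m
        )
        offsets = rng.integers(0, 7, size=m)
        attrs = {}
        for var, marg in _DEFAULT_MARGINALS.items():
            lv = list(marg)
            pr = np.array([marg[l] for l in lv])
            attrs[var] = np.array(lv)[rng.choice(len(lv), size=m, p=pr / pr.sum())]
        attrs[mscenario.strata_variable] = np.array(levels)[stratum_idx]
        phys = np.minimum(rng.poisson(3.0, m), 30)

        for i in range(m):
            rows.append(
                (
                    record_id,
                    (week_start + dt.timedelta(days=int(offsets[i]))).isoformat(),
                    int(days[i]),
                    float(weights[i]),
                    attrs["age_group"][i],
                    attrs["sex"][i],
                    attrs["race_ethnicity"][i],
                    attrs["income_band"][i],
                    int(phys[i]),
                    attrs["raising_children"][i],
                )
            )
            record_id += 1

    return pd.DataFrame(rows, columns=MICRODATA_COLUMNS)
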