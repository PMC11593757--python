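"""Synthetic GDPPR-like cohort and measurement-event generator.

Emulates, with known ground truth, the structure of an England-wide
primary-care extract: a person table (demographics, deprivation quintile,
death month) and a record-level measurement-event table for 12
cardiometabolic risk-factor code clusters.  The generative monthly mean for
a person in subgroup *g*, factor *f* and calendar month *m* is

    mu = exp( base_f + effect_g
              + A_f * cos(2*pi*(pos(m) - phase_f)/12)
              + beta_year * t(m)
              + log g_f(m) )

where ``pos(m)`` is the month-of-year, ``t(m)`` the trend index in years
relative to March 2020 and ``g_f`` a multiplicative disruption profile
(step drop to ``depth`` at onset, exponential return with a configurable
half-life toward ``1 + post_offset``).  Counts are drawn overdispersed with
variance phi*mu via a Poisson-gamma mixture.  Curation contaminants
(under-18s, unknown sex, missing deprivation, same-day duplicates,
valueless records, deaths during follow-up) are injected at configurable
rates so every downstream filtering rule is exercisable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .months import as_month, month_position, month_range, trend_index

__all__ = [
    "FACTORS",
    "VALUELESS_EXEMPT",
    "AGE_BANDS",
    "SEXES",
    "ETHNICITIES",
    "IMD_QUINTILES",
    "Disruption",
    "ContaminantProbs",
    "ScenarioConfig",
    "generate_population",
    "generate_events",
    "true_expected_rate",
    "write_persons",
    "read_persons",
    "write_events",
    "read_events",
    "save_scenario",
    "load_scenario",
]

#: The 12 tracked risk-factor measurement clusters.
FACTORS = (
    "bmi",
    "smoking",
    "alcohol",
    "bp",
    "hba1c",
    "fasting_glucose",
    "total_cholesterol",
    "ldl_cholesterol",
    "hdl_cholesterol",
    "triglycerides",
    "lft",
    "egfr",
)

#: Factors whose records are retained even without a recorded value.
VALUELESS_EXEMPT = frozenset({"smoking", "alcohol"})

AGE_BANDS = ("18-39", "40-59", "60-79", "80+")
SEXES = ("female", "male")
ETHNICITIES = ("White", "Asian", "Black", "Mixed", "Other/Unknown")
IMD_QUINTILES = (1, 2, 3, 4, 5)

_AGE_SPAN = {"18-39": (18, 39), "40-59": (40, 59), "60-79": (60, 79), "80+": (80, 95)}


class ConfigError(ValueError):
    """Raised when a scenario configuration field is invalid."""


@dataclass(frozen=True)
class Disruption:
    """Multiplicative post-onset disruption profile for one factor.

    The profile is 1 before ``onset``; at onset it drops to ``depth`` and
    then returns exponentially, with the given half-life in months, toward
    a long-run level of ``1 + post_offset``.  ``depth=1`` means no
    disruption; an infinite half-life with ``post_offset = depth - 1``
    gives a sustained drop.
    """

    depth: float = 1.0
    onset: str = "2020-03"
    half_life: float = math.inf  # months
    post_offset: float = 0.0

    def multiplier(self, month) -> float:
        """Ground-truth disruption multiplier for a calendar month."""
        delta = (as_month(month) - as_month(self.onset)).n
        if delta < 0:
            return 1.0
        if math.isinf(self.half_life):
            return self.depth
        target = 1.0 + self.post_offset
        return target + (self.depth - target) * 0.5 ** (delta / self.half_life)


@dataclass(frozen=True)
class ContaminantProbs:
    """Per-person probabilities of curation contaminants."""

    under18: float = 0.25
    unknown_sex: float = 3e-5
    missing_imd: float = 0.004
    short_followup: float = 1e-4


def _default_baseline() -> Dict[str, float]:
    # Order-of-magnitude plausible per-person-month rates (synthetic; the
    # BP level matches the ~117/1,000 monthly rate implied by published
    # national summaries, others are loosely scaled to it).
    rates = {
        "bmi": 0.040,
        "smoking": 0.040,
        "alcohol": 0.030,
        "bp": 0.115,
        "hba1c": 0.060,
        "fasting_glucose": 0.010,
        "total_cholesterol": 0.050,
        "ldl_cholesterol": 0.020,
        "hdl_cholesterol": 0.045,
        "triglycerides": 0.030,
        "lft": 0.060,
        "egfr": 0.070,
    }
    return {f: math.log(r) for f, r in rates.items()}


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic study scenario.

    Subgroup proportions are given as four marginal distributions (age
    band, sex, ethnicity, IMD quintile) assumed independent; the implied
    full-cross mix is their product.  ``baseline_log_rate`` is the log
    expected number of measurements per person-month for the reference
    subgroup (youngest age band, female, White, IMD 1); additive log-rate
    subgroup effects shift it.
    """

    n_persons: int = 10_000
    start_month: str = "2018-11"
    end_month: str = "2024-03"
    age_mix: Dict[str, float] = field(
        default_factory=lambda: dict(zip(AGE_BANDS, (0.416, 0.324, 0.210, 0.050)))
    )
    sex_mix: Dict[str, float] = field(
        default_factory=lambda: dict(zip(SEXES, (0.503, 0.497)))
    )
    ethnicity_mix: Dict[str, float] = field(
        default_factory=lambda: dict(
            zip(ETHNICITIES, (0.777, 0.110, 0.042, 0.017, 0.054))
        )
    )
    imd_mix: Dict[int, float] = field(
        default_factory=lambda: dict(zip(IMD_QUINTILES, (0.201, 0.213, 0.205, 0.195, 0.186)))
    )
    baseline_log_rate: Dict[str, float] = field(default_factory=_default_baseline)
    age_effect: Dict[str, float] = field(
        default_factory=lambda: dict(zip(AGE_BANDS, (0.0, 0.35, 0.75, 0.95)))
    )
    sex_effect: Dict[str, float] = field(
        default_factory=lambda: dict(zip(SEXES, (0.0, -0.05)))
    )
    ethnicity_effect: Dict[str, float] = field(
        default_factory=lambda: dict(zip(ETHNICITIES, (0.0, 0.10, 0.05, 0.0, -0.05)))
    )
    imd_effect: Dict[int, float] = field(
        default_factory=lambda: dict(zip(IMD_QUINTILES, (0.05, 0.03, 0.0, -0.02, -0.03)))
    )
    seasonal_amplitude: Dict[str, float] = field(
        default_factory=lambda: {f: 0.10 for f in FACTORS}
    )
    seasonal_phase: Dict[str, float] = field(
        default_factory=lambda: {f: 10.0 for f in FACTORS}  # peak in November
    )
    annual_trend: float = -0.02  # log-rate change per year
    disruption: Dict[str, Disruption] = field(
        default_factory=lambda: {f: Disruption() for f in FACTORS}
    )
    dispersion_phi: float = 1.5
    dup_prob: float = 0.05
    valueless_prob: float = 0.05
    contaminants: ContaminantProbs = field(default_factory=ContaminantProbs)
    death_hazard: Dict[str, float] = field(
        default_factory=lambda: dict(
            zip(AGE_BANDS, (5e-5, 2e-4, 1.5e-3, 8e-3))
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be non-negative")
        if as_month(self.start_month) > as_month(self.end_month):
            raise ConfigError("start_month must not be after end_month")
        for name, mix in (
            ("age_mix", self.age_mix),
            ("sex_mix", self.sex_mix),
            ("ethnicity_mix", self.ethnicity_mix),
            ("imd_mix", self.imd_mix),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} has a negative proportion")
        if self.dispersion_phi < 1.0:
            raise ConfigError("dispersion_phi must be >= 1")
        for name, p in (
            ("dup_prob", self.dup_prob),
            ("valueless_prob", self.valueless_prob),
            ("contaminants.under18", self.contaminants.under18),
            ("contaminants.unknown_sex", self.contaminants.unknown_sex),
            ("contaminants.missing_imd", self.contaminants.missing_imd),
            ("contaminants.short_followup", self.contaminants.short_followup),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for f, d in self.disruption.items():
            if f not in FACTORS:
                raise ConfigError(f"disruption given for unknown factor {f!r}")
            if not 0.0 < d.depth <= 1.0:
                raise ConfigError(f"disruption.depth for {f!r} must be in (0, 1]")
            if d.half_life <= 0:
                raise ConfigError(f"disruption.half_life for {f!r} must be > 0")
        for f in self.baseline_log_rate:
            if f not in FACTORS:
                raise ConfigError(f"baseline_log_rate for unknown factor {f!r}")

    # -- derived --------------------------------------------------------
    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.start_month, self.end_month)

    @property
    def factors(self) -> Sequence[str]:
        return tuple(self.baseline_log_rate)

    def subgroup_mix(self) -> Dict[tuple, float]:
        """Implied full-cross subgroup proportions (product of marginals)."""
        mix = {}
        for a, pa in self.age_mix.items():
            for s, ps in self.sex_mix.items():
                for e, pe in self.ethnicity_mix.items():
                    for q, pq in self.imd_mix.items():
                        mix[(a, s, e, q)] = pa * ps * pe * pq
        return mix


def age_band_of(age: float) -> str:
    """Age band label for an age in years (bands start at 18)."""
    if age < 18:
        return "<18"
    if age < 40:
        return "18-39"
    if age < 60:
        return "40-59"
    if age < 80:
        return "60-79"
    return "80+"


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the person table for a scenario.

    Returns a DataFrame with one row per person: ``person_id``,
    ``age_at_index`` (years at the first study month), ``age_band``,
    ``sex``, ``ethnicity``, ``imd_quintile`` (nullable), ``death_month``
    (monthly Period, NaT if alive throughout) and ``months_followup``
    (months contributed to denominators, counting the death month).
    Deterministic given the scenario seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_persons
    n_months = len(config.months)

    bands = list(config.age_mix)
    band_idx = rng.choice(len(bands), size=n, p=list(config.age_mix.values()))
    lo = np.array([_AGE_SPAN[bands[i]][0] for i in band_idx])
    hi = np.array([_AGE_SPAN[bands[i]][1] for i in band_idx])
    age = lo + rng.integers(0, hi - lo + 1, size=n) if n else np.array([], dtype=int)

    sexes = list(config.sex_mix)
    sex = np.array(sexes, dtype=object)[
        rng.choice(len(sexes), size=n, p=list(config.sex_mix.values()))
    ]
    eths = list(config.ethnicity_mix)
    ethnicity = np.array(eths, dtype=object)[
        rng.choice(len(eths), size=n, p=list(config.ethnicity_mix.values()))
    ]
    quints = list(config.imd_mix)
    imd = np.array(quints, dtype=float)[
        rng.choice(len(quints), size=n, p=list(config.imd_mix.values()))
    ]

    # contaminants: each drawn independently per person
    c = config.contaminants
    under18 = rng.random(n) < c.under18
    if under18.any():
        age = age.copy()
        age[under18] = rng.integers(0, 18, size=int(under18.sum()))
    unknown_sex = rng.random(n) < c.unknown_sex
    sex[unknown_sex] = "unknown"
    missing = rng.random(n) < c.missing_imd
    imd[missing] = np.nan
    short = rng.random(n) < c.short_followup

    # death: geometric waiting time under a monthly hazard by age band
    hazard = np.array(
        [config.death_hazard.get(age_band_of(a), min(config.death_hazard.values(), default=0.0)) for a in age]
    )
    death_offset = np.full(n, -1, dtype=int)  # month index of death, -1 = none
    pos = hazard > 0
    if pos.any():
        wait = rng.geometric(hazard[pos])  # 1-based month of death
        died = wait <= n_months
        idx = np.flatnonzero(pos)[died]
        death_offset[idx] = wait[died] - 1

    months_followup = np.where(death_offset >= 0, death_offset + 1, n_months)
    months_followup[short] = 0

    start = as_month(config.start_month)
    death_month = pd.PeriodIndex(
        [start + int(o) if o >= 0 else pd.NaT for o in death_offset], freq="M"
    )

    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "age_at_index": age,
            "age_band": [age_band_of(a) for a in age],
            "sex": sex,
            "ethnicity": ethnicity,
            "imd_quintile": imd,
            "death_month": death_month,
            "months_followup": months_followup,
        }
    )
    return persons


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _monthly_log_components(config: ScenarioConfig, factor: str) -> np.ndarray:
    """Per-month log-scale component (seasonality + trend + disruption)."""
    months = config.months
    amp = config.seasonal_amplitude.get(factor, 0.0)
    phase = config.seasonal_phase.get(factor, 0.0)
    dis = config.disruption.get(factor, Disruption())
    out = np.empty(len(months))
    for j, m in enumerate(months):
        seas = amp * math.cos(2 * math.pi * (month_position(m) - phase) / 12.0)
        out[j] = (
            seas
            + config.annual_trend * trend_index(m)
            + math.log(dis.multiplier(m))
        )
    return out


def _person_log_effects(config: ScenarioConfig, persons: pd.DataFrame) -> np.ndarray:
    """Additive log-rate subgroup effect per person (contaminant-tolerant)."""
    age_eff = persons["age_band"].map(
        lambda b: config.age_effect.get(b, config.age_effect.get("18-39", 0.0))
    )
    sex_eff = persons["sex"].map(lambda s: config.sex_effect.get(s, 0.0))
    eth_eff = persons["ethnicity"].map(lambda e: config.ethnicity_effect.get(e, 0.0))
    imd_eff = persons["imd_quintile"].map(
        lambda q: config.imd_effect.get(int(q), 0.0) if pd.notna(q) else 0.0
    )
    return (age_eff + sex_eff + eth_eff + imd_eff).to_numpy(dtype=float)


def generate_events(persons: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Generate the measurement-event table for a generated population.

    One row per recorded event: ``person_id``, ``event_date`` (calendar
    day), ``factor``, ``value`` (NaN when the record carries no value).
    Counts per person-month-factor follow a Poisson-gamma mixture with
    mean mu and variance phi*mu; no event postdates its person's death
    month; same-day duplicate rows are appended at ``dup_prob``.
    """
    if persons is None or len(persons) == 0:
        raise ValueError("persons must be a non-empty population table")
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    months = config.months
    n_months = len(months)
    followup = persons["months_followup"].to_numpy()
    person_ids = persons["person_id"].to_numpy()
    eff = _person_log_effects(config, persons)
    phi = config.dispersion_phi

    alive = followup[:, None] > np.arange(n_months)[None, :]
    days_in_month = np.array([m.days_in_month for m in months])
    month_starts = np.array([m.to_timestamp() for m in months], dtype="datetime64[D]")

    frames = []
    for factor in config.factors:
        base = config.baseline_log_rate[factor]
        mu = np.exp(base + eff[:, None] + _monthly_log_components(config, factor)[None, :])
        mu = np.where(alive, mu, 0.0)
        if phi > 1.0:
            lam = np.zeros_like(mu)
            pos = mu > 0
            lam[pos] = rng.gamma(shape=mu[pos] / (phi - 1.0), scale=phi - 1.0)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)

        p_idx, m_idx = np.nonzero(counts)
        reps = counts[p_idx, m_idx]
        ev_person = np.repeat(person_ids[p_idx], reps)
        ev_month = np.repeat(m_idx, reps)
        n_ev = ev_person.size
        if n_ev == 0:
            continue
        day = rng.integers(0, days_in_month[ev_month])
        dates = month_starts[ev_month] + day.astype("timedelta64[D]")

        value = rng.normal(50.0, 10.0, size=n_ev)
        value[rng.random(n_ev) < config.valueless_prob] = np.nan
        # duplicated records carry the same content as the original
        dup = rng.random(n_ev) < config.dup_prob
        if dup.any():
            ev_person = np.concatenate([ev_person, ev_person[dup]])
            dates = np.concatenate([dates, dates[dup]])
            value = np.concatenate([value, value[dup]])
        frames.append(
            pd.DataFrame(
                {
                    "person_id": ev_person,
                    "event_date": pd.to_datetime(dates),
                    "factor": factor,
                    "value": value,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype=object),
                "event_date": pd.Series(dtype="datetime64[ns]"),
                "factor": pd.Series(dtype=object),
                "value": pd.Series(dtype=float),
            }
        )
    events = pd.concat(frames, ignore_index=True)
    return events


# ---------------------------------------------------------------------------
# ground-truth oracle
# ---------------------------------------------------------------------------

def true_expected_rate(
    config: ScenarioConfig,
    subgroup: Mapping[str, object],
    factor: str,
    month,
) -> float:
    """Closed-form generative expected rate per 1,000 persons per month.

    ``subgroup`` maps any of ``age_band``, ``sex``, ``ethnicity``,
    ``imd_quintile`` to a level; omitted dimensions contribute the
    reference effect 0.  Serves as the ground-truth oracle for recovery
    tests.
    """
    if factor not in config.baseline_log_rate:
        raise KeyError(f"unknown factor {factor!r}")
    m = as_month(month)
    if not (as_month(config.start_month) <= m <= as_month(config.end_month)):
        raise ValueError(f"month {m} outside scenario date range")
    eff = 0.0
    lookups = {
        "age_band": config.age_effect,
        "sex": config.sex_effect,
        "ethnicity": config.ethnicity_effect,
        "imd_quintile": config.imd_effect,
    }
    for key, value in subgroup.items():
        if key not in lookups:
            raise KeyError(f"unknown subgroup dimension {key!r}")
        table = lookups[key]
        if value not in table:
            raise KeyError(f"unknown level {value!r} for {key}")
        eff += table[value]
    amp = config.seasonal_amplitude.get(factor, 0.0)
    phase = config.seasonal_phase.get(factor, 0.0)
    dis = config.disruption.get(factor, Disruption())
    log_mu = (
        config.baseline_log_rate[factor]
        + eff
        + amp * math.cos(2 * math.pi * (month_position(m) - phase) / 12.0)
        + config.annual_trend * trend_index(m)
        + math.log(dis.multiplier(m))
    )
    return 1000.0 * math.exp(log_mu)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_persons(persons: pd.DataFrame, path) -> None:
    """Write the person table as headered CSV (empty field = missing)."""
    out = persons.copy()
    out["death_month"] = out["death_month"].astype(object).where(
        out["death_month"].notna(), ""
    )
    out.to_csv(path, index=False)


def read_persons(path) -> pd.DataFrame:
    persons = pd.read_csv(path, dtype={"person_id": str})
    dm = pd.PeriodIndex(
        [pd.Period(v, freq="M") if isinstance(v, str) and v else pd.NaT
         for v in persons["death_month"].fillna("")],
        freq="M",
    )
    persons["death_month"] = dm
    return persons


def write_events(events: pd.DataFrame, path) -> None:
    """Write the event table as headered CSV with ISO-8601 dates."""
    out = events.copy()
    out["event_date"] = out["event_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, dtype={"person_id": str})
    events["event_date"] = pd.to_datetime(events["event_date"])
    return events


def _scenario_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["disruption"] = {
        f: dataclasses.asdict(x) for f, x in config.disruption.items()
    }
    return d


def save_scenario(config: ScenarioConfig, path) -> None:
    """Write a scenario configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_scenario_to_dict(config), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    """Read a scenario configuration from YAML."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "disruption" in d:
        d["disruption"] = {
            f: Disruption(**{**x, "half_life": float(x.get("half_life", math.inf))})
            for f, x in d["disruption"].items()
        }
    if "contaminants" in d:
        d["contaminants"] = ContaminantProbs(**d["contaminants"])
    for key in ("imd_mix", "imd_effect"):
        if key in d:
            d[key] = {int(k): v for k, v in d[key].items()}
    return ScenarioConfig(**d)
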