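"""Shared test utilities: end-to-end runs and random fixture builders."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

import careband as cb
from careband import bands, curation, gam


def curated_rates(cfg, stratify=()):
    """simulate → curate → monthly rates for a scenario."""
    persons = cb.generate_population(cfg)
    events = cb.generate_events(persons, cfg)
    eligible, tally = curation.apply_exclusions(persons)
    ev = curation.drop_valueless(curation.dedup_events(events))
    rates = curation.monthly_rates(
        ev, eligible, cfg.start_month, cfg.end_month, stratify=stratify
    )
    return rates, eligible, tally


def fit_and_band(cfg, factor="bp", project_start="2020-03", project_end="2024-03"):
    """Full run for one factor; returns (model, monthly frame with band+observed)."""
    rates, _, _ = curated_rates(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = gam.fit_trend_model(rates, factor=factor)
    band = bands.expectation_band(model, cb.month_range(project_start, project_end))
    obs = rates.loc[rates["factor"] == factor, ["month", "rate"]]
    monthly = band.merge(obs.rename(columns={"rate": "observed"}), on="month")
    return model, monthly


def random_events(rng, n=60, n_persons=5, n_days=4, factors=("bp", "smoking")):
    """Small random event table exercising duplicates and missing values."""
    pid = rng.integers(0, n_persons, size=n)
    day = rng.integers(0, n_days, size=n)
    fac = rng.integers(0, len(factors), size=n)
    value = rng.normal(50, 10, size=n)
    value[rng.random(n) < 0.3] = np.nan
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in pid],
            "event_date": pd.to_datetime("2019-01-01")
            + pd.to_timedelta(day, unit="D"),
            "factor": [factors[i] for i in fac],
            "value": value,
        }
    )


def random_persons(rng, n=40):
    """Random person table with all contaminant kinds present."""
    age = rng.integers(0, 95, size=n)
    sex = np.where(rng.random(n) < 0.1, "unknown",
                   np.where(rng.random(n) < 0.5, "female", "male"))
    imd = rng.integers(1, 6, size=n).astype(float)
    imd[rng.random(n) < 0.15] = np.nan
    fu = rng.integers(0, 66, size=n)
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "age_at_index": age,
            "age_band": ["<18" if a < 18 else "18+" for a in age],
            "sex": sex,
            "ethnicity": "White",
            "imd_quintile": imd,
            "death_month": pd.PeriodIndex([pd.NaT] * n, freq="M"),
            "months_followup": fu,
        }
    )


def brute_force_tally(persons):
    """Independent per-person first-failing-rule evaluation."""
    counts = {"under18": 0, "unknown_sex": 0, "no_area": 0, "short": 0, "ok": 0}
    for _, row in persons.iterrows():
        if row["age_at_index"] < 18:
            counts["under18"] += 1
        elif row["sex"] == "unknown":
            counts["unknown_sex"] += 1
        elif pd.isna(row["imd_quintile"]):
            counts["no_area"] += 1
        elif row["months_followup"] < 1:
            counts["short"] += 1
        else:
            counts["ok"] += 1
    return counts
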