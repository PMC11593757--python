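"""Cohort and record curation: exclusion cascade, record filters, monthly rates.

The exclusion cascade removes, in fixed order, persons aged under 18 at the
index date, persons with unknown recorded sex, persons without a valid
residential area (modelled as a missing deprivation quintile) and persons
with less than one month of follow-up; each person is attributed to the
first rule they fail so the tally partitions the input.  Record filters
drop same-day duplicates of the same code cluster and, except for smoking
and alcohol, records without a value.  Monthly observed rates per 1,000 are
computed with denominators that count every eligible person alive during
any part of the month (censoring at the death month).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .months import as_month, month_range
from .synth import VALUELESS_EXEMPT

__all__ = [
    "ExclusionTally",
    "CurationError",
    "apply_exclusions",
    "dedup_events",
    "drop_valueless",
    "monthly_rates",
    "disclosure_round",
    "round_half_away",
    "composition_percent",
    "STRATA_COLUMNS",
]

#: Stratification dimensions available in the person table.
STRATA_COLUMNS = ("age_band", "sex", "ethnicity", "imd_quintile")


class CurationError(ValueError):
    """Raised when a curation computation cannot be completed."""


@dataclass(frozen=True)
class ExclusionTally:
    """Counts of persons removed by each rule of the exclusion cascade."""

    input_total: int
    excluded_under18: int
    excluded_unknown_sex: int
    excluded_no_area: int
    excluded_short_followup: int

    @property
    def included(self) -> int:
        return self.input_total - (
            self.excluded_under18
            + self.excluded_unknown_sex
            + self.excluded_no_area
            + self.excluded_short_followup
        )

    def to_dict(self) -> dict:
        d = {
            "input_total": self.input_total,
            "excluded_under18": self.excluded_under18,
            "excluded_unknown_sex": self.excluded_unknown_sex,
            "excluded_no_area": self.excluded_no_area,
            "excluded_short_followup": self.excluded_short_followup,
            "included": self.included,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_exclusions(
    persons: pd.DataFrame, index_age_column: str = "age_at_index"
) -> Tuple[pd.DataFrame, ExclusionTally]:
    """Apply the cohort exclusion cascade and return (eligible, tally).

    Rules are evaluated in the fixed order under-18 → unknown sex → no
    valid area → less than one month of follow-up; a person failing
    several rules is counted only under the first.
    """
    if len(persons) == 0:
        return persons.copy(), ExclusionTally(0, 0, 0, 0, 0)
    under18 = persons[index_age_column] < 18
    unknown_sex = ~under18 & (persons["sex"] == "unknown")
    no_area = ~under18 & ~unknown_sex & persons["imd_quintile"].isna()
    short = ~under18 & ~unknown_sex & ~no_area & (persons["months_followup"] < 1)
    eligible = persons[~(under18 | unknown_sex | no_area | short)].copy()
    tally = ExclusionTally(
        input_total=int(len(persons)),
        excluded_under18=int(under18.sum()),
        excluded_unknown_sex=int(unknown_sex.sum()),
        excluded_no_area=int(no_area.sum()),
        excluded_short_followup=int(short.sum()),
    )
    assert tally.included == len(eligible)
    return eligible, tally


def dedup_events(events: pd.DataFrame) -> pd.DataFrame:
    """Drop repeated same-day records of the same factor for a person.

    Keeps the first record in input order for each (person, factor, day)
    key; idempotent.
    """
    if len(events) == 0:
        return events.copy()
    day = events["event_date"].dt.normalize()
    keep = ~pd.DataFrame(
        {"p": events["person_id"], "f": events["factor"], "d": day}
    ).duplicated()
    return events[keep].copy()


def drop_valueless(events: pd.DataFrame) -> pd.DataFrame:
    """Drop records without a value, except smoking and alcohol records."""
    if len(events) == 0:
        return events.copy()
    keep = events["value"].notna() | events["factor"].isin(VALUELESS_EXEMPT)
    return events[keep].copy()


def monthly_rates(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    start_month,
    end_month,
    stratify: Sequence[str] = (),
) -> pd.DataFrame:
    """Monthly measurement counts and rates per 1,000 eligible persons.

    ``persons`` must already be the eligible cohort; events of persons not
    in it are ignored.  The denominator for month *m* is the number of
    persons whose follow-up covers any part of *m* (a person contributes
    through their death month).  ``stratify`` is a subset of
    ``STRATA_COLUMNS``; the result has one row per factor × stratum ×
    month with columns ``factor``, the stratification columns, ``month``
    (Period), ``count``, ``denominator`` and ``rate``.

    Raises :class:`CurationError` if any reported month has a zero
    denominator.
    """
    stratify = tuple(stratify)
    for col in stratify:
        if col not in STRATA_COLUMNS:
            raise CurationError(f"unknown stratification column {col!r}")
    months = month_range(start_month, end_month)
    start = months[0]
    n_months = len(months)

    # denominators: persons alive during month index m  (m < months_followup)
    followup = persons["months_followup"].to_numpy()

    def denom_profile(fu: np.ndarray) -> np.ndarray:
        # number of persons with months_followup > m, for m = 0..n_months-1
        counts = np.bincount(np.clip(fu, 0, n_months), minlength=n_months + 1)
        alive = len(fu) - np.cumsum(counts[:-1])
        return alive

    if stratify:
        groups = persons.groupby(list(stratify), dropna=False, observed=True)
    else:
        groups = [((), persons)]

    ev = events.merge(
        persons[["person_id", *stratify, "months_followup"]],
        on="person_id",
        how="inner",
    )
    ev_month = pd.PeriodIndex(ev["event_date"].dt.to_period("M"))
    ev = ev.assign(_midx=(ev_month - start).map(lambda o: o.n))
    # an event only counts while its person is in follow-up
    ev = ev[
        (ev["_midx"] >= 0)
        & (ev["_midx"] < n_months)
        & (ev["_midx"] < ev["months_followup"])
    ]

    out_frames = []
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        denom = denom_profile(grp["months_followup"].to_numpy())
        if (denom == 0).any():
            bad = [str(months[i]) for i in np.flatnonzero(denom == 0)[:5]]
            raise CurationError(
                f"zero denominator for stratum {dict(zip(stratify, key))} "
                f"in months {bad}"
            )
        if stratify:
            mask = np.ones(len(ev), dtype=bool)
            for col, val in zip(stratify, key):
                if pd.isna(val):
                    mask &= ev[col].isna().to_numpy()
                else:
                    mask &= (ev[col] == val).to_numpy()
            sub = ev[mask]
        else:
            sub = ev
        for factor, fgrp in sub.groupby("factor", observed=True):
            counts = np.bincount(fgrp["_midx"], minlength=n_months)
            frame = pd.DataFrame(
                {
                    "factor": factor,
                    "month": months,
                    "count": counts,
                    "denominator": denom,
                }
            )
            for col, val in zip(stratify, key):
                frame[col] = val
            out_frames.append(frame)

    if not out_frames:
        return pd.DataFrame(
            columns=["factor", *stratify, "month", "count", "denominator", "rate"]
        )
    out = pd.concat(out_frames, ignore_index=True)
    out["rate"] = out["count"] / out["denominator"] * 1000.0
    cols = ["factor", *stratify, "month", "count", "denominator", "rate"]
    return out[cols].sort_values(["factor", *stratify, "month"]).reset_index(drop=True)


def disclosure_round(counts) -> np.ndarray:
    """Round counts to the nearest multiple of 5, ties away from zero.

    Applied only when publishing outputs, never before modelling.
    """
    x = np.asarray(counts, dtype=float)
    rounded = 5.0 * np.sign(x) * np.floor(np.abs(x) / 5.0 + 0.5)
    if np.issubdtype(np.asarray(counts).dtype, np.integer):
        return rounded.astype(np.int64)
    return rounded


def round_half_away(x, decimals: int = 1):
    """Decimal rounding with ties away from zero (publication convention)."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def composition_percent(count, total, decimals: int = 1):
    """Percentage share of ``count`` in ``total``, rounded for publication."""
    return round_half_away(100.0 * np.asarray(count, dtype=float) / total, decimals)
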