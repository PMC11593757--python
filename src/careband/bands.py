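"""Counterfactual projections, composite expectation bands and deviations.

Two counterfactual projections of the fitted pre-pandemic model give the
expected monthly rate after March 2020: the *continued-trend* projection
evaluates the model at each month's true trend index, the *frozen-trend*
projection clamps the trend index at 0 from March 2020 onward.  Their 95%
confidence intervals are combined into a composite expectation band — the
union of the two intervals (minimum of lower bounds, maximum of upper
bounds) — whose midpoint is the point estimate of the expected level.
Deviations are observed minus expected (per 1,000) and the same difference
relative to the expected level (in %), per month or averaged over summary
periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gam import FittedTrendModel, Z_95
from .months import as_month, month_range

__all__ = [
    "BandError",
    "SummaryPeriod",
    "DEFAULT_PERIODS",
    "project",
    "composite_band",
    "band_midpoint",
    "expectation_band",
    "deviation",
    "period_summary",
    "aggregate_overall",
]


class BandError(ValueError):
    """Raised for ill-formed intervals or incomplete inputs."""


@dataclass(frozen=True)
class SummaryPeriod:
    """A labelled contiguous month range used for reporting."""

    label: str
    start: str
    end: str

    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.start, self.end)


#: The three reporting periods: the restrictions era and two recovery years.
DEFAULT_PERIODS = (
    SummaryPeriod("Mar 2020-Feb 2022", "2020-03", "2022-02"),
    SummaryPeriod("Mar 2022-Feb 2023", "2022-03", "2023-02"),
    SummaryPeriod("Mar 2023-Mar 2024", "2023-03", "2024-03"),
)


def _strata_frame(model: FittedTrendModel, months) -> pd.DataFrame:
    """Cartesian product of projection months with the model's strata."""
    months = [as_month(m) for m in months]
    frame = pd.DataFrame({"month": pd.PeriodIndex(months, freq="M")})
    for dim in model.info.stratify:
        levels = pd.DataFrame({dim: model.info.levels[dim]})
        frame = frame.merge(levels, how="cross")
    return frame


def project(
    model: FittedTrendModel,
    months,
    frozen_trend: bool = False,
    newdata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Project expected rates per 1,000 with 95% Wald intervals.

    Returns one row per month × stratum with columns ``rate``, ``lo`` and
    ``hi``, where rate = 1000 * exp(eta) and the interval is
    1000 * exp(eta ± z * se(eta)).  ``frozen_trend`` selects the
    stable-trend counterfactual.
    """
    if newdata is None:
        newdata = _strata_frame(model, months)
    eta, se = model.predict_eta(newdata, frozen_trend=frozen_trend)
    out = newdata.copy()
    out["rate"] = 1000.0 * np.exp(eta)
    out["lo"] = 1000.0 * np.exp(eta - Z_95 * se)
    out["hi"] = 1000.0 * np.exp(eta + Z_95 * se)
    return out


def composite_band(
    lo_a, hi_a, lo_b, hi_b
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of two confidence intervals: (L, U, midpoint).

    L = min of lower bounds, U = max of upper bounds, midpoint = (L+U)/2.
    """
    lo_a, hi_a = np.asarray(lo_a, dtype=float), np.asarray(hi_a, dtype=float)
    lo_b, hi_b = np.asarray(lo_b, dtype=float), np.asarray(hi_b, dtype=float)
    if np.any(lo_a > hi_a) or np.any(lo_b > hi_b):
        raise BandError("component interval has lower bound above upper bound")
    L = np.minimum(lo_a, lo_b)
    U = np.maximum(hi_a, hi_b)
    return L, U, band_midpoint(L, U)


def band_midpoint(L, U):
    """Point estimate of the expected level: the band midpoint (L+U)/2."""
    L, U = np.asarray(L, dtype=float), np.asarray(U, dtype=float)
    if np.any(L > U):
        raise BandError("band lower bound exceeds upper bound")
    mid = (L + U) / 2.0
    return float(mid) if mid.ndim == 0 else mid


def expectation_band(model: FittedTrendModel, months) -> pd.DataFrame:
    """Composite expectation band per month × stratum.

    Columns: component intervals ``lo_cont``/``hi_cont`` (continued trend)
    and ``lo_froz``/``hi_froz`` (frozen trend), band ``L``, ``U`` and
    midpoint ``E``, all rates per 1,000.
    """
    cont = project(model, months, frozen_trend=False)
    froz = project(model, months, frozen_trend=True)
    out = cont.drop(columns=["rate", "lo", "hi"]).copy()
    out["rate_cont"] = cont["rate"].to_numpy()
    out["lo_cont"] = cont["lo"].to_numpy()
    out["hi_cont"] = cont["hi"].to_numpy()
    out["rate_froz"] = froz["rate"].to_numpy()
    out["lo_froz"] = froz["lo"].to_numpy()
    out["hi_froz"] = froz["hi"].to_numpy()
    L, U, E = composite_band(
        out["lo_cont"], out["hi_cont"], out["lo_froz"], out["hi_froz"]
    )
    out["L"], out["U"], out["E"] = L, U, E
    return out


def deviation(observed, L, U) -> pd.DataFrame:
    """Absolute and relative deviation of observed rates from a band.

    Absolute: O - E with interval (O - U, O - L).  Relative:
    100 * (O - E) / E with interval endpoints evaluated at E = U and
    E = L respectively (the conservative bound uses the matching band
    edge).  Requires a strictly positive expected midpoint.
    """
    O = np.asarray(observed, dtype=float)
    L = np.asarray(L, dtype=float)
    U = np.asarray(U, dtype=float)
    E = (L + U) / 2.0
    if np.any(E <= 0):
        raise BandError("relative deviation undefined: band midpoint <= 0")
    if np.any(L > U):
        raise BandError("band lower bound exceeds upper bound")
    return pd.DataFrame(
        {
            "observed": O,
            "expected": E,
            "d_abs": O - E,
            "d_abs_lo": O - U,
            "d_abs_hi": O - L,
            "d_rel": 100.0 * (O - E) / E,
            "d_rel_lo": 100.0 * (O - U) / U,
            "d_rel_hi": 100.0 * (O - L) / L,
        }
    )


def period_summary(
    monthly: pd.DataFrame,
    period: SummaryPeriod,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Summarize deviations over a reporting period.

    ``monthly`` must hold one row per month (per stratum if ``by`` is
    given) with columns ``month``, ``observed``, ``L`` and ``U``.  The
    monthly observed rate and band bounds are averaged over the period's
    months, the period midpoint is the midpoint of the averaged band and
    deviations follow as for a single month.  Raises
    :class:`BandError` listing any missing months.
    """
    by = list(by)
    months = set(period.months)
    mcol = pd.PeriodIndex([as_month(m) for m in monthly["month"]])
    sel = monthly[mcol.isin(list(months))]

    def summarize(grp: pd.DataFrame) -> pd.Series:
        have = {as_month(m) for m in grp["month"]}
        missing = sorted(str(m) for m in months - have)
        if missing:
            raise BandError(
                f"period {period.label!r} missing months: {missing}"
            )
        O = grp["observed"].mean()
        L = grp["L"].mean()
        U = grp["U"].mean()
        dev = deviation([O], [L], [U]).iloc[0]
        fields = dev.drop(labels=["observed"]).to_dict()
        return pd.Series(
            {"period": period.label, "observed": O, "L": L, "U": U, **fields}
        )

    if by:
        out = (
            sel.groupby(by, dropna=False, observed=True)
            .apply(summarize, include_groups=False)
            .reset_index()
        )
    else:
        out = summarize(sel).to_frame().T.reset_index(drop=True)
    return out


def aggregate_overall(
    band: pd.DataFrame,
    denominators: pd.DataFrame,
    by: Sequence[str],
) -> pd.DataFrame:
    """Aggregate stratum-level expectations to an overall series.

    Aggregation is in count space: expected counts (rate × N / 1000) are
    summed over strata and divided by the total denominator; band bounds
    are aggregated the same way.  ``denominators`` must hold ``month``,
    the stratum columns and ``denominator`` for the complete partition;
    an inconsistent stratum set across months raises :class:`BandError`.
    """
    by = list(by)
    merged = band.merge(denominators[["month", *by, "denominator"]], on=["month", *by])
    if len(merged) != len(band):
        raise BandError("denominators do not cover every stratum-month of the band")
    counts_per_month = merged.groupby("month", observed=True)[by[0]].count()
    if counts_per_month.nunique() > 1:
        raise BandError("inconsistent stratum sets across months")

    w = merged["denominator"].to_numpy(dtype=float)
    agg_cols = [c for c in ("rate_cont", "lo_cont", "hi_cont", "rate_froz",
                            "lo_froz", "hi_froz", "L", "U", "E") if c in merged]
    for c in agg_cols:
        merged[c] = merged[c].to_numpy() * w / 1000.0  # expected counts
    g = merged.groupby("month", observed=True)
    out = g[agg_cols].sum()
    out = out.div(g["denominator"].sum(), axis=0) * 1000.0
    out = out.reset_index()
    out["E"] = (out["L"] + out["U"]) / 2.0
    return out
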