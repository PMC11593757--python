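"""Calendar-month helpers and the pandemic trend index.

Months are represented throughout as :class:`pandas.Period` objects with
monthly frequency.  The trend index ``t`` measures signed time in years
relative to March 2020 (the pandemic onset month): March 2020 maps to 0,
March 2019 to -1 and May 2022 to 2 + 2/12.  Consecutive months differ by
exactly 1/12.
"""

from __future__ import annotations

from typing import Iterable, Union

import pandas as pd

MonthLike = Union[str, pd.Period]

#: Pandemic onset month; origin of the trend index.
ONSET = pd.Period("2020-03", freq="M")


def as_month(month: MonthLike) -> pd.Period:
    """Coerce a ``'YYYY-MM'`` string or Period to a monthly Period."""
    if isinstance(month, pd.Period):
        if month.freqstr.upper().startswith("M"):
            return month
        return month.asfreq("M")
    return pd.Period(month, freq="M")


def month_range(start: MonthLike, end: MonthLike) -> pd.PeriodIndex:
    """Inclusive contiguous range of calendar months."""
    return pd.period_range(as_month(start), as_month(end), freq="M")


def months_from_onset(month: MonthLike) -> int:
    """Whole months elapsed since March 2020 (negative before onset)."""
    return (as_month(month) - ONSET).n


def trend_index(month: MonthLike) -> float:
    """Trend index t in years relative to March 2020.

    Computed as the exact month offset divided by 12; any rounding (e.g.
    the conventional two-decimal display of 2.17 for May 2022) is applied
    only when reporting, never here.
    """
    return months_from_onset(month) / 12.0


def month_position(month: MonthLike) -> int:
    """Month-of-year position in [0, 12): January = 0 ... December = 11."""
    return as_month(month).month - 1


def trend_index_array(months: Iterable[MonthLike]) -> "pd.Series":
    """Vectorised :func:`trend_index` returning a float Series."""
    idx = pd.PeriodIndex([as_month(m) for m in months], freq="M")
    return pd.Series([(m - ONSET).n / 12.0 for m in idx], dtype=float)
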