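"""Assessment-period calendar.

The quality-assessment cycle runs July 1 to June 30.  Explanatory variables
(grades, severity, adherence, comorbidity) are collected in the
premeasurement window A and the exacerbation outcome in the measurement
window B, which is the immediately following July-June year.  All windows
are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import List

import numpy as np
import pandas as pd

#: Calendar month numbers in assessment order (July .. June).
MONTH_ORDER = (7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6)
MONTH_LABELS = ("Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
                "Jan", "Feb", "Mar", "Apr", "May", "Jun")


@dataclass(frozen=True)
class AssessmentPeriod:
    index: int
    a_start: date
    a_end: date
    b_start: date
    b_end: date

    def __post_init__(self) -> None:
        if self.a_end != self.b_start:
            raise ValueError("measurement window B must immediately follow A")
        if not (self.a_start < self.a_end < self.b_end):
            raise ValueError("windows must be non-empty and ordered")

    @property
    def n_days_a(self) -> int:
        return (self.a_end - self.a_start).days

    @property
    def n_days_b(self) -> int:
        return (self.b_end - self.b_start).days

    def month_of_day(self) -> np.ndarray:
        """Assessment-month index (0=July .. 11=June) for each day offset in A."""
        days = pd.date_range(self.a_start, self.a_end, inclusive="left")
        lookup = {m: i for i, m in enumerate(MONTH_ORDER)}
        return np.array([lookup[m] for m in days.month])

    def days_in_month(self) -> np.ndarray:
        """Number of days of window A falling in each assessment month."""
        return np.bincount(self.month_of_day(), minlength=12)


def make_periods(first_year: int = 2013, n_periods: int = 3) -> List[AssessmentPeriod]:
    """Consecutive July-June assessment periods starting July 1 of `first_year`."""
    if n_periods < 1:
        raise ValueError("n_periods must be positive")
    out = []
    for i in range(n_periods):
        y = first_year + i
        out.append(
            AssessmentPeriod(
                index=i + 1,
                a_start=date(y, 7, 1),
                a_end=date(y + 1, 7, 1),
                b_start=date(y + 1, 7, 1),
                b_end=date(y + 2, 7, 1),
            )
        )
    return out
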