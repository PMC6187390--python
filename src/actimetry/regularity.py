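"""Regularity Index (RI): correlation of daily hourly-AI patterns.

RI for day *i* is the Pearson product-moment correlation between the
24-element hourly AI vectors of day *i* and a reference day — the
previous day (day-to-day RI) or the same weekday one week earlier
(week-to-week RI).  RI = +1 means an identical daily activity pattern,
0 uncorrelated, −1 an inverted pattern.  Hourly rather than minute
vectors are used so the comparison reflects the coarse daily routine
instead of minute-level noise; minute-level RI can be computed by
passing 1440-element vectors to :func:`pattern_correlation` directly.

A day with zero variance across its 24 hours (e.g. a flat all-zero day)
has no defined correlation; RI is then reported as missing (NaN), never
coerced to 0, which would falsely read as "uncorrelated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_index import HourlyAIVector
from .errors import DataError

__all__ = [
    "RegularitySeries",
    "pattern_correlation",
    "day_to_day_ri",
    "week_to_week_ri",
    "ri_trend",
]


@dataclass
class RegularitySeries:
    """Per-day RI trend; NaN marks days without a usable reference day."""

    day_label: list
    ri_day: np.ndarray
    ri_week: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day_label, "ri_day": self.ri_day, "ri_week": self.ri_week}
        )


def pattern_correlation(a, b) -> float:
    """Pearson correlation of two equal-length AI patterns; NaN if degenerate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("patterns must be 1-D and of equal length")
    if a.std() == 0 or b.std() == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def _vec(v: HourlyAIVector | np.ndarray) -> np.ndarray:
    values = v.values if isinstance(v, HourlyAIVector) else np.asarray(v, float)
    if values.shape != (24,):
        raise DataError("hourly AI vector must have exactly 24 values")
    return values


def day_to_day_ri(prev: HourlyAIVector, cur: HourlyAIVector) -> float:
    """RI of a day against the previous day (both noon-first hourly vectors)."""
    return pattern_correlation(_vec(prev), _vec(cur))


def week_to_week_ri(past: HourlyAIVector, cur: HourlyAIVector) -> float:
    """RI of a day against the same weekday one week earlier."""
    return pattern_correlation(_vec(past), _vec(cur))


def ri_trend(days: list[HourlyAIVector]) -> RegularitySeries:
    """Assemble the day-to-day and week-to-week RI trend for a span of days.

    ``days`` must be chronologically ordered with unique day labels.
    References are calendar-based: day *i*'s ri_day needs the vector
    labelled one calendar day earlier, ri_week one calendar week earlier;
    either is NaN when the reference day is absent.
    """
    labels = [d.day.day_label for d in days]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate day labels in RI trend input")
    if labels != sorted(labels):
        raise DataError("days must be chronologically ordered")
    by_label = {d.day.day_label: d for d in days}
    ri_day = np.full(len(days), math.nan)
    ri_week = np.full(len(days), math.nan)
    one_day = pd.Timedelta(days=1)
    for i, d in enumerate(days):
        prev = by_label.get((pd.Timestamp(d.day.day_label) - one_day).date())
        if prev is not None:
            ri_day[i] = day_to_day_ri(prev, d)
        past = by_label.get((pd.Timestamp(d.day.day_label) - 7 * one_day).date())
        if past is not None:
            ri_week[i] = week_to_week_ri(past, d)
    return RegularitySeries(day_label=labels, ri_day=ri_day, ri_week=ri_week)
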