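"""Daily monitoring parameters for one noon-to-noon day.

The summary condenses a day into the monitoring parameter set:

* ``t_ai`` — total AI, the sum of the day's 1440 minute AIs;
* ``d_ri`` — day-to-day Regularity Index versus the previous day (NaN
  when no previous day is available);
* ``sl_t`` — sleep hours: total minutes inside detected sleep periods
  (naps included) divided by 60;
* ``sl_q`` — sleep quality: mean minute AI over all sleep periods
  (lower = stiller = better);
* ``t_level`` — hours spent at each of the five activity levels;
* ``post_wake`` — for each configured ``(x_hours, min_level)`` window,
  hours spent at or above ``min_level`` within ``x_hours`` after waking
  from the main sleep.  The canonical clinical query is 3 h / moderate:
  how much moderate-or-harder activity a subject manages in the three
  hours after a full night's rest.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_index import MinuteAISeries
from .activity_levels import ActivityLevel, LevelThresholds, classify_ai, level_durations
from .errors import AlignmentError, DataError
from .sleep_detection import SleepPeriod, SleepStateSeries, main_sleep

__all__ = ["DailySummary", "summarize_day", "post_wake_activity"]

#: default post-wake queries: (window hours, minimum level)
DEFAULT_POST_WAKE = ((3.0, ActivityLevel.MODERATE),)


@dataclass
class DailySummary:
    """The monitoring parameter set for one analysis day."""

    day_label: dt.date
    t_ai: float
    d_ri: float
    sl_t: float
    sl_q: float
    t_level: dict
    post_wake: dict  # (x_hours, min_level) -> hours, NaN if no main sleep

    def to_dict(self) -> dict:
        """JSON-friendly flat record (``a3_t_3``-style keys for post-wake)."""
        rec = {
            "day": str(self.day_label),
            "t_ai": self.t_ai,
            "d_ri": None if math.isnan(self.d_ri) else self.d_ri,
            "sl_t": self.sl_t,
            "sl_q": None if math.isnan(self.sl_q) else self.sl_q,
        }
        for lvl in ActivityLevel:
            rec[f"t_{lvl.value}"] = self.t_level[lvl]
        for (x, lvl), hours in self.post_wake.items():
            key = f"a{x:g}_t_{int(lvl)}"
            rec[key] = None if math.isnan(hours) else hours
        return rec


def post_wake_activity(
    minutes: MinuteAISeries,
    wake: pd.Timestamp,
    x_hours: float,
    min_level: ActivityLevel,
    thresholds: LevelThresholds | None = None,
) -> float:
    """Hours at or above ``min_level`` within ``x_hours`` after ``wake``."""
    if x_hours <= 0:
        raise DataError("x_hours must be positive")
    wake = pd.Timestamp(wake)
    end = wake + pd.Timedelta(hours=x_hours)
    if len(minutes) and end > minutes.minute_start[-1] + pd.Timedelta(minutes=1):
        warnings.warn("post-wake window extends past the series end; truncated", stacklevel=2)
    mask = (minutes.minute_start >= wake) & (minutes.minute_start < end)
    if not mask.any():
        return 0.0
    codes = classify_ai(minutes.ai[mask], thresholds)
    return float(np.sum(codes >= int(min_level)) / 60.0)


def summarize_day(
    minutes: MinuteAISeries,
    states: SleepStateSeries,
    periods: list[SleepPeriod],
    ri: float = math.nan,
    thresholds: LevelThresholds | None = None,
    post_wake_queries=DEFAULT_POST_WAKE,
) -> DailySummary:
    """Assemble the daily parameter set from the per-day pipeline outputs."""
    if len(minutes) == 0:
        raise DataError("cannot summarize an empty day")
    if len(states) != len(minutes) or not states.minute_start.equals(minutes.minute_start):
        raise AlignmentError("sleep states misaligned with minute series")

    thresholds = thresholds or LevelThresholds()
    t_ai = float(minutes.ai.sum())

    sleep_minutes = 0
    ai_sum = 0.0
    for p in periods:
        mask = (minutes.minute_start >= p.onset) & (minutes.minute_start < p.offset)
        if int(mask.sum()) != p.duration_min:
            raise AlignmentError("sleep period does not align with the minute series")
        sleep_minutes += p.duration_min
        ai_sum += float(minutes.ai[mask].sum())
    sl_t = sleep_minutes / 60.0
    sl_q = ai_sum / sleep_minutes if sleep_minutes else math.nan

    durations = level_durations(minutes, thresholds)
    t_level = {lvl: durations[lvl] / 60.0 for lvl in ActivityLevel}

    anchor = main_sleep(periods)
    post_wake = {}
    for x_hours, min_level in post_wake_queries:
        if anchor is None:
            post_wake[(x_hours, min_level)] = math.nan
        else:
            post_wake[(x_hours, min_level)] = post_wake_activity(
                minutes, anchor.offset, x_hours, min_level, thresholds
            )

    # noon-to-noon label: the calendar date of the day's noon start
    first = minutes.minute_start[0]
    label = first.date() if first.hour >= 12 else (first - pd.Timedelta(days=1)).date()
    return DailySummary(
        day_label=label,
        t_ai=t_ai,
        d_ri=float(ri),
        sl_t=sl_t,
        sl_q=sl_q,
        t_level=t_level,
        post_wake=post_wake,
    )
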