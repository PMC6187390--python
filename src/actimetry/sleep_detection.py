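"""Two-phase sleep-duration detection on a minute-AI series.

Phase I is a left-to-right state machine over the minute AIs.  Starting
from an initial state fixed by the rest-level bound (awake iff the first
AI ≥ 0.1), each minute is judged against the previous minute's state:

* awake → asleep when the current AI is below a threshold T *and* at
  least ``sleep_minth`` of the next ``window1_min`` AIs are also below T;
* asleep → awake when the current AI is above T *and* fewer than
  ``wakeup_minth`` of the next ``window2_min`` AIs are below T.

T is normally the strict threshold.  For the ``fuzzy_min`` minutes after
an awakening that interrupted a sleep episode, the relaxed (higher)
threshold is used instead — a subject who just woke during the night is
likely to fall back asleep, so borderline stillness counts as sleep there
but not during the day.  Look-ahead windows exclude the current minute
and truncate at the end of the series; an AI exactly equal to T keeps the
previous state.

Phase II merges sleep runs separated by awake gaps shorter than
``merge_gap_min``, iterating left to right to a fixed point.  This folds
brief nocturnal awakenings back into one sleep period, matching the
subject's own perception of "a night's sleep"; the merged period's
quality is the mean minute AI over its whole span, so restless nights
score worse (higher) than still ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_index import MinuteAISeries
from .errors import AlignmentError, ConfigError

__all__ = [
    "SleepDetectionConfig",
    "SleepStateSeries",
    "SleepPeriod",
    "detect_sleep_states",
    "merge_sleep_periods",
    "main_sleep",
]

AWAKE = 0
SLEEP = 1


@dataclass(frozen=True)
class SleepDetectionConfig:
    """Tunable constants of the two-phase detector.

    Thresholds are on the minute-AI scale; durations are whole minutes.
    The defaults keep the published rest-level bound (0.1) as the strict
    threshold and bootstrap value.
    """

    sleep_th_strict: float = 0.1
    sleep_th_relaxed: float = 0.2
    window1_min: int = 10
    sleep_minth: int = 8
    window2_min: int = 10
    wakeup_minth: int = 3
    fuzzy_min: int = 15
    merge_gap_min: int = 30

    def __post_init__(self) -> None:
        if not (self.sleep_th_relaxed >= self.sleep_th_strict > 0):
            raise ConfigError("need sleep_th_relaxed ≥ sleep_th_strict > 0")
        ints = (
            self.window1_min,
            self.sleep_minth,
            self.window2_min,
            self.wakeup_minth,
            self.fuzzy_min,
            self.merge_gap_min,
        )
        if any(int(v) != v or v <= 0 for v in ints):
            raise ConfigError("durations/counts must be positive integers")
        if self.sleep_minth > self.window1_min or self.wakeup_minth > self.window2_min:
            raise ConfigError("count bounds cannot exceed their look-ahead windows")


@dataclass
class SleepStateSeries:
    """Per-minute awake(0)/sleep(1) labels aligned with a minute-AI series."""

    minute_start: pd.DatetimeIndex
    state: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start = pd.DatetimeIndex(self.minute_start)
        self.state = np.asarray(self.state, dtype=np.int8)
        if len(self.minute_start) != len(self.state):
            raise AlignmentError("state series misaligned with its timestamps")

    def __len__(self) -> int:
        return len(self.state)


@dataclass(frozen=True)
class SleepPeriod:
    """A detected (possibly merged) sleep interval."""

    onset: pd.Timestamp
    offset: pd.Timestamp
    duration_min: int
    quality: float  # mean minute AI over the span; lower = better sleep

    def __post_init__(self) -> None:
        if self.offset <= self.onset or self.quality < 0:
            raise AlignmentError("invalid sleep period")


def detect_sleep_states(
    minutes: MinuteAISeries, config: SleepDetectionConfig | None = None
) -> SleepStateSeries:
    """Phase I: label every minute awake or asleep."""
    config = config or SleepDetectionConfig()
    ai = minutes.ai
    n = len(ai)
    if n < config.window1_min:
        raise ConfigError("series shorter than the fall-asleep look-ahead window")

    state = np.empty(n, dtype=np.int8)
    state[0] = AWAKE if ai[0] >= config.sleep_th_strict else SLEEP
    last_wake = None  # index of the most recent sleep-interrupting awakening
    for i in range(1, n):
        in_fuzzy = last_wake is not None and (i - last_wake) < config.fuzzy_min
        th = config.sleep_th_relaxed if in_fuzzy else config.sleep_th_strict
        if state[i - 1] == AWAKE:
            look = ai[i + 1 : i + 1 + config.window1_min]
            if ai[i] < th and int(np.sum(look < th)) >= config.sleep_minth:
                state[i] = SLEEP
            else:
                state[i] = AWAKE
        else:
            look = ai[i + 1 : i + 1 + config.window2_min]
            if ai[i] > th and int(np.sum(look < th)) < config.wakeup_minth:
                state[i] = AWAKE
                last_wake = i
            else:
                state[i] = SLEEP
    return SleepStateSeries(minute_start=minutes.minute_start, state=state)


def _runs(state: np.ndarray):
    """(start, stop) index pairs of consecutive sleep minutes, stop exclusive."""
    padded = np.diff(np.concatenate(([0], (state == SLEEP).astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def merge_sleep_periods(
    states: SleepStateSeries,
    minutes: MinuteAISeries,
    config: SleepDetectionConfig | None = None,
) -> list[SleepPeriod]:
    """Phase II: absorb short awake gaps and report merged sleep periods."""
    config = config or SleepDetectionConfig()
    if len(states) != len(minutes) or not states.minute_start.equals(minutes.minute_start):
        raise AlignmentError("sleep states do not align with the minute-AI series")
    runs = _runs(states.state)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < config.merge_gap_min:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    periods = []
    for start, stop in merged:
        span_ai = minutes.ai[start:stop]
        periods.append(
            SleepPeriod(
                onset=minutes.minute_start[start],
                offset=minutes.minute_start[stop - 1] + pd.Timedelta(minutes=1),
                duration_min=int(stop - start),
                quality=float(span_ai.mean()),
            )
        )
    return periods


def main_sleep(periods: list[SleepPeriod]) -> SleepPeriod | None:
    """The day's principal sleep period: longest, ties broken by later onset."""
    if not periods:
        return None
    return max(periods, key=lambda p: (p.duration_min, p.onset.value))
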