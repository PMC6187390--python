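"""Five-level physical-activity classification from minute AI values.

Minute AIs are mapped to five ordered levels — rest/sleep (0), sedentary
(1), light (2), moderate (3), vigorous (4) — by fixed cut points on the AI
scale, default 0.1 / 0.5 / 2.0 / 4.0.  Intervals are half-open and
lower-inclusive ([0, 0.1) → rest, ..., [4.0, ∞) → vigorous) so that the
partition is total and every minute lands in exactly one level.

``REFERENCE_ACTIVITIES`` ships the published per-activity AI statistics
(max / min / mean over a 14-activity wear test of ten subjects) that the
default cut points were derived from.  They are reference fixtures: the
classifier itself uses only the cut points.  Note the activity ranges
overlap the cuts — e.g. descending stairs without arm swing peaks above
the vigorous cut while its mean is moderate — so per-minute labels can
legitimately exceed an activity's nominal level.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .activity_index import MinuteAISeries
from .errors import ConfigError, DataError

__all__ = [
    "ActivityLevel",
    "LevelThresholds",
    "classify_ai",
    "level_durations",
    "REFERENCE_ACTIVITIES",
]


class ActivityLevel(enum.IntEnum):
    """Ordered activity intensity levels."""

    REST_SLEEP = 0
    SEDENTARY = 1
    LIGHT = 2
    MODERATE = 3
    VIGOROUS = 4


@dataclass(frozen=True)
class LevelThresholds:
    """Ascending AI cut points separating the five levels."""

    cut_points: tuple = (0.1, 0.5, 2.0, 4.0)

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cut_points)
        if len(cp) != 4 or any(c <= 0 for c in cp) or list(cp) != sorted(set(cp)):
            raise ConfigError("cut_points must be 4 strictly ascending positive values")
        object.__setattr__(self, "cut_points", cp)


#: (activity name, nominal level, max AI, min AI, mean AI) — wear-test reference values.
REFERENCE_ACTIVITIES = [
    ("Rest/Sleeping", ActivityLevel.REST_SLEEP, 0.096975, 0.082482, 0.088523),
    ("Sit-Watching TV", ActivityLevel.SEDENTARY, 0.345286, 0.092849, 0.186028),
    ("Sit-Reading Newspaper", ActivityLevel.SEDENTARY, 0.466089, 0.090514, 0.301787),
    ("Sit-Web browsing", ActivityLevel.SEDENTARY, 0.12198, 0.100102, 0.111355),
    ("Housekeeping", ActivityLevel.LIGHT, 1.604074, 0.829076, 1.222838),
    ("Driving", ActivityLevel.LIGHT, 1.378413, 0.976756, 1.171664),
    ("Walking-no Hand-Swing", ActivityLevel.LIGHT, 2.334001, 0.648251, 1.59335),
    ("Walking-w/Hand-Swing", ActivityLevel.MODERATE, 3.973975, 2.048219, 2.541614),
    ("DownStairs-no Hand-Swing", ActivityLevel.MODERATE, 8.124398, 1.673799, 3.890505),
    ("DownStairs-w/Hand-Swing", ActivityLevel.MODERATE, 3.40835, 1.243286, 2.415157),
    ("UpStairs-no Hand-Swing", ActivityLevel.MODERATE, 2.602795, 2.352814, 2.515802),
    ("UpStairs-w/Hand-Swing", ActivityLevel.MODERATE, 2.464628, 2.308799, 2.393241),
    ("Jogging-no Hand-Swing", ActivityLevel.VIGOROUS, 12.95352, 4.437786, 8.742815),
    ("Jogging-w/Hand-Swing", ActivityLevel.VIGOROUS, 7.27138, 4.832407, 6.033422),
]


def classify_ai(ai, thresholds: LevelThresholds | None = None):
    """Map minute AI value(s) to :class:`ActivityLevel`.

    Scalar in → single level; array in → integer level codes.
    """
    thresholds = thresholds or LevelThresholds()
    arr = np.asarray(ai, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DataError("AI must be finite and non-negative")
    codes = np.searchsorted(np.asarray(thresholds.cut_points), arr, side="right")
    if arr.ndim == 0:
        return ActivityLevel(int(codes))
    return codes.astype(np.int8)


def level_durations(
    minutes: MinuteAISeries, thresholds: LevelThresholds | None = None
) -> dict:
    """Minutes spent at each level; values sum to the series length."""
    if len(minutes) == 0:
        return {lvl: 0 for lvl in ActivityLevel}
    codes = classify_ai(minutes.ai, thresholds)
    counts = np.bincount(codes, minlength=5)
    return {lvl: int(counts[lvl]) for lvl in ActivityLevel}
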