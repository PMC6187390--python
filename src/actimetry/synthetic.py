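"""Synthetic wrist-accelerometer recordings with planted behavioral structure.

A :class:`BehaviorSchedule` describes days as ordered segments (clock
start, duration, state label, target epoch-level magnitude-σ in g).  Two
generators consume it:

* :func:`simulate_recording` emits raw 20 Hz tri-axial samples: a 1 g
  gravity vector at a random fixed orientation per segment plus isotropic
  zero-mean Gaussian axis noise, optionally quantized to the 3.9 mg step
  of a ±8 g 12-bit sensor.  The per-axis noise scale is *calibrated* so
  the standard deviation of the resulting magnitude equals the segment's
  target σ: for noise s comparable to gravity the magnitude σ falls well
  below s (the vector norm is a noncentral-chi variable), so the exact
  moment relation is inverted numerically rather than assuming σ ≈ s.
* :func:`simulate_minute_ai` shortcuts straight to minute AI values
  (target mean M·σ with multiplicative lognormal jitter), for tests of
  the sleep and regularity stages that do not need raw samples.

Both are deterministic given the schedule's seed.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.laguerre import laggauss
from scipy.optimize import brentq

from .activity_index import MinuteAISeries
from .errors import ConfigError
from .raw_io import TriaxialRecording

__all__ = [
    "Segment",
    "BehaviorSchedule",
    "simulate_recording",
    "simulate_minute_ai",
    "preset_schedules",
    "axis_noise_scale",
    "magnitude_sigma",
]

#: quantization step of a ±8 g, 12-bit accelerometer (3.9 mg)
QUANT_STEP_G = 0.0039
RANGE_G = 8.0


@dataclass(frozen=True)
class Segment:
    """One behavioral block of a simulated day."""

    start: dt.time
    duration_min: int
    label: str
    sigma: float  # target per-epoch magnitude-σ in g

    def __post_init__(self) -> None:
        if self.duration_min <= 0 or self.sigma < 0:
            raise ConfigError("segment needs positive duration and σ ≥ 0")


def _minutes_of(t: dt.time) -> int:
    return t.hour * 60 + t.minute


def _check_tiling(pattern) -> None:
    total = sum(s.duration_min for s in pattern)
    if total != 1440:
        raise ConfigError(f"segments must tile 24 h (1440 min), got {total}")
    pos = _minutes_of(pattern[0].start)
    for seg in pattern:
        if _minutes_of(seg.start) != pos % 1440:
            raise ConfigError(
                f"segment {seg.label!r} starts at {seg.start}, expected "
                f"{pos % 1440 // 60:02d}:{pos % 60:02d}"
            )
        pos += seg.duration_min


@dataclass(frozen=True)
class BehaviorSchedule:
    """Seeded multi-day behavioral schedule.

    ``segments`` is either one daily pattern (a sequence of
    :class:`Segment`, reused for every day) or one pattern per day
    (a sequence of ``day_count`` such sequences).  Each pattern must tile
    its 24-h day exactly, and all days must share the same anchor time.
    """

    segments: tuple
    day_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_count < 1:
            raise ConfigError("day_count must be ≥ 1")
        segs = tuple(self.segments)
        if segs and isinstance(segs[0], Segment):
            patterns = (segs,) * self.day_count
        else:
            patterns = tuple(tuple(p) for p in segs)
            if len(patterns) != self.day_count:
                raise ConfigError("need one segment pattern per day")
        anchors = {p[0].start for p in patterns}
        if len(anchors) != 1:
            raise ConfigError("all day patterns must share the same anchor time")
        for p in patterns:
            _check_tiling(p)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "_patterns", patterns)

    @property
    def day_patterns(self) -> tuple:
        return self._patterns

    @property
    def anchor(self) -> dt.time:
        return self._patterns[0][0].start

    def with_seed(self, seed: int) -> "BehaviorSchedule":
        return replace(self, seed=seed)


# --- noise calibration ----------------------------------------------------

_HERM = hermgauss(96)
_LAG = laggauss(64)


def magnitude_sigma(s: float) -> float:
    """Exact sd of |g·u + n| for unit gravity and isotropic axis noise s.

    Decomposing the noise into its component along gravity (h ~ N(0,1),
    scaled by s) and the perpendicular plane (s²·χ²₂), the squared norm is
    (1+s·h)² + 2s²·u with u ~ Exp(1); the first two moments then follow
    from Gauss–Hermite × Gauss–Laguerre quadrature.
    """
    if s == 0:
        return 0.0
    xh, wh = _HERM
    xl, wl = _LAG
    a = (1.0 + s * np.sqrt(2.0) * xh[:, None]) ** 2 + 2.0 * s * s * xl[None, :]
    mean_a = float((wh[:, None] / np.sqrt(np.pi) * wl[None, :] * np.sqrt(a)).sum())
    var = 1.0 + 3.0 * s * s - mean_a**2
    return float(np.sqrt(max(var, 0.0)))


@lru_cache(maxsize=256)
def axis_noise_scale(target_sigma: float) -> float:
    """Per-axis Gaussian scale s whose magnitude-σ equals ``target_sigma``."""
    if target_sigma == 0:
        return 0.0
    lo, hi = 0.4 * target_sigma, 3.5 * target_sigma + 0.1
    return float(brentq(lambda s: magnitude_sigma(s) - target_sigma, lo, hi, xtol=1e-12))


# --- generators -----------------------------------------------------------


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_recording(
    schedule: BehaviorSchedule,
    rate_hz: float = 20.0,
    quantize: bool = False,
    start_date: dt.date = dt.date(2018, 5, 9),
    drift_deg_per_min: float = 0.0,
) -> TriaxialRecording:
    """Generate a raw tri-axial recording realizing the schedule.

    Each segment gets a fresh random orientation for the 1 g gravity
    vector; ``drift_deg_per_min`` > 0 adds a slow random-walk
    reorientation (one step per second) within segments.  With
    ``quantize`` the samples are rounded to 3.9 mg steps and clipped to
    ±8 g (a warning is issued if clipping actually occurs).
    """
    rng = np.random.default_rng(schedule.seed)
    chunks = []
    for day_i, pattern in enumerate(schedule.day_patterns):
        for seg in pattern:
            n = int(round(seg.duration_min * 60 * rate_hz))
            u = _random_unit(rng)
            if drift_deg_per_min > 0:
                step_rad = np.deg2rad(drift_deg_per_min) / 60.0
                seconds = seg.duration_min * 60
                per_sec = max(int(round(rate_hz)), 1)
                us = np.empty((seconds, 3))
                for sec in range(seconds):
                    us[sec] = u
                    kick = rng.normal(scale=step_rad, size=3)
                    u = u + kick - np.dot(kick, u) * u
                    u /= np.linalg.norm(u)
                grav = np.repeat(us, per_sec, axis=0)[:n]
            else:
                grav = np.broadcast_to(u, (n, 3))
            s = axis_noise_scale(seg.sigma)
            if s > 0:
                samples = grav + rng.normal(scale=s, size=(n, 3))
            else:
                samples = np.array(grav, copy=True)
            chunks.append(samples)
    data = np.concatenate(chunks, axis=0)
    if quantize:
        if np.any(np.abs(data) > RANGE_G):
            warnings.warn("samples exceed ±8 g; clipping to range", stacklevel=2)
        data = np.clip(np.round(data / QUANT_STEP_G) * QUANT_STEP_G, -RANGE_G, RANGE_G)
    start = pd.Timestamp.combine(start_date, schedule.anchor)
    return TriaxialRecording(
        start_time=start,
        sample_rate_hz=rate_hz,
        x=data[:, 0],
        y=data[:, 1],
        z=data[:, 2],
        device_meta={"range_g": RANGE_G if quantize else None, "synthetic": True},
    )


def simulate_minute_ai(
    schedule: BehaviorSchedule,
    jitter: float = 0.1,
    epochs_per_minute: int = 12,
    start_date: dt.date = dt.date(2018, 5, 9),
) -> MinuteAISeries:
    """Draw minute AIs directly from the schedule's targets.

    Each minute's AI is ``epochs_per_minute × σ`` times a mean-one
    lognormal factor with log-sd ``jitter`` (exactly the target when
    ``jitter`` is 0); σ = 0 minutes are exactly 0.
    """
    rng = np.random.default_rng(schedule.seed)
    values = []
    for pattern in schedule.day_patterns:
        for seg in pattern:
            target = epochs_per_minute * seg.sigma
            if target == 0 or jitter == 0:
                vals = np.full(seg.duration_min, target)
            else:
                vals = target * np.exp(
                    rng.normal(scale=jitter, size=seg.duration_min) - jitter**2 / 2
                )
            values.append(vals)
    ai = np.concatenate(values)
    start = pd.Timestamp.combine(start_date, schedule.anchor)
    minute_start = start + pd.to_timedelta(np.arange(len(ai)), unit="min")
    return MinuteAISeries(
        minute_start=pd.DatetimeIndex(minute_start),
        ai=ai,
        epochs_per_minute=epochs_per_minute,
    )


# --- preset schedules -----------------------------------------------------


def _t(h: int, m: int = 0) -> dt.time:
    return dt.time(h, m)


def _regular_day() -> tuple:
    # typical free-living day: evening wind-down, 23:00-07:00 night sleep,
    # brisk morning block.  σ values chosen so minute AI ≈ 12σ sits inside
    # the intended level band (sleep ≈ 0.05, sedentary ≈ 0.2, light ≈ 1.2,
    # moderate ≈ 3).
    return (
        Segment(_t(12), 180, "light", 0.10),
        Segment(_t(15), 240, "sedentary", 0.018),
        Segment(_t(19), 120, "light", 0.08),
        Segment(_t(21), 120, "sedentary", 0.015),
        Segment(_t(23), 480, "sleep", 0.004),
        Segment(_t(7), 60, "moderate", 0.25),
        Segment(_t(8), 240, "light", 0.10),
    )


def _fragmented_day() -> tuple:
    return (
        Segment(_t(12), 660, "light", 0.10),
        Segment(_t(23), 180, "sleep", 0.004),
        Segment(_t(2), 10, "awakening", 0.10),
        Segment(_t(2, 10), 110, "sleep", 0.004),
        Segment(_t(4), 15, "awakening", 0.10),
        Segment(_t(4, 15), 135, "sleep", 0.004),
        Segment(_t(6, 30), 90, "light", 0.10),
        Segment(_t(8), 60, "moderate", 0.25),
        Segment(_t(9), 180, "light", 0.10),
    )


def _shift_days() -> tuple:
    day1 = (
        Segment(_t(12), 561, "light", 0.10),
        Segment(_t(21, 21), 440, "sleep", 0.004),
        Segment(_t(4, 41), 439, "light", 0.10),
    )
    day2 = (
        Segment(_t(12), 960, "light", 0.10),
        Segment(_t(4), 201, "sleep", 0.004),
        Segment(_t(7, 21), 279, "light", 0.10),
    )
    return (day1, day2)


def _fourteen_activities_day() -> tuple:
    from .activity_levels import REFERENCE_ACTIVITIES

    acts = []
    pos = 12 * 60
    for name, _level, _mx, _mn, mean_ai in REFERENCE_ACTIVITIES:
        acts.append(Segment(_t(pos // 60, pos % 60), 3, name, mean_ai / 12.0))
        pos += 3
    tail = (
        Segment(_t(12, 42), 618, "sedentary", 0.018),
        Segment(_t(23), 480, "sleep", 0.004),
        Segment(_t(7), 300, "light", 0.10),
    )
    return tuple(acts) + tail


def preset_schedules(seed: int = 0) -> dict:
    """Named schedule catalog for tests, examples and the CLI."""
    return {
        "regular_week": BehaviorSchedule(_regular_day(), day_count=7, seed=seed),
        "fragmented_sleep": BehaviorSchedule(_fragmented_day(), day_count=1, seed=seed),
        "irregular_shift": BehaviorSchedule(_shift_days(), day_count=2, seed=seed),
        "fourteen_activities": BehaviorSchedule(
            _fourteen_activities_day(), day_count=1, seed=seed
        ),
    }
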