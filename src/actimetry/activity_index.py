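"""Activity Index (AI) computation.

The AI condenses raw tri-axial acceleration into a per-interval scalar in
three steps:

1. the signal magnitude ``A_j = sqrt(ax^2 + ay^2 + az^2)`` removes the
   sensor-orientation dependence;
2. within each short *epoch* (default 5 s) the population standard
   deviation sigma of the magnitudes is taken — subtracting the epoch mean
   absorbs the quasi-static 1 g gravity component, so sigma measures net
   body-movement acceleration;
3. the AI over a reporting interval (default one minute) is the sum of its
   M epoch sigmas.

At the default 20 Hz / 5 s / 60 s configuration each epoch holds N = 100
samples, each minute holds M = 12 epochs, and a noon-to-noon day holds
1440 minute AIs.  AI is reported unitless (a sum of g-valued sigmas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, CoverageError, DataError
from .raw_io import DayWindow, TriaxialRecording, partition_days

__all__ = [
    "EpochSigmaSeries",
    "MinuteAISeries",
    "HourlyAIVector",
    "magnitude",
    "epoch_sigma",
    "minute_ai",
    "hourly_ai",
    "split_days",
]


@dataclass
class EpochSigmaSeries:
    """Per-epoch standard deviation of acceleration magnitude, in g."""

    epoch_start: pd.DatetimeIndex
    sigma: np.ndarray
    n_samples_per_epoch: int
    epoch_seconds: float

    def __post_init__(self) -> None:
        self.epoch_start = pd.DatetimeIndex(self.epoch_start)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise DataError("epoch sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.sigma)


@dataclass
class MinuteAISeries:
    """Minute-wise Activity Index series — the pipeline's central intermediate."""

    minute_start: pd.DatetimeIndex
    ai: np.ndarray
    epochs_per_minute: int = 12

    def __post_init__(self) -> None:
        self.minute_start = pd.DatetimeIndex(self.minute_start)
        self.ai = np.asarray(self.ai, dtype=float)
        if len(self.minute_start) != len(self.ai):
            raise DataError("minute_start and ai must have equal length")
        if np.any(self.ai < 0):
            raise DataError("AI must be non-negative")

    def __len__(self) -> int:
        return len(self.ai)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"minute_start": self.minute_start, "ai": self.ai})

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame["minute_start"] = frame["minute_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        frame.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, epochs_per_minute: int = 12) -> "MinuteAISeries":
        frame = pd.read_csv(path)
        if not {"minute_start", "ai"} <= set(frame.columns):
            raise DataError("minute-AI CSV needs columns minute_start,ai")
        return cls(
            minute_start=pd.DatetimeIndex(pd.to_datetime(frame["minute_start"])),
            ai=frame["ai"].to_numpy(float),
            epochs_per_minute=epochs_per_minute,
        )


@dataclass
class HourlyAIVector:
    """24 hourly AI sums for one noon-to-noon day, ordered 12:00 ... 11:00."""

    day: DayWindow
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (24,):
            raise DataError("hourly vector must have exactly 24 values")
        if np.any(self.values < 0):
            raise DataError("hourly AI must be non-negative")


def magnitude(x, y, z):
    """Euclidean magnitude of the acceleration vector, in g.

    Rotation-invariant, which is what makes the downstream AI independent
    of how the device sits on the wrist.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise DataError("non-finite acceleration sample")
    return np.sqrt(x * x + y * y + z * z)


def epoch_sigma(
    recording: TriaxialRecording,
    epoch_seconds: float = 5.0,
    clock_aligned: bool = True,
) -> EpochSigmaSeries:
    """Population standard deviation of |a| over non-overlapping epochs.

    The divisor is N (population form), matching the defining formula; the
    epoch mean mu plays the role of the local gravity estimate.  With
    ``clock_aligned`` (default) the first epoch starts at the first instant
    >= the recording start that is a whole multiple of ``epoch_seconds``
    past the minute, so that epochs tile clock minutes exactly; otherwise
    epochs start at the first sample.  A trailing partial epoch is dropped.
    """
    n_float = epoch_seconds * recording.sample_rate_hz
    n = int(round(n_float))
    if abs(n_float - n) > 1e-6 or n < 2:
        raise ConfigError(
            f"epoch_seconds × rate must be an integer ≥ 2, got {n_float}"
        )
    start = recording.start_time
    skip = 0
    if clock_aligned:
        within_min = start.second + start.microsecond / 1e6 + start.nanosecond / 1e9
        offset = (-within_min) % epoch_seconds
        skip = int(np.ceil(offset * recording.sample_rate_hz - 1e-9))
    mags = magnitude(recording.x, recording.y, recording.z)[skip:]
    n_epochs = len(mags) // n
    if n_epochs == 0:
        return EpochSigmaSeries(
            epoch_start=pd.DatetimeIndex([]),
            sigma=np.empty(0),
            n_samples_per_epoch=n,
            epoch_seconds=epoch_seconds,
        )
    blocks = mags[: n_epochs * n].reshape(n_epochs, n)
    sigma = blocks.std(axis=1)  # population (1/N) form
    first = start + pd.Timedelta(seconds=skip / recording.sample_rate_hz)
    starts = first + pd.to_timedelta(np.arange(n_epochs) * epoch_seconds, unit="s")
    return EpochSigmaSeries(
        epoch_start=pd.DatetimeIndex(starts),
        sigma=sigma,
        n_samples_per_epoch=n,
        epoch_seconds=epoch_seconds,
    )


def minute_ai(sigmas: EpochSigmaSeries, interval_seconds: float = 60.0) -> MinuteAISeries:
    """Sum epoch sigmas into per-interval Activity Index values.

    Only complete, clock-aligned intervals are emitted; leading epochs
    before the first interval boundary and a trailing partial interval are
    dropped.
    """
    ratio = interval_seconds / sigmas.epoch_seconds
    m = int(round(ratio))
    if abs(ratio - m) > 1e-9 or m < 1:
        raise ConfigError("interval must be a positive integer multiple of epoch_seconds")
    if len(sigmas) > 1:
        strides = np.diff(sigmas.epoch_start.view("int64")) / 1e9
        if not np.allclose(strides, sigmas.epoch_seconds, atol=1e-6):
            raise AlignmentError("epoch starts are not at a constant epoch stride")
    if len(sigmas) == 0:
        return MinuteAISeries(pd.DatetimeIndex([]), np.empty(0), epochs_per_minute=m)
    # advance to the first epoch sitting on an interval boundary
    skip = 0
    for skip in range(min(m, len(sigmas))):
        t = sigmas.epoch_start[skip]
        within = (t.minute * 60 + t.second + t.microsecond / 1e6) % interval_seconds
        if within < 1e-9 or interval_seconds - within < 1e-9:
            break
    else:
        raise AlignmentError("no epoch aligns with an interval boundary")
    sig = sigmas.sigma[skip:]
    n_int = len(sig) // m
    ai = sig[: n_int * m].reshape(n_int, m).sum(axis=1)
    first = sigmas.epoch_start[skip]
    starts = first + pd.to_timedelta(np.arange(n_int) * interval_seconds, unit="s")
    return MinuteAISeries(pd.DatetimeIndex(starts), ai, epochs_per_minute=m)


def hourly_ai(
    minutes: MinuteAISeries, day: DayWindow, allow_partial: bool = False
) -> HourlyAIVector:
    """Accumulate the day's minute AIs into 24 hourly sums, noon first."""
    mask = (minutes.minute_start >= day.start) & (minutes.minute_start < day.end)
    sel_ts = minutes.minute_start[mask]
    sel_ai = minutes.ai[mask]
    if len(sel_ts) < 1440 and not allow_partial:
        raise CoverageError(
            f"day {day.day_label} has {len(sel_ts)}/1440 minutes; "
            "pass allow_partial=True to override"
        )
    hour_idx = ((sel_ts.view("int64") - day.start.value) // (3600 * 10**9)).astype(int)
    values = np.zeros(24)
    np.add.at(values, hour_idx, sel_ai)
    return HourlyAIVector(day=day, values=values)


def split_days(minutes: MinuteAISeries, anchor=None):
    """Cut a minute-AI series into noon-to-noon days.

    Returns ``[(DayWindow, MinuteAISeries), ...]``; sample conservation
    across the windows is guaranteed by construction.
    """
    kwargs = {} if anchor is None else {"anchor": anchor}
    out = []
    for win, mask in partition_days(minutes.minute_start, **kwargs):
        sub = MinuteAISeries(
            minutes.minute_start[mask], minutes.ai[mask], minutes.epochs_per_minute
        )
        out.append((win, sub))
    return out
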