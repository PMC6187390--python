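"""Raw-data I/O and noon-to-noon day partitioning.

The native on-disk format is long CSV — ``timestamp,x,y,z`` with ISO-8601
millisecond timestamps and acceleration in g — produced by whatever export
tool sits between the device and this package.  A :class:`ColumnDialect`
maps arbitrary column names onto that layout so vendor CSVs can be read
without rewriting them.

Analysis days run from local clock noon to the next noon so that a whole
night's sleep falls inside a single day; :func:`partition_days` cuts any
timestamped series on that grid.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "TriaxialRecording",
    "DayWindow",
    "ColumnDialect",
    "read_raw_csv",
    "write_raw_csv",
    "partition_days",
]

#: seconds in an analysis day
DAY_SECONDS = 86400.0

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


@dataclass
class ColumnDialect:
    """Column mapping for raw CSV input.

    ``declared_rate_hz`` is the rate the device claims; the measured median
    rate is compared against it and a warning is issued when they disagree
    by more than 1%.
    """

    timestamp: str = "timestamp"
    x: str = "x"
    y: str = "y"
    z: str = "z"
    declared_rate_hz: float | None = None


@dataclass
class TriaxialRecording:
    """Uniformly sampled tri-axial wrist acceleration in g.

    Sample *j* is implicitly timestamped ``start_time + j / sample_rate_hz``.
    ``device_meta`` carries free-form device facts; if it declares a sensing
    ``range_g`` (e.g. 8 for a ±8 g sensor) the samples must lie within it.
    """

    start_time: pd.Timestamp
    sample_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    device_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise DataError("x, y, z must have identical length")
        if len(self.x) < 1:
            raise DataError("recording must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise DataError("sample_rate_hz must be positive")
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(axis)):
                raise DataError(f"non-finite values on axis {name}")
        rng = self.device_meta.get("range_g")
        if rng is not None:
            lim = float(rng)
            if max(np.abs(self.x).max(), np.abs(self.y).max(), np.abs(self.z).max()) > lim + 1e-12:
                raise DataError(f"samples exceed declared ±{lim} g range")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def times(self) -> pd.DatetimeIndex:
        """Per-sample timestamps implied by start time and rate."""
        offsets = pd.to_timedelta(np.arange(len(self)) / self.sample_rate_hz, unit="s")
        return pd.DatetimeIndex(self.start_time + offsets)

    @property
    def duration_seconds(self) -> float:
        return len(self) / self.sample_rate_hz


@dataclass(frozen=True)
class DayWindow:
    """One noon-to-noon analysis day.

    ``day_label`` is the calendar date of the window's noon *start*, so the
    window labelled 9 May covers 9 May 12:00:00.000 through 10 May
    11:59:59.xxx.  ``complete`` is set by :func:`partition_days` when the
    partitioned series fully covers the window at its native stride.
    """

    day_label: dt.date
    start: pd.Timestamp
    end: pd.Timestamp
    complete: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != pd.Timedelta(hours=24):
            raise DataError("DayWindow must span exactly 24 h")

    def contains(self, ts: pd.Timestamp) -> bool:
        return self.start <= ts < self.end


def read_raw_csv(path, dialect: ColumnDialect | None = None) -> TriaxialRecording:
    """Read a raw tri-axial CSV into a validated :class:`TriaxialRecording`.

    Rows are sorted by timestamp; duplicate timestamps are a data error.
    The reported rate is the median inter-sample rate, which also guards
    against irregular sampling: any inter-sample gap deviating from the
    median by more than 10% raises :class:`~actimetry.errors.DataError`.
    """
    dialect = dialect or ColumnDialect()
    frame = pd.read_csv(path)
    needed = [dialect.timestamp, dialect.x, dialect.y, dialect.z]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing}; columns present: {list(frame.columns)}")
    frame = frame[needed].copy()
    frame[dialect.timestamp] = pd.to_datetime(frame[dialect.timestamp])
    frame = frame.sort_values(dialect.timestamp, kind="stable")
    ts = pd.DatetimeIndex(frame[dialect.timestamp])
    if len(frame) == 0:
        raise DataError("empty raw file")
    if len(frame) > 1:
        deltas = np.diff(ts.view("int64")) / 1e9
        if np.any(deltas <= 0):
            raise DataError("duplicate timestamps after sorting")
        med = float(np.median(deltas))
        if np.any(np.abs(deltas - med) > 0.1 * med):
            raise DataError("sampling interval not constant within 10% jitter tolerance")
        rate = 1.0 / med
    else:
        rate = dialect.declared_rate_hz or 20.0
    if dialect.declared_rate_hz is not None and len(frame) > 1:
        if abs(rate - dialect.declared_rate_hz) > 0.01 * dialect.declared_rate_hz:
            warnings.warn(
                f"measured rate {rate:.4g} Hz deviates >1% from declared "
                f"{dialect.declared_rate_hz:.4g} Hz; using measured rate",
                stacklevel=2,
            )
    return TriaxialRecording(
        start_time=ts[0],
        sample_rate_hz=rate,
        x=frame[dialect.x].to_numpy(float),
        y=frame[dialect.y].to_numpy(float),
        z=frame[dialect.z].to_numpy(float),
    )


def write_raw_csv(recording: TriaxialRecording, path) -> None:
    """Write ``timestamp,x,y,z`` CSV (ISO-8601 ms timestamps, g units).

    Values are written with 12 significant digits so a write/read round
    trip reproduces the samples well below 1e-9 g.
    """
    # truncate microsecond stamps to milliseconds
    stamps = recording.times.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3]
    frame = pd.DataFrame(
        {"timestamp": stamps, "x": recording.x, "y": recording.y, "z": recording.z}
    )
    frame.to_csv(path, index=False, float_format="%.12g")


def _noon_on_or_before(ts: pd.Timestamp, anchor: dt.time) -> pd.Timestamp:
    cand = pd.Timestamp.combine(ts.date(), anchor)
    if cand > ts:
        cand -= pd.Timedelta(days=1)
    return cand


def partition_days(index: pd.DatetimeIndex, anchor: dt.time = dt.time(12, 0)):
    """Partition sorted timestamps into anchored 24-h windows.

    Returns a list of ``(DayWindow, bool_mask)`` pairs covering every
    timestamp exactly once, in chronological order.  A window is flagged
    complete when the samples inside it tile the full 24 h at the series'
    native (median) stride.  Timestamps are naive local clock time; DST is
    not modelled.
    """
    index = pd.DatetimeIndex(index)
    if len(index) == 0:
        return []
    if not index.is_monotonic_increasing:
        raise DataError("series timestamps must be sorted")
    stride = None
    if len(index) > 1:
        stride = float(np.median(np.diff(index.view("int64"))) / 1e9)
        if stride <= 0:
            raise DataError("duplicate timestamps in series")
    out = []
    start = _noon_on_or_before(index[0], anchor)
    day = pd.Timedelta(hours=24)
    while start <= index[-1]:
        end = start + day
        mask = (index >= start) & (index < end)
        n = int(mask.sum())
        if n:
            complete = stride is not None and n == round(DAY_SECONDS / stride)
            win = DayWindow(day_label=start.date(), start=start, end=end, complete=complete)
            out.append((win, mask))
        start = end
    return out
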