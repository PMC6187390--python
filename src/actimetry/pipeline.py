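"""End-to-end pipeline: raw CSV → minute AI → levels/sleep/RI → daily summaries.

:class:`PipelineConfig` gathers every stage's tunables and validates
strictly (unknown keys are rejected so a typo in a YAML file fails loudly
instead of silently using a default).  :func:`run_pipeline` wires the
stages together, writes each intermediate to the output directory and
returns the per-day summaries.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .activity_index import epoch_sigma, hourly_ai, minute_ai, split_days
from .activity_levels import ActivityLevel, LevelThresholds, classify_ai
from .daily_summary import DEFAULT_POST_WAKE, summarize_day
from .errors import ConfigError, DataError
from .raw_io import ColumnDialect, read_raw_csv
from .regularity import ri_trend
from .sleep_detection import SleepDetectionConfig, detect_sleep_states, merge_sleep_periods

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("actimetry")


def _from_mapping(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the whole analytics chain."""

    dialect: ColumnDialect = field(default_factory=ColumnDialect)
    epoch_seconds: float = 5.0
    interval_seconds: float = 60.0
    thresholds: LevelThresholds = field(default_factory=LevelThresholds)
    sleep: SleepDetectionConfig = field(default_factory=SleepDetectionConfig)
    day_anchor: dt.time = dt.time(12, 0)
    allow_partial: bool = False
    post_wake_queries: tuple = DEFAULT_POST_WAKE

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0 or self.interval_seconds <= 0:
            raise ConfigError("epoch and interval must be positive")
        if (self.interval_seconds / self.epoch_seconds) % 1 > 1e-9:
            raise ConfigError("interval must be a multiple of epoch_seconds")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "dialect" in data:
            data["dialect"] = _from_mapping(ColumnDialect, data["dialect"])
        if "thresholds" in data:
            data["thresholds"] = LevelThresholds(tuple(data["thresholds"]))
        if "sleep" in data:
            data["sleep"] = _from_mapping(SleepDetectionConfig, data["sleep"])
        if "day_anchor" in data:
            data["day_anchor"] = dt.time.fromisoformat(str(data["day_anchor"]))
        if "post_wake_queries" in data:
            data["post_wake_queries"] = tuple(
                (float(x), ActivityLevel(int(lvl))) for x, lvl in data["post_wake_queries"]
            )
        return _from_mapping(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write_levels(minutes, thresholds, path) -> None:
    codes = classify_ai(minutes.ai, thresholds) if len(minutes) else np.empty(0, int)
    frame = minutes.to_frame()
    frame["level"] = codes
    frame["minute_start"] = frame["minute_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(raw_path, config: PipelineConfig | None = None, out_dir=None) -> list:
    """Run every stage on a raw CSV; returns the list of DailySummary records.

    When ``out_dir`` is given, writes ``minute_ai.csv``, ``levels.csv``,
    ``sleep_states.csv``, ``sleep_periods.csv``, ``hourly_ai.csv``,
    ``ri.csv`` and ``summary.json`` there.  Incomplete noon-to-noon days
    are skipped unless ``config.allow_partial`` is set.
    """
    from pathlib import Path

    config = config or PipelineConfig()
    recording = read_raw_csv(raw_path, config.dialect)
    log.info("raw: %d samples at %.4g Hz", len(recording), recording.sample_rate_hz)
    sigmas = epoch_sigma(recording, config.epoch_seconds)
    log.info("epochs: %d (N=%d)", len(sigmas), sigmas.n_samples_per_epoch)
    minutes = minute_ai(sigmas, config.interval_seconds)
    log.info("minutes: %d (M=%d)", len(minutes), minutes.epochs_per_minute)
    if len(minutes) == 0:
        raise DataError("no complete minutes in input")

    day_series = split_days(minutes, anchor=config.day_anchor)
    usable = [(w, sub) for w, sub in day_series if w.complete or config.allow_partial]
    log.info("days: %d complete of %d", sum(w.complete for w, _ in day_series), len(day_series))
    if not usable:
        raise DataError("no usable analysis days (all incomplete)")

    hourly = []
    per_day = []
    for win, sub in usable:
        states = detect_sleep_states(sub, config.sleep)
        periods = merge_sleep_periods(states, sub, config.sleep)
        vec = hourly_ai(sub, win, allow_partial=config.allow_partial)
        hourly.append(vec)
        per_day.append((win, sub, states, periods, vec))

    trend = ri_trend(hourly)
    summaries = []
    for i, (win, sub, states, periods, _vec) in enumerate(per_day):
        summaries.append(
            summarize_day(
                sub,
                states,
                periods,
                ri=trend.ri_day[i],
                thresholds=config.thresholds,
                post_wake_queries=config.post_wake_queries,
            )
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        minutes.to_csv(out / "minute_ai.csv")
        _write_levels(minutes, config.thresholds, out / "levels.csv")
        state_rows = []
        period_rows = []
        for win, sub, states, periods, _ in per_day:
            for ts, ai, st in zip(sub.minute_start, sub.ai, states.state):
                state_rows.append((ts.strftime("%Y-%m-%dT%H:%M:%S"), ai, int(st)))
            for p in periods:
                period_rows.append(
                    (
                        str(win.day_label),
                        p.onset.strftime("%Y-%m-%dT%H:%M:%S"),
                        p.offset.strftime("%Y-%m-%dT%H:%M:%S"),
                        p.duration_min,
                        p.quality,
                    )
                )
        pd.DataFrame(state_rows, columns=["minute_start", "ai", "state"]).to_csv(
            out / "sleep_states.csv", index=False, float_format="%.12g"
        )
        pd.DataFrame(
            period_rows, columns=["day", "onset", "offset", "duration_min", "quality"]
        ).to_csv(out / "sleep_periods.csv", index=False, float_format="%.12g")
        hrows = []
        for vec in hourly:
            for h in range(24):
                hrows.append(
                    (
                        str(vec.day.day_label),
                        (vec.day.start + pd.Timedelta(hours=h)).strftime("%Y-%m-%dT%H:%M:%S"),
                        vec.values[h],
                    )
                )
        pd.DataFrame(hrows, columns=["day", "hour_start", "ai"]).to_csv(
            out / "hourly_ai.csv", index=False, float_format="%.12g"
        )
        trend.to_frame().to_csv(out / "ri.csv", index=False, float_format="%.12g")
        with open(out / "summary.json", "w") as fh:
            json.dump([s.to_dict() for s in summaries], fh, indent=2)
    return summaries
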