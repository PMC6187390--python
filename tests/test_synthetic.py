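import datetime as dt

import numpy as np
import pytest

from actimetry import (
    ActivityLevel,
    BehaviorSchedule,
    ConfigError,
    Segment,
    classify_ai,
    detect_sleep_states,
    epoch_sigma,
    main_sleep,
    merge_sleep_periods,
    minute_ai,
    preset_schedules,
    simulate_minute_ai,
    simulate_recording,
    split_days,
    hourly_ai,
    ri_trend,
)
from actimetry.activity_levels import REFERENCE_ACTIVITIES
from actimetry.synthetic import QUANT_STEP_G, axis_noise_scale, magnitude_sigma


def one_segment_day(sigma, label="x"):
    return BehaviorSchedule(
        (Segment(dt.time(12, 0), 1440, label, sigma),), day_count=1, seed=11
    )


def short_schedule(sigma, minutes=10, seed=11):
    # a tiling day whose first `minutes` minutes carry the target σ; only
    # that prefix needs simulating for σ-recovery checks
    end = 12 * 60 + minutes
    return BehaviorSchedule(
        (
            Segment(dt.time(12, 0), minutes, "probe", sigma),
            Segment(dt.time(end // 60 % 24, end % 60), 1440 - minutes, "rest", 0.0),
        ),
        day_count=1,
        seed=seed,
    )


class TestScheduleValidation:
    def test_must_tile_full_day(self):
        with pytest.raises(ConfigError):
            BehaviorSchedule((Segment(dt.time(12, 0), 100, "x", 0.1),))

    def test_gap_between_segments_rejected(self):
        with pytest.raises(ConfigError):
            BehaviorSchedule(
                (
                    Segment(dt.time(12, 0), 700, "a", 0.1),
                    Segment(dt.time(1, 0), 740, "b", 0.1),  # should start 23:40
                )
            )

    def test_per_day_patterns_must_match_day_count(self):
        day = (Segment(dt.time(12, 0), 1440, "a", 0.1),)
        with pytest.raises(ConfigError):
            BehaviorSchedule((day, day), day_count=3)


class TestSimulateRecording:
    def test_zero_sigma_gives_zero_ai_everywhere(self):
        rec = simulate_recording(one_segment_day(0.0))
        minutes = minute_ai(epoch_sigma(rec))
        np.testing.assert_array_equal(minutes.ai, np.zeros(1440))
        # gravity magnitude is exactly 1 g
        mags = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
        np.testing.assert_allclose(mags, 1.0, atol=1e-12)

    def test_same_seed_bit_identical(self):
        a = simulate_recording(short_schedule(0.3))
        b = simulate_recording(short_schedule(0.3))
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.z, b.z)

    def test_different_seed_differs(self):
        a = simulate_recording(short_schedule(0.3, seed=1))
        b = simulate_recording(short_schedule(0.3, seed=2))
        assert not np.array_equal(a.x, b.x)

    @pytest.mark.parametrize("target", [0.05, 0.25, 0.5])
    def test_epoch_sigma_recovers_target(self, target):
        # mean recovered σ over 120 five-second epochs within the ±10%
        # per-epoch Monte-Carlo tolerance
        rec = simulate_recording(short_schedule(target))
        sig = epoch_sigma(rec)
        probe = sig.sigma[:120]
        assert np.mean(probe) == pytest.approx(target, rel=0.10)

    def test_hour_average_sigma_within_two_percent(self):
        target = 0.25
        rec = simulate_recording(short_schedule(target, minutes=60))
        sig = epoch_sigma(rec)
        assert np.mean(sig.sigma[:720]) == pytest.approx(target, rel=0.02)

    def test_minute_ai_approximates_twelve_sigma(self):
        target = 0.5
        rec = simulate_recording(short_schedule(target, minutes=30))
        minutes = minute_ai(epoch_sigma(rec))
        assert np.mean(minutes.ai[:30]) == pytest.approx(12 * target, rel=0.10)

    def test_quantization_steps_and_range(self):
        rec = simulate_recording(short_schedule(0.3), quantize=True)
        steps = rec.x / QUANT_STEP_G
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
        assert np.abs(rec.x).max() <= 8.0

    def test_orientation_drift_keeps_unit_gravity(self):
        rec = simulate_recording(
            one_segment_day(0.0), drift_deg_per_min=5.0
        )
        mags = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
        np.testing.assert_allclose(mags, 1.0, atol=1e-12)
        # orientation actually moves
        assert np.ptp(rec.x) > 0.01


class TestNoiseCalibration:
    def test_magnitude_sigma_matches_monte_carlo(self, rng):
        for s in (0.1, 0.5, 1.0):
            n = rng.normal(0, s, (400_000, 3))
            mc = np.sqrt((1 + n[:, 0]) ** 2 + n[:, 1] ** 2 + n[:, 2] ** 2).std()
            assert magnitude_sigma(s) == pytest.approx(mc, rel=5e-3)

    def test_inversion_round_trip(self):
        for target in (0.004, 0.05, 0.25, 0.73):
            s = axis_noise_scale(target)
            assert magnitude_sigma(s) == pytest.approx(target, abs=1e-9)

    def test_zero_maps_to_zero(self):
        assert axis_noise_scale(0.0) == 0.0


class TestSimulateMinuteAI:
    def test_sleep_segments_stay_below_rest_bound(self):
        sched = preset_schedules(seed=5)["regular_week"]
        minutes = simulate_minute_ai(sched)
        labels = np.concatenate(
            [[seg.label] * seg.duration_min for p in sched.day_patterns for seg in p]
        )
        sleep_ai = minutes.ai[labels == "sleep"]
        assert len(sleep_ai) == 7 * 480
        assert np.all(sleep_ai < 0.1)

    def test_zero_jitter_is_piecewise_constant(self):
        sched = preset_schedules(seed=5)["fragmented_sleep"]
        minutes = simulate_minute_ai(sched, jitter=0.0)
        expected_first = 12 * sched.day_patterns[0][0].sigma
        np.testing.assert_allclose(minutes.ai[:660], expected_first)

    def test_identical_repeated_days_have_unit_ri(self):
        day = (
            Segment(dt.time(12, 0), 480, "a", 0.1),
            Segment(dt.time(20, 0), 600, "b", 0.01),
            Segment(dt.time(6, 0), 360, "c", 0.2),
        )
        sched = BehaviorSchedule(day, day_count=3, seed=0)
        minutes = simulate_minute_ai(sched, jitter=0.0)
        vecs = [hourly_ai(sub, win) for win, sub in split_days(minutes)]
        trend = ri_trend(vecs)
        np.testing.assert_allclose(trend.ri_day[1:], 1.0, atol=1e-12)


class TestPresets:
    def test_catalog_names(self):
        cat = preset_schedules()
        assert set(cat) == {
            "regular_week",
            "fragmented_sleep",
            "irregular_shift",
            "fourteen_activities",
        }

    def test_fourteen_activities_classify_to_reference_levels(self):
        sched = preset_schedules()["fourteen_activities"]
        minutes = simulate_minute_ai(sched, jitter=0.0)
        pos = 0
        for (name, level, _mx, _mn, _mean), seg in zip(
            REFERENCE_ACTIVITIES, sched.day_patterns[0]
        ):
            assert seg.label == name
            for v in minutes.ai[pos : pos + seg.duration_min]:
                assert classify_ai(v) is level, name
            pos += seg.duration_min

    def test_regular_week_is_highly_regular(self):
        sched = preset_schedules(seed=9)["regular_week"]
        minutes = simulate_minute_ai(sched)
        vecs = [hourly_ai(sub, win) for win, sub in split_days(minutes)]
        trend = ri_trend(vecs)
        assert np.all(trend.ri_day[1:] >= 0.9)

    def test_fragmented_sleep_merges_to_single_main_period(self):
        sched = preset_schedules(seed=13)["fragmented_sleep"]
        minutes = simulate_minute_ai(sched)
        states = detect_sleep_states(minutes)
        periods = merge_sleep_periods(states, minutes)
        main = main_sleep(periods)
        # planted: 23:00-06:30 night sleep with 10- and 15-min awakenings
        assert main.duration_min == 450
        assert main.onset == minutes.minute_start[660]
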