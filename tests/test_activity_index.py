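import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from actimetry import (
    AlignmentError,
    ConfigError,
    CoverageError,
    DataError,
    DayWindow,
    EpochSigmaSeries,
    TriaxialRecording,
    epoch_sigma,
    hourly_ai,
    magnitude,
    minute_ai,
    split_days,
)
from conftest import NOON, minutes_from_values


def brute_force_sigma(x, y, z):
    """Direct evaluation of the defining population-σ formula."""
    mags = [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
    mu = sum(mags) / len(mags)
    return math.sqrt(sum((m - mu) ** 2 for m in mags) / len(mags))


def recording_from_xyz(xyz, rate=20.0, start=NOON):
    return TriaxialRecording(start, rate, xyz[:, 0], xyz[:, 1], xyz[:, 2])


class TestMagnitude:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0.0, 0.0, 1.0), 1.0), ((0.6, 0.8, 0.0), 1.0), ((0.0, 0.0, 0.0), 0.0)],
    )
    def test_known_values(self, vec, expected):
        assert magnitude(*vec) == pytest.approx(expected)

    @given(
        st.tuples(*[st.floats(-8, 8) for _ in range(3)]),
        st.integers(0, 2**32 - 1),
    )
    def test_rotation_invariance(self, vec, seed):
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        rotated = rot @ np.asarray(vec)
        assert magnitude(*rotated) == pytest.approx(magnitude(*vec), abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            magnitude(np.inf, 0.0, 0.0)


class TestEpochSigma:
    def test_motionless_recording_has_zero_sigma(self):
        n = 100
        rec = recording_from_xyz(np.tile([0.0, 0.0, 1.0], (n, 1)))
        out = epoch_sigma(rec, 5.0)
        assert out.n_samples_per_epoch == 100
        np.testing.assert_array_equal(out.sigma, [0.0])

    def test_two_point_magnitude_distribution(self):
        # magnitudes alternating mu+c, mu-c have population σ exactly c
        c, mu = 0.25, 1.0
        mags = np.where(np.arange(100) % 2 == 0, mu + c, mu - c)
        rec = recording_from_xyz(np.column_stack([mags, np.zeros(100), np.zeros(100)]))
        out = epoch_sigma(rec, 5.0)
        assert out.sigma[0] == pytest.approx(c, abs=1e-15)

    def test_matches_brute_force_formula(self, rng):
        xyz = rng.normal(0, 0.5, (300, 3)) + [0, 0, 1]
        rec = recording_from_xyz(xyz)
        out = epoch_sigma(rec, 5.0)
        assert len(out) == 3
        for k in range(3):
            block = xyz[k * 100 : (k + 1) * 100]
            expected = brute_force_sigma(block[:, 0], block[:, 1], block[:, 2])
            assert out.sigma[k] == pytest.approx(expected, abs=1e-12)

    def test_orientation_invariance_of_sigma(self, rng):
        xyz = rng.normal(0, 0.3, (1200, 3)) + [0, 0, 1]
        rot = Rotation.random(rng=rng).as_matrix()
        a = epoch_sigma(recording_from_xyz(xyz))
        b = epoch_sigma(recording_from_xyz(xyz @ rot.T))
        np.testing.assert_allclose(a.sigma, b.sigma, atol=1e-9, rtol=0)

    def test_trailing_partial_epoch_dropped(self):
        rec = recording_from_xyz(np.tile([0.0, 0.0, 1.0], (250, 1)))
        assert len(epoch_sigma(rec, 5.0)) == 2

    def test_clock_alignment_skips_to_epoch_grid(self):
        start = NOON + pd.Timedelta(seconds=2)
        rec = TriaxialRecording(start, 20.0, *np.zeros((3, 300)))
        out = epoch_sigma(rec, 5.0)
        assert out.epoch_start[0] == NOON + pd.Timedelta(seconds=5)

    def test_sub_two_sample_epoch_is_config_error(self):
        rec = recording_from_xyz(np.tile([0.0, 0.0, 1.0], (100, 1)), rate=0.2)
        with pytest.raises(ConfigError):
            epoch_sigma(rec, 5.0)


class TestMinuteAI:
    def sigmas(self, values, start=NOON, epoch_seconds=5.0):
        idx = pd.DatetimeIndex(
            start + pd.to_timedelta(np.arange(len(values)) * epoch_seconds, unit="s")
        )
        return EpochSigmaSeries(idx, np.asarray(values, float), 100, epoch_seconds)

    def test_constant_sigmas_sum(self):
        out = minute_ai(self.sigmas([0.5] * 12))
        assert len(out) == 1
        assert out.ai[0] == pytest.approx(6.0)
        assert out.epochs_per_minute == 12

    def test_rest_level_example(self):
        # 12 quiet epochs land below the 0.1 rest/sleep bound
        out = minute_ai(self.sigmas([0.008] * 12))
        assert out.ai[0] == pytest.approx(0.096)
        assert out.ai[0] < 0.1

    def test_matches_explicit_summation(self, rng):
        values = rng.uniform(0, 0.4, 60)
        out = minute_ai(self.sigmas(values))
        expected = values.reshape(5, 12).sum(axis=1)
        np.testing.assert_allclose(out.ai, expected, atol=1e-12, rtol=0)

    def test_unaligned_epochs_skipped_to_minute_boundary(self):
        out = minute_ai(self.sigmas([1.0] * 45, start=NOON + pd.Timedelta(seconds=15)))
        assert out.minute_start[0] == NOON + pd.Timedelta(minutes=1)
        assert len(out) == 3  # 45 epochs, 9 skipped to the boundary, 36 remain

    def test_non_multiple_interval_is_config_error(self):
        with pytest.raises(ConfigError):
            minute_ai(self.sigmas([1.0] * 12), interval_seconds=13.0)

    def test_irregular_epoch_stride_is_alignment_error(self):
        idx = pd.DatetimeIndex([NOON, NOON + pd.Timedelta(seconds=5), NOON + pd.Timedelta(seconds=11)])
        sig = EpochSigmaSeries(idx, np.ones(3), 100, 5.0)
        with pytest.raises(AlignmentError):
            minute_ai(sig)


class TestHourlyAI:
    def day(self):
        return DayWindow(NOON.date(), NOON, NOON + pd.Timedelta(hours=24))

    def test_all_ones_gives_sixty_per_hour(self):
        vec = hourly_ai(minutes_from_values(np.ones(1440)), self.day())
        np.testing.assert_allclose(vec.values, 60.0)

    def test_all_zeros(self):
        vec = hourly_ai(minutes_from_values(np.zeros(1440)), self.day())
        np.testing.assert_array_equal(vec.values, np.zeros(24))

    def test_conservation_and_noon_first_order(self, rng):
        values = rng.uniform(0, 5, 1440)
        minutes = minutes_from_values(values)
        vec = hourly_ai(minutes, self.day())
        assert vec.values.sum() == pytest.approx(values.sum(), abs=1e-9)
        assert vec.values[0] == pytest.approx(values[:60].sum())  # 12:00 hour first
        assert vec.values[-1] == pytest.approx(values[-60:].sum())  # 11:00 hour last

    def test_incomplete_day_raises_unless_overridden(self):
        minutes = minutes_from_values(np.ones(1000))
        with pytest.raises(CoverageError):
            hourly_ai(minutes, self.day())
        vec = hourly_ai(minutes, self.day(), allow_partial=True)
        assert vec.values.sum() == pytest.approx(1000.0)


class TestAggregationConservation:
    def test_epochs_to_minutes_to_hours_to_day(self, rng):
        xyz = rng.normal(0, 0.2, (1728000, 3)) + [0, 0, 1]  # one day at 20 Hz
        rec = recording_from_xyz(xyz)
        sig = epoch_sigma(rec)
        minutes = minute_ai(sig)
        assert len(minutes) == 1440
        assert minutes.ai.sum() == pytest.approx(sig.sigma.sum(), abs=1e-9)
        (win, sub), = split_days(minutes)
        vec = hourly_ai(sub, win)
        assert vec.values.sum() == pytest.approx(minutes.ai.sum(), abs=1e-9)
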