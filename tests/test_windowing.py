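"""Binarization, FFT window estimation, scaling, and sliding-window framing."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogadhere.cohort import CohortConfig, simulate_cohort
from cogadhere.windowing import (
    LabelRule,
    WindowingError,
    apply_scaler,
    binarize,
    estimate_window_size,
    fit_scaler,
    make_supervised,
)
from conftest import autocorr_period, periodic_series


class TestBinarize:
    @pytest.mark.parametrize(
        "seconds,expected",
        [(600.0, 1), (0.0, 0), (599.9, 0), (2700.0, 1)],
    )
    def test_ten_minute_threshold_boundary_is_adherent(self, seconds, expected):
        assert binarize(seconds, LabelRule()) == expected

    def test_negative_play_time_rejected(self):
        with pytest.raises(WindowingError):
            binarize(-1.0)

    @given(a=st.floats(0, 5000), b=st.floats(0, 5000))
    def test_monotone_in_play_seconds(self, a, b):
        lo, hi = sorted((a, b))
        assert binarize(lo) <= binarize(hi)


class TestEstimateWindowSize:
    def test_period5_sinusoid_over_30_days(self):
        x = periodic_series(5, 30)
        est = estimate_window_size(x)
        assert est.window_size == 5
        assert est.dominant_bin == 6
        assert not est.is_fallback
        assert autocorr_period(x) == 5  # independent oracle agrees

    def test_weekly_cycle_over_28_day_slice(self):
        x = periodic_series(7, 28)
        est = estimate_window_size(x)
        assert est.window_size == 7
        assert est.dominant_bin == 4
        assert autocorr_period(x) == 7

    def test_constant_series_falls_back(self):
        est = estimate_window_size(np.full(30, 2700.0), fallback=3)
        assert est.is_fallback and est.window_size == 3

    @pytest.mark.parametrize("period", [2, 3, 5, 6, 10])
    def test_period_recovery_noise_free(self, period):
        est = estimate_window_size(periodic_series(period, 30))
        assert est.window_size == period

    def test_agrees_with_autocorrelation_oracle_under_noise(self):
        """100 random periodic-plus-noise series at SNR >= 5: the FFT window
        matches the brute-force autocorrelation-peak oracle."""
        rng = np.random.default_rng(42)
        agree = 0
        for _ in range(100):
            period = int(rng.choice([2, 3, 5, 6, 10]))
            # unit-amplitude sinusoid (power 1/2); SNR 10 satisfies the >= 5 bound
            noise_sd = np.sqrt(0.5 / 10.0)
            x = periodic_series(period, 30, noise_sd=noise_sd, rng=rng)
            est = estimate_window_size(x)
            agree += est.window_size == autocorr_period(x) == period
        assert agree == 100

    def test_too_short_series_rejected(self):
        with pytest.raises(WindowingError):
            estimate_window_size(np.ones(3))

    def test_long_period_clamped_to_w_max(self):
        x = periodic_series(30, 30)  # one cycle -> bin 1 -> period 30
        est = estimate_window_size(x, w_max=10)
        assert est.window_size == 10 and est.dominant_bin == 1


class TestScaler:
    def test_min_max_arithmetic(self):
        col = np.array([[0.0], [1350.0], [2700.0]])
        stats = fit_scaler(col)
        np.testing.assert_allclose(
            apply_scaler(col, stats)[:, 0], [0.0, 0.5, 1.0]
        )

    def test_constant_column_maps_to_zero(self):
        col = np.full((5, 2), 7.0)
        assert (apply_scaler(col, fit_scaler(col)) == 0).all()

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(-1e4, 1e4), min_size=2, max_size=20, unique=True
        )
    )
    def test_affine_and_monotone_per_feature(self, values):
        col = np.array(values)[:, None]
        stats = fit_scaler(col)
        scaled = apply_scaler(col, stats)[:, 0]
        order = np.argsort(col[:, 0])
        assert (np.diff(scaled[order]) >= 0).all()
        assert scaled.min() == 0.0 and scaled.max() == 1.0


@pytest.fixture(scope="module")
def log():
    return simulate_cohort(CohortConfig(n_participants=1, seed=3))[0]


class TestMakeSupervised:
    def _estimate(self, w):
        from cogadhere.windowing import WindowSizeEstimate
        return WindowSizeEstimate("P000", w, 0, True)

    @pytest.mark.parametrize("w", range(2, 11))
    def test_count_law_all_window_sizes(self, log, w):
        split = make_supervised(log, self._estimate(w))
        assert len(split.train) == 30 - w
        assert len(split.test) == 30
        assert all(s.target_day <= 30 for s in split.train)
        assert all(s.target_day > 30 for s in split.test)

    def test_first_samples_and_labels(self, log):
        split = make_supervised(log, self._estimate(3))
        first = split.train[0]
        assert first.target_day == 4
        assert first.label == binarize(log.records[3].play_seconds)
        first_test = split.test[0]
        assert first_test.target_day == 31  # window covers days 28-30

    def test_features_are_normalized_training_scale(self, log):
        split = make_supervised(log, self._estimate(3))
        train_feats = np.concatenate([s.features for s in split.train])
        assert train_feats.min() >= 0.0 and train_feats.max() <= 1.0

    def test_leakage_freedom(self, log):
        """Mutating days 31-60 changes neither the scaler statistics nor the
        window estimate nor any training sample."""
        from cogadhere.cohort import DailyRecord
        from cogadhere.windowing import TRAIN_DAYS

        est = estimate_window_size(log.play_series()[:TRAIN_DAYS])
        split = make_supervised(log, est)
        mutated_records = list(log.records)
        for i in range(TRAIN_DAYS, 60):
            r = mutated_records[i]
            mutated_records[i] = DailyRecord(
                day_index=r.day_index,
                play_seconds=r.play_seconds + 5000.0,
                n_sessions=r.n_sessions + 3,
                max_level=r.max_level,
                n_tasks=r.n_tasks + 9,
            )
        mutated = dataclasses.replace(log, records=tuple(mutated_records))
        est2 = estimate_window_size(mutated.play_series()[:TRAIN_DAYS])
        split2 = make_supervised(mutated, est2)
        assert est2 == est
        np.testing.assert_array_equal(
            split2.scaler_stats.minimum, split.scaler_stats.minimum
        )
        np.testing.assert_array_equal(
            split2.scaler_stats.maximum, split.scaler_stats.maximum
        )
        for s1, s2 in zip(split.train, split2.train):
            np.testing.assert_array_equal(s1.features, s2.features)
            assert s1.label == s2.label

    def test_all_zero_log_gives_all_zero_labels(self):
        from cogadhere.cohort import DailyRecord, ParticipantLog

        records = tuple(
            DailyRecord(day_index=d, play_seconds=0.0, n_sessions=0,
                        max_level=0, n_tasks=0)
            for d in range(1, 61)
        )
        log = ParticipantLog("Z", records)
        split = make_supervised(log, self._estimate(3))
        assert all(s.label == 0 for s in split.train + split.test)
        assert all((s.features == 0).all() for s in split.train)

    def test_oversized_window_rejected(self, log):
        with pytest.raises(WindowingError):
            make_supervised(log, self._estimate(31))
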