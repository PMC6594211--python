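from __future__ import annotations

import numpy as np
import pytest

import oxiweek as ox
from oxiweek.cleaning import (
    BIN_INTERPOLATED,
    BIN_MISSING,
    BIN_VALID,
    CleaningError,
    autocorrelation_sampling_time,
    clean_segment,
    downsample_median,
    exclude_deviating_blocks,
    exclude_small_blocks,
    interpolate_gaps,
    quality_fractions,
    segment_context_mean,
)
from oxiweek.io_formats import CLEANED_OUT, ERROR, RAW_VALID

from .conftest import T0, spo2_from_offsets
from .oracles import brute_force_clean


def contiguous(values):
    return spo2_from_offsets(np.arange(len(values)), values)


class TestExcludeSmallBlocks:
    def test_short_run_between_errors_removed(self):
        values = [500] + [95] * 5 + [500]
        out = exclude_small_blocks(contiguous(values))
        assert out.status.tolist() == [ERROR] + [CLEANED_OUT] * 5 + [ERROR]

    def test_twenty_sample_run_retained(self):
        values = [500] + [95] * 20 + [500]
        out = exclude_small_blocks(contiguous(values))
        assert (out.status[1:21] == RAW_VALID).all()

    def test_run_touching_segment_edge_retained(self):
        values = [95] * 5 + [500]
        out = exclude_small_blocks(contiguous(values))
        assert (out.status[:5] == RAW_VALID).all()


class TestExcludeDeviatingBlocks:
    def test_deviating_block_removed(self):
        values = [500] + [85] * 50 + [500]
        out = exclude_deviating_blocks(contiguous(values), context_mean=93.0)
        assert (out.status[1:51] == CLEANED_OUT).all()

    def test_small_deviation_retained(self):
        values = [500] + [90] * 50 + [500]
        out = exclude_deviating_blocks(contiguous(values), context_mean=93.0)
        assert (out.status[1:51] == RAW_VALID).all()

    def test_deviation_of_exactly_six_retained(self):
        values = [500] + [87] * 50 + [500]
        out = exclude_deviating_blocks(contiguous(values), context_mean=93.0)
        assert (out.status[1:51] == RAW_VALID).all()

    def test_lengths_outside_window_untouched(self):
        for length in (19, 101):
            values = [500] + [80] * length + [500]
            out = exclude_deviating_blocks(contiguous(values), context_mean=93.0)
            assert not (out.status[1:1 + length] == CLEANED_OUT).any()

    def test_context_mean_is_pre_exclusion_nonerror_mean(self):
        series = contiguous([500, 90, 90, 500, 96, 96])
        assert segment_context_mean(series) == pytest.approx(93.0)


class TestDownsampleMedian:
    def test_constant_hour_gives_180_full_bins(self):
        series = contiguous([95] * 3600)
        cs = downsample_median(series, T0, T0 + np.timedelta64(3600, "s"))
        assert len(cs) == 180
        assert (cs.values == 95).all()
        assert (cs.status == BIN_VALID).all()

    def test_single_outlier_suppressed(self):
        series = contiguous([95] * 19 + [70])
        cs = downsample_median(series, T0, T0 + np.timedelta64(20, "s"))
        assert cs.values.tolist() == [95.0]

    def test_even_count_median_is_mean_of_central_pair(self):
        series = contiguous([90, 90, 91, 91])
        cs = downsample_median(series, T0, T0 + np.timedelta64(20, "s"))
        assert cs.values.tolist() == [90.5]

    def test_bin_with_no_valid_samples_missing(self):
        series = contiguous([500] * 20 + [95] * 20)
        cs = downsample_median(series, T0, T0 + np.timedelta64(40, "s"))
        assert np.isnan(cs.values[0]) and cs.status[0] == BIN_MISSING
        assert cs.values[1] == 95.0
        assert cs.n_raw_error.tolist() == [20, 0]


class TestInterpolateGaps:
    def make(self, values):
        status = np.where(np.isnan(values), BIN_MISSING, BIN_VALID).astype(np.int8)
        zeros = np.zeros(len(values), dtype=int)
        from oxiweek.cleaning import CleanSeries
        return CleanSeries(T0, 20, np.asarray(values, float), status, zeros, zeros, zeros)

    def test_linear_midpoint(self):
        cs = interpolate_gaps(self.make([94, np.nan, 96]))
        assert cs.values.tolist() == [94, 95, 96]
        assert cs.status[1] == BIN_INTERPOLATED

    def test_three_bin_gap_filled_linearly(self):
        cs = interpolate_gaps(self.make([92, np.nan, np.nan, np.nan, 96]))
        assert cs.values.tolist() == [92, 93, 94, 95, 96]

    def test_four_bin_gap_untouched(self):
        cs = interpolate_gaps(self.make([92, np.nan, np.nan, np.nan, np.nan, 96]))
        assert np.isnan(cs.values[1:5]).all()

    def test_edge_gaps_untouched(self):
        cs = interpolate_gaps(self.make([np.nan, 95, np.nan]))
        assert np.isnan(cs.values[0]) and np.isnan(cs.values[2])


class TestCleanSegment:
    def test_all_valid_hour(self):
        series = contiguous([95] * 3600)
        cs, qf = clean_segment(series, T0, T0 + np.timedelta64(3600, "s"))
        assert len(cs) == 180 and (cs.values == 95).all()
        assert (qf.fraction_error, qf.fraction_cleaned, qf.fraction_valid) == (0, 0, 1)

    def test_error_flanked_low_runs_removed(self):
        """Spuriously low values trapped between error runs are cleaned out."""
        clean = [93] * 600
        episode = [500] * 10 + [70] * 15 + [500] * 10 + [65] * 30 + [500] * 10
        values = clean + episode + clean
        series = contiguous(values)
        cs, qf = clean_segment(series, T0, T0 + np.timedelta64(len(values), "s"))
        assert qf.fraction_cleaned == pytest.approx(45 / len(values))
        assert qf.fraction_error == pytest.approx(30 / len(values))
        # no depressed value survives into the bins
        assert np.nanmin(cs.values) >= 90

    def test_empty_segment_refused(self):
        empty = spo2_from_offsets([], [])
        with pytest.raises(CleaningError, match="empty"):
            clean_segment(empty, T0, T0 + np.timedelta64(60, "s"))

    def test_idempotent_on_error_free_segment(self):
        """Cleaning an error-free segment only down-samples, removes nothing."""
        rng = np.random.default_rng(0)
        values = np.clip(np.rint(rng.normal(93, 2, 1200)), 0, 100).astype(int)
        series = contiguous(values)
        _, qf = clean_segment(series, T0, T0 + np.timedelta64(1200, "s"))
        assert qf.fraction_valid == 1.0

    def test_per_segment_independence(self):
        """Changing one segment's data never changes another segment's output."""
        a = contiguous([93] * 300)
        b1 = [500] * 5 + [60] * 10 + [500] * 5 + [95] * 280
        b2 = [95] * 300
        end = T0 + np.timedelta64(300, "s")
        out_a1, _ = clean_segment(a, T0, end)
        _ = clean_segment(contiguous(b1), T0, end)
        out_a2, _ = clean_segment(a, T0, end)
        _ = clean_segment(contiguous(b2), T0, end)
        np.testing.assert_array_equal(out_a1.values, out_a2.values)


class TestQualityFractions:
    def test_simple_arithmetic(self):
        status = np.array([ERROR] * 10 + [CLEANED_OUT] * 5 + [RAW_VALID] * 85)
        qf = quality_fractions(status)
        assert (qf.fraction_error, qf.fraction_cleaned, qf.fraction_valid) == (0.10, 0.05, 0.85)

    def test_fractions_sum_to_one_on_fuzzed_segments(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(50, 500))
            values = np.where(
                rng.random(n) < 0.1, 500, rng.integers(60, 100, n)
            )
            series = contiguous(values)
            _, qf = clean_segment(series, T0, T0 + np.timedelta64(n, "s"))
            assert qf.fraction_error + qf.fraction_cleaned + qf.fraction_valid == pytest.approx(
                1.0, abs=1e-9
            )

    def test_empty_scope_refused(self):
        with pytest.raises(CleaningError):
            quality_fractions(np.array([], dtype=np.int8))


class TestAutocorrelationSamplingTime:
    def test_white_noise_decorrelates_at_lag_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20000)
        assert autocorrelation_sampling_time(x, max_lag=50) == 1

    def test_constant_series_refused(self):
        with pytest.raises(CleaningError, match="constant"):
            autocorrelation_sampling_time(np.full(100, 95.0))

    def test_gap_aware_acf_ignores_invalid_samples(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 20000)
        valid = rng.random(20000) > 0.3
        x[~valid] = 500.0  # garbage that must not influence the estimate
        assert autocorrelation_sampling_time(x, valid=valid, max_lag=50) == 1


class TestOracleEquivalence:
    def test_random_segments_match_brute_force(self):
        """Vectorised cleaning equals the loop-based reference on fuzzed input."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(60, 600))
            values = rng.integers(80, 100, n)
            # inject error runs and deviating blocks
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, n))
                run = int(rng.integers(1, 30))
                values[s:s + run] = 500
            offsets = np.arange(n)
            duration = n + int(rng.integers(0, 40))
            bins, fate, counts = brute_force_clean(
                offsets.tolist(), values.tolist(), duration
            )
            series = spo2_from_offsets(offsets, values)
            cs, qf = clean_segment(series, T0, T0 + np.timedelta64(duration, "s"))
            expected = np.array([np.nan if b is None else b for b in bins])
            np.testing.assert_allclose(cs.values, expected, equal_nan=True)
            assert qf.fraction_error == pytest.approx(counts["error"] / n)
            assert qf.fraction_cleaned == pytest.approx(counts["cleaned"] / n)
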