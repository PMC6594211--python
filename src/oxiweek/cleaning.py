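"""Four-step SpO2 artifact cleaning and data-quality accounting.

The oximeter flags invalid measurements with the sentinel 500, but invalid
data (sudden low values) also surround these error values.  Per segment
(one night or one day), the cleaning algorithm therefore applies, in order:

1. exclude *small* runs of data (< 20 samples) lying between error values;
2. exclude *bigger* runs (20-100 samples) between error values whose mean
   deviates more than 6 percentage points from the mean of the full segment
   (computed over all non-error samples, before any exclusion);
3. down-sample by taking the median of each consecutive 20-s window (the
   median suppresses remaining isolated outliers);
4. fill gaps of at most 3 consecutive missing 20-s bins, strictly between
   valid bins, by linear interpolation.

Runs touching a segment boundary are never removed by steps 1-2: removal is
tied to being *between* error values.  The steps run once, sequentially; the
per-sample audit trail (valid / error / cleaned_out) is preserved so that
quality fractions can be accounted for any sub-population of raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CleaningConfig
from .io_formats import CLEANED_OUT, ERROR, RAW_VALID, Spo2Series

# bin status codes
BIN_VALID = 0
BIN_MISSING = 1
BIN_INTERPOLATED = 2


class CleaningError(ValueError):
    """Raised for inputs the cleaning stage refuses (e.g. empty segments)."""


@dataclass
class CleanSeries:
    """20-s binned SpO2 series for one segment.

    ``values[i]`` is the median SpO2 of raw valid samples in the window
    ``[start + i*bin_seconds, start + (i+1)*bin_seconds)`` (NaN when the
    window holds none and the gap was not interpolated).  ``n_raw_valid`` /
    ``n_raw_error`` / ``n_raw_cleaned`` record each bin's raw-sample
    provenance.
    """

    start: np.datetime64
    bin_seconds: int
    values: np.ndarray
    status: np.ndarray
    n_raw_valid: np.ndarray
    n_raw_error: np.ndarray
    n_raw_cleaned: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def bin_times(self) -> np.ndarray:
        """Start timestamp of every bin."""
        base = self.start.astype("datetime64[s]").astype("int64")
        return (base + np.arange(len(self.values), dtype="int64") * self.bin_seconds).astype(
            "datetime64[s]"
        )

    @property
    def nonmissing(self) -> np.ndarray:
        return self.status != BIN_MISSING


@dataclass(frozen=True)
class QualityFractions:
    """Proportions of raw 1-Hz samples by fate; they sum to one."""

    fraction_error: float
    fraction_cleaned: float
    fraction_valid: float
    n_samples: int

    def as_dict(self) -> dict[str, float]:
        return {
            "fraction_error": self.fraction_error,
            "fraction_cleaned": self.fraction_cleaned,
            "fraction_valid": self.fraction_valid,
        }


def _nonerror_runs(status: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of non-error samples as (start, stop, bounded_both_sides).

    ``bounded_both_sides`` is True iff the run is adjacent to an error sample
    on both sides, i.e. does not touch either segment boundary.
    """
    nonerr = status != ERROR
    if not nonerr.any():
        return []
    padded = np.concatenate(([False], nonerr, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    n = len(status)
    return [(int(a), int(b), a > 0 and b < n) for a, b in zip(starts, stops)]


def exclude_small_blocks(series: Spo2Series, cfg: CleaningConfig = CleaningConfig()) -> Spo2Series:
    """Mark runs of < 20 non-error samples between error values as cleaned out."""
    status = series.status.copy()
    for a, b, bounded in _nonerror_runs(series.status):
        if bounded and (b - a) <= cfg.small_block_max:
            status[a:b] = CLEANED_OUT
    return Spo2Series(series.timestamps, series.values, status)


def segment_context_mean(series: Spo2Series) -> float:
    """Mean SpO2 of all non-error samples of the segment, before exclusions."""
    nonerr = series.status != ERROR
    if not nonerr.any():
        raise CleaningError("segment has no non-error samples; context mean undefined")
    return float(series.values[nonerr].mean())


def exclude_deviating_blocks(
    series: Spo2Series,
    context_mean: float,
    cfg: CleaningConfig = CleaningConfig(),
) -> Spo2Series:
    """Mark 20-100 sample runs between errors deviating > 6 points from the segment mean.

    The deviation is absolute percentage points of SpO2 by default
    (``cfg.dev_relative`` switches to percent of the context mean).  Samples
    already marked cleaned out keep that status; run boundaries are defined
    by error samples only.
    """
    status = series.status.copy()
    for a, b, bounded in _nonerror_runs(series.status):
        length = b - a
        if not (bounded and cfg.dev_block_min <= length <= cfg.dev_block_max):
            continue
        block_mean = float(series.values[a:b].mean())
        deviation = abs(block_mean - context_mean)
        if cfg.dev_relative:
            deviation = 100.0 * deviation / context_mean
        if deviation > cfg.dev_threshold:
            status[a:b] = CLEANED_OUT
    return Spo2Series(series.timestamps, series.values, status)


def downsample_median(
    series: Spo2Series,
    start: np.datetime64,
    end: np.datetime64,
    cfg: CleaningConfig = CleaningConfig(),
) -> CleanSeries:
    """Median down-sampling into consecutive bins aligned to the segment start.

    Bin value = median of raw-valid samples in the window (even counts: mean
    of the two central values); a bin with no valid sample is missing.
    """
    start = np.datetime64(start, "s")
    end = np.datetime64(end, "s")
    span = int((end - start).astype("int64"))
    if span <= 0:
        raise CleaningError("segment interval must have positive duration")
    n_bins = -(-span // cfg.bin_seconds)  # ceil
    secs = series.seconds
    offsets = secs - start.astype("int64")
    if len(offsets) and (offsets.min() < 0 or offsets.max() >= span):
        raise CleaningError("samples fall outside the segment interval")
    bin_idx = offsets // cfg.bin_seconds

    n_valid = np.bincount(bin_idx[series.status == RAW_VALID], minlength=n_bins)
    n_error = np.bincount(bin_idx[series.status == ERROR], minlength=n_bins)
    n_cleaned = np.bincount(bin_idx[series.status == CLEANED_OUT], minlength=n_bins)

    values = np.full(n_bins, np.nan)
    valid_mask = series.status == RAW_VALID
    if valid_mask.any():
        med = (
            pd.Series(series.values[valid_mask].astype(float))
            .groupby(bin_idx[valid_mask])
            .median()
        )
        values[med.index.to_numpy()] = med.to_numpy()
    status = np.where(np.isnan(values), BIN_MISSING, BIN_VALID).astype(np.int8)
    return CleanSeries(start, cfg.bin_seconds, values, status, n_valid, n_error, n_cleaned)


def interpolate_gaps(cs: CleanSeries, cfg: CleaningConfig = CleaningConfig()) -> CleanSeries:
    """Fill missing-bin runs of length <= 3 strictly between valid bins.

    Interpolation is linear between the flanking bin values; longer runs and
    runs touching a segment edge stay missing.
    """
    values = cs.values.copy()
    status = cs.status.copy()
    missing = status == BIN_MISSING
    if missing.any():
        padded = np.concatenate(([False], missing, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            if a == 0 or b == len(values):
                continue  # touches a segment edge
            if (b - a) > cfg.max_interp_gap_bins:
                continue
            left, right = values[a - 1], values[b]
            idx = np.arange(a, b)
            values[idx] = left + (right - left) * (idx - (a - 1)) / (b - (a - 1))
            status[idx] = BIN_INTERPOLATED
    return CleanSeries(
        cs.start, cs.bin_seconds, values, status,
        cs.n_raw_valid, cs.n_raw_error, cs.n_raw_cleaned,
    )


def clean_segment_audit(
    series: Spo2Series,
    start: np.datetime64,
    end: np.datetime64,
    cfg: CleaningConfig = CleaningConfig(),
) -> tuple[CleanSeries, QualityFractions, Spo2Series]:
    """Full cleaning plus the audited per-sample series.

    Like :func:`clean_segment` but additionally returns the raw series with
    its post-exclusion sample statuses, which downstream quality accounting
    per activity class needs.
    """
    if len(series) == 0:
        raise CleaningError("cannot clean an empty segment")
    if (series.status == CLEANED_OUT).any():
        raise CleaningError("segment already carries cleaned_out samples")
    step1 = exclude_small_blocks(series, cfg)
    if (series.status != ERROR).any():
        context = segment_context_mean(series)
        step2 = exclude_deviating_blocks(step1, context, cfg)
    else:
        step2 = step1
    cs = downsample_median(step2, start, end, cfg)
    cs = interpolate_gaps(cs, cfg)
    return cs, quality_fractions(step2.status), step2


def clean_segment(
    series: Spo2Series,
    start: np.datetime64,
    end: np.datetime64,
    cfg: CleaningConfig = CleaningConfig(),
) -> tuple[CleanSeries, QualityFractions]:
    """Run the full cleaning algorithm on one segment's raw samples.

    Returns the 20-s cleaned series plus quality fractions over the raw
    samples (error / cleaned-out / valid).
    """
    cs, qf, _ = clean_segment_audit(series, start, end, cfg)
    return cs, qf


def quality_fractions(status: np.ndarray, mask: np.ndarray | None = None) -> QualityFractions:
    """Error / cleaned / valid fractions of raw samples in the masked scope."""
    status = np.asarray(status)
    if mask is not None:
        status = status[np.asarray(mask)]
    n = len(status)
    if n == 0:
        raise CleaningError("quality fractions undefined for an empty scope")
    n_err = int((status == ERROR).sum())
    n_cleaned = int((status == CLEANED_OUT).sum())
    return QualityFractions(
        fraction_error=n_err / n,
        fraction_cleaned=n_cleaned / n,
        fraction_valid=(n - n_err - n_cleaned) / n,
        n_samples=n,
    )


def autocorrelation_sampling_time(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    max_lag: int = 600,
    threshold: float = CleaningConfig().acf_threshold,
) -> int:
    """Decorrelation lag (seconds) of a 1-Hz signal from its sample ACF.

    The autocorrelation is computed mean-removed and gap-aware: lag-k
    products run only over pairs whose two samples are both valid.  Returns
    the smallest lag at which the ACF falls below ``threshold`` (default
    1/e); this is the sampling time at which consecutive retained samples
    become essentially decorrelated.
    """
    x = np.asarray(values, dtype=float)
    m = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    if m.sum() < 2:
        raise CleaningError("need at least two valid samples for autocorrelation")
    xm = x[m].mean()
    xc = np.where(m, x - xm, 0.0)
    denom = float((xc[m] ** 2).sum())
    if denom == 0.0:
        raise CleaningError("autocorrelation undefined for a constant series")
    max_lag = min(max_lag, len(x) - 1)
    for k in range(1, max_lag + 1):
        pair = m[:-k] & m[k:]
        if not pair.any():
            continue
        num = float((xc[:-k] * xc[k:])[pair].sum())
        # normalise by the lag-0 sum restricted to paired samples to stay
        # comparable across lags with different pair counts
        d = float((xc[:-k][pair] ** 2).sum() * (xc[k:][pair] ** 2).sum()) ** 0.5
        if d == 0.0:
            continue
        if num / d < threshold:
            return k
    raise CleaningError(f"autocorrelation stayed above threshold up to lag {max_lag}")
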