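"""Per-period SpO2 features, sleep metrics, weekly aggregation and the
nocturnal-desaturator classification.

Features are computed on the cleaned 20-s series: mean SpO2, SpO2 SD
(sample SD), CT90 (percentage of valid measured time spent with SpO2 below
90%) and, for days in rest, the within-day range (max - min).  A patient is
a nocturnal desaturator on a given night when CT90 exceeds 30% ("below 90%
for more than 30% of the time"; both inequalities strict per that wording).
Over a week a patient is a consistent desaturator (every night above the
threshold), a consistent nondesaturator (every night at or below it) or an
occasional desaturator (nights on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cleaning import CleanSeries
from .config import FeatureConfig
from .io_formats import ActigraphySeries
from .segmentation import BedInterval

CONSISTENT_DESATURATOR = "consistent_desaturator"
CONSISTENT_NONDESATURATOR = "consistent_nondesaturator"
OCCASIONAL_DESATURATOR = "occasional_desaturator"


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class PeriodFeatures:
    mean_spo2: float
    spo2_sd: float
    ct90: float
    n_valid_bins: int
    range_spo2: float | None = None


@dataclass(frozen=True)
class SleepMetrics:
    """Per-night sleep metrics from the armband indications.

    tnst: total night sleeping time, the sum of in-bed minutes scored as
    sleep.  waso: wake after sleep onset, awake in-bed minutes strictly
    after the first sleep minute.  seff: sleep efficiency, TNST as a
    percentage of time in bed.  Identity: onset latency + TNST + WASO =
    time in bed.
    """

    tnst: float
    waso: float
    seff: float
    time_in_bed: float

    @property
    def onset_latency(self) -> float:
        return self.time_in_bed - self.tnst - self.waso


def period_features(
    cs: CleanSeries,
    threshold: float = FeatureConfig().spo2_threshold,
    bin_mask: np.ndarray | None = None,
    with_range: bool = False,
) -> PeriodFeatures:
    """Mean, SD and CT90 of a cleaned series (optionally over a bin subset).

    Interpolated bins count as data; the SD is the sample SD (n-1, zero for
    a single bin); CT90 is the percentage of non-missing bins with value
    strictly below the threshold.
    """
    values = cs.values if bin_mask is None else cs.values[np.asarray(bin_mask)]
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        raise FeatureError("period has no non-missing bins")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    ct90 = 100.0 * float((values < threshold).sum()) / n
    rng = float(values.max() - values.min()) if with_range else None
    return PeriodFeatures(mean, sd, ct90, n, rng)


def day_rest_range(rest_values: np.ndarray) -> float:
    """Within-day SpO2 range (max - min) over the valid rest bins of one day."""
    values = np.asarray(rest_values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise FeatureError("no rest bins for day range")
    return float(values.max() - values.min())


def sleep_metrics(act: ActigraphySeries, bed: BedInterval) -> SleepMetrics:
    """TNST, WASO and sleep efficiency for one bed interval."""
    secs = act.seconds
    lo = np.searchsorted(secs, bed.bed_start.astype("datetime64[s]").astype("int64"))
    hi = np.searchsorted(secs, bed.bed_end.astype("datetime64[s]").astype("int64"))
    in_bed_sleep = act.sleep[lo:hi]
    time_in_bed = bed.minutes
    tnst = float((in_bed_sleep == 1).sum())
    onsets = np.flatnonzero(in_bed_sleep == 1)
    if len(onsets) == 0:
        return SleepMetrics(0.0, 0.0, 0.0, time_in_bed)
    waso = float((in_bed_sleep[onsets[0]:] == 0).sum())
    seff = 100.0 * tnst / time_in_bed if time_in_bed > 0 else 0.0
    return SleepMetrics(tnst, waso, seff, time_in_bed)


def classify_desaturator(
    nightly_ct90: Sequence[float],
    threshold: float = FeatureConfig().ct90_threshold,
) -> str:
    """Weekly desaturator category from per-night CT90 values.

    Strictly more than ``threshold`` percent on every night makes a
    consistent desaturator; at or below on every night a consistent
    nondesaturator; anything mixed an occasional desaturator.  At least two
    nights are required for the category to be meaningful.
    """
    ct90 = np.asarray(list(nightly_ct90), dtype=float)
    if len(ct90) < 2:
        raise FeatureError("desaturator category requires at least two nights")
    above = ct90 > threshold
    if above.all():
        return CONSISTENT_DESATURATOR
    if not above.any():
        return CONSISTENT_NONDESATURATOR
    return OCCASIONAL_DESATURATOR


def two_night_vs_week_category(
    nightly_ct90: Sequence[float],
    threshold: float = FeatureConfig().ct90_threshold,
) -> bool:
    """Whether a two-night protocol would misjudge the weekly category.

    Short protocols measure only one or two nights.  The flag is raised when
    the first two nights are concordant (both desaturating or both not) yet
    the full week is occasional, i.e. the patient crosses the threshold only
    after night two.  Patients already mixed within the first two nights are
    not flagged: a two-night measurement would itself have revealed the
    inconsistency.  Night order matters, unlike the weekly category.
    """
    ct90 = list(nightly_ct90)
    if len(ct90) < 2:
        raise FeatureError("two-night comparison requires at least two nights")
    first_two = classify_desaturator(ct90[:2], threshold)
    week = classify_desaturator(ct90, threshold)
    return first_two != week


def weekly_summary(per_period: dict[str, Sequence[float]]) -> dict[str, dict[str, float]]:
    """Weekly average and range (max - min) per feature over retained periods."""
    out: dict[str, dict[str, float]] = {}
    for feature, values in per_period.items():
        arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
        if len(arr) == 0:
            continue
        out[feature] = {
            "average": float(arr.mean()),
            "range": float(arr.max() - arr.min()),
            "n_periods": int(len(arr)),
        }
    return out


def afternoon_evening_diff(
    afternoon_rest_values: Iterable[float],
    evening_rest_values: Iterable[float],
) -> float:
    """Per-day afternoon-minus-evening difference of mean SpO2 in rest.

    Positive values mean higher afternoon SpO2.  Eligibility (at least one
    hour of measurements in each window) is established upstream by the
    segmentation's clock windows; here each window must still contribute at
    least one valid rest bin.
    """
    aft = np.asarray([v for v in afternoon_rest_values if not np.isnan(v)], dtype=float)
    eve = np.asarray([v for v in evening_rest_values if not np.isnan(v)], dtype=float)
    if len(aft) == 0 or len(eve) == 0:
        raise FeatureError("both windows need at least one valid rest bin")
    return float(aft.mean() - eve.mean())
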