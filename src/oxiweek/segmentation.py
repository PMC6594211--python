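"""Actigraphy-based segmentation of the SpO2 stream.

The armband's lying-down and sleep indications delimit the time of going to
bed and of getting out of bed.  Nights are the bed intervals; days are the
out-of-bed intervals between consecutive nights.  Retention rules: only
full-night nocturnal recordings are kept (coverage of at least 90% of the
bed interval by default) and daytime recordings with at least one hour of
SpO2 samples.  Daytime samples are further partitioned by activity level
from the per-minute MET values: rest (MET <= 1.5 while awake), LIPA
(1.5 < MET <= 3) and MVPA (MET > 3).

All intervals are half-open ``[start, end)``; each actigraphy minute's
values apply to the 60 seconds it covers (step expansion, no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FeatureConfig, SegmentationConfig
from .io_formats import ActigraphySeries, Spo2Series

# activity label codes for 1-s samples
REST = 0
LIPA = 1
MVPA = 2
ASLEEP = 3
UNALIGNED = 4

ACTIVITY_NAMES = {REST: "rest", LIPA: "lipa", MVPA: "mvpa", ASLEEP: "asleep", UNALIGNED: "unaligned"}


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class BedInterval:
    """One night's in-bed interval, ``[bed_start, bed_end)``."""

    bed_start: np.datetime64
    bed_end: np.datetime64

    def __post_init__(self) -> None:
        if not self.bed_end > self.bed_start:
            raise SegmentationError("bed_end must be after bed_start")

    @property
    def minutes(self) -> float:
        return float((self.bed_end - self.bed_start).astype("timedelta64[s]").astype("int64")) / 60.0


@dataclass
class Segment:
    """One night (bed interval) or one day (out-of-bed interval) of SpO2 data."""

    kind: str  # "night" | "day"
    start: np.datetime64
    end: np.datetime64
    spo2: Spo2Series
    bed: BedInterval | None = None
    unsegmentable: bool = False

    @property
    def date(self) -> str:
        """Calendar date labelling the period (date of the interval start)."""
        return str(self.start.astype("datetime64[D]"))

    @property
    def duration_seconds(self) -> int:
        return int((self.end - self.start).astype("timedelta64[s]").astype("int64"))

    @property
    def n_samples(self) -> int:
        return len(self.spo2)


@dataclass
class Exclusion:
    period_date: str
    period_kind: str
    rule: str
    measured: float


def detect_bed_intervals(
    act: ActigraphySeries, cfg: SegmentationConfig = SegmentationConfig()
) -> list[BedInterval]:
    """Detect nightly bed intervals from lying/sleep indications.

    A bed interval is a maximal run of consecutive lying minutes that
    contains at least one sleep minute and lasts at least
    ``cfg.min_bed_minutes`` (shorter lying runs are naps or couch rest, not
    nights).  A night without a qualifying run is simply absent from the
    result.
    """
    if len(act) == 0:
        raise SegmentationError("cannot detect bed intervals in empty actigraphy")
    secs = act.seconds
    lying = act.lying == 1
    # runs must be contiguous in time (60-s steps) as well as in lying state
    contiguous = np.concatenate(([True], np.diff(secs) == 60))
    run_break = np.concatenate(([True], (~contiguous[1:]) | (lying[1:] != lying[:-1])))
    run_id = np.cumsum(run_break)
    intervals: list[BedInterval] = []
    for rid in np.unique(run_id):
        idx = np.flatnonzero(run_id == rid)
        if not lying[idx[0]]:
            continue
        if len(idx) < cfg.min_bed_minutes:
            continue
        if not (act.sleep[idx] == 1).any():
            continue
        start = act.timestamps[idx[0]]
        end = act.timestamps[idx[-1]] + np.timedelta64(60, "s")
        intervals.append(BedInterval(start, end))
    return intervals


def split_day_night(spo2: Spo2Series, beds: list[BedInterval]) -> list[Segment]:
    """Assign every SpO2 sample to exactly one night or day segment.

    Night segments coincide with the bed intervals; day segments span the
    gaps between consecutive bed intervals, plus a leading/trailing segment
    when samples exist before the first or after the last night.  With no
    bed intervals at all, a single all-day segment flagged ``unsegmentable``
    is returned (excluded downstream).  Empty segments are dropped.
    """
    if len(spo2) == 0:
        raise SegmentationError("cannot segment an empty SpO2 series")
    secs = spo2.seconds
    if not beds:
        return [
            Segment(
                "day",
                spo2.timestamps[0],
                spo2.timestamps[-1] + np.timedelta64(1, "s"),
                spo2,
                unsegmentable=True,
            )
        ]
    beds = sorted(beds, key=lambda b: b.bed_start)
    boundaries: list[tuple[str, np.datetime64, np.datetime64, BedInterval | None]] = []
    first_start = min(spo2.timestamps[0], beds[0].bed_start)
    last_end = max(spo2.timestamps[-1] + np.timedelta64(1, "s"), beds[-1].bed_end)
    cursor = first_start
    for bed in beds:
        if bed.bed_start > cursor:
            boundaries.append(("day", cursor, bed.bed_start, None))
        boundaries.append(("night", bed.bed_start, bed.bed_end, bed))
        cursor = bed.bed_end
    if last_end > cursor:
        boundaries.append(("day", cursor, last_end, None))

    segments: list[Segment] = []
    for kind, start, end, bed in boundaries:
        lo = np.searchsorted(secs, start.astype("datetime64[s]").astype("int64"), side="left")
        hi = np.searchsorted(secs, end.astype("datetime64[s]").astype("int64"), side="left")
        if hi <= lo:
            continue
        segments.append(Segment(kind, start, end, spo2.slice(slice(lo, hi)), bed=bed))
    return segments


def apply_retention_rules(
    segments: list[Segment], cfg: SegmentationConfig = SegmentationConfig()
) -> tuple[list[Segment], list[Exclusion]]:
    """Apply the retention rules; every exclusion is logged with its reason.

    Days are retained with at least one hour of SpO2 samples; nights when
    the recording covers at least the full-night coverage fraction of the
    bed interval.
    """
    retained: list[Segment] = []
    exclusions: list[Exclusion] = []
    for seg in segments:
        if seg.unsegmentable:
            exclusions.append(Exclusion(seg.date, seg.kind, "unsegmentable", seg.n_samples))
            continue
        if seg.kind == "day":
            if seg.n_samples >= cfg.min_day_seconds:
                retained.append(seg)
            else:
                exclusions.append(Exclusion(seg.date, seg.kind, "under one hour", seg.n_samples))
        else:
            coverage = seg.n_samples / seg.duration_seconds
            if coverage >= cfg.night_coverage_fraction:
                retained.append(seg)
            else:
                exclusions.append(Exclusion(seg.date, seg.kind, "not full night", coverage))
    return retained, exclusions


def sample_activity_labels(
    spo2: Spo2Series,
    act: ActigraphySeries,
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Per-sample activity labels from the covering actigraphy minute.

    Each 1-s sample inherits the MET and sleep flag of the actigraphy minute
    containing it.  Minutes with sleep=1 label their samples asleep; awake
    minutes label rest (MET <= 1.5, boundary inclusive), LIPA
    (1.5 < MET <= 3) or MVPA (MET > 3).  Samples without a covering minute
    are unaligned and excluded from activity-specific features.
    """
    labels = np.full(len(spo2), UNALIGNED, dtype=np.int8)
    if len(act) == 0 or len(spo2) == 0:
        return labels
    minute_secs = act.seconds
    sample_minutes = (spo2.seconds // 60) * 60
    pos = np.searchsorted(minute_secs, sample_minutes)
    pos_clip = np.clip(pos, 0, len(minute_secs) - 1)
    covered = minute_secs[pos_clip] == sample_minutes
    met = act.met[pos_clip]
    sleep = act.sleep[pos_clip]
    lab = np.where(
        sleep == 1,
        ASLEEP,
        np.where(met <= cfg.rest_met_max, REST, np.where(met <= cfg.lipa_met_max, LIPA, MVPA)),
    ).astype(np.int8)
    labels[covered] = lab[covered]
    return labels


def partition_by_activity(
    day_segment: Segment,
    act: ActigraphySeries,
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """ActivityMask for one day segment (see :func:`sample_activity_labels`)."""
    if day_segment.kind != "day":
        raise SegmentationError("activity partition applies to day segments")
    return sample_activity_labels(day_segment.spo2, act, cfg)


@dataclass(frozen=True)
class ClockWindows:
    """Wall-clock sub-windows of a day segment (half-open, local time)."""

    morning: tuple[np.datetime64, np.datetime64]
    afternoon: tuple[np.datetime64, np.datetime64]
    evening: tuple[np.datetime64, np.datetime64]
    afternoon_eligible: bool
    evening_eligible: bool


def clock_windows(
    day_segment: Segment, cfg: SegmentationConfig = SegmentationConfig()
) -> ClockWindows:
    """Morning/afternoon/evening windows of a day segment.

    Afternoon is 13:00-18:00 and evening 18:00 to going to bed (the segment
    end); the morning window (before 13:00) is computed for completeness but
    no morning contrast is reported.  A window is eligible for the
    afternoon-evening comparison only when it holds at least one hour of
    SpO2 samples.
    """
    if day_segment.kind != "day":
        raise SegmentationError("clock windows apply to day segments")
    day = day_segment.start.astype("datetime64[D]")
    t13 = (day + np.timedelta64(13, "h")).astype("datetime64[s]")
    t18 = (day + np.timedelta64(18, "h")).astype("datetime64[s]")
    start = day_segment.start.astype("datetime64[s]")
    end = day_segment.end.astype("datetime64[s]")
    morning = (start, min(t13, end))
    afternoon = (max(t13, start), min(t18, end))
    evening = (max(t18, start), end)

    def n_in(window: tuple[np.datetime64, np.datetime64]) -> int:
        a, b = window
        if b <= a:
            return 0
        secs = day_segment.spo2.seconds
        lo = np.searchsorted(secs, a.astype("int64"))
        hi = np.searchsorted(secs, b.astype("int64"))
        return int(hi - lo)

    return ClockWindows(
        morning,
        afternoon,
        evening,
        afternoon_eligible=n_in(afternoon) >= cfg.min_window_seconds,
        evening_eligible=n_in(evening) >= cfg.min_window_seconds,
    )
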