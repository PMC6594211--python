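from __future__ import annotations

import numpy as np
import pytest

import oxiweek as ox
from oxiweek.segmentation import (
    ASLEEP,
    LIPA,
    MVPA,
    REST,
    UNALIGNED,
    SegmentationError,
    clock_windows,
    sample_activity_labels,
)

from .conftest import T0, minutes_act, spo2_from_offsets
from .oracles import brute_force_activity_labels


def simple_night_act(base=T0):
    """Lying 23:00-07:00 with sleep 23:20-06:40, awake around it."""
    met, lying, sleep = [], [], []
    for minute in range(0, 1440 + 8 * 60):  # midnight to 08:00 next day
        in_lying = 23 * 60 <= minute < 31 * 60
        in_sleep = 23 * 60 + 20 <= minute < 30 * 60 + 40
        lying.append(1 if in_lying else 0)
        sleep.append(1 if in_sleep else 0)
        met.append(0.9 if in_lying else 1.2)
    return minutes_act(0, met, lying, sleep, base)


class TestDetectBedIntervals:
    def test_single_lying_run_with_sleep(self):
        act = simple_night_act()
        beds = ox.detect_bed_intervals(act)
        assert len(beds) == 1
        assert beds[0].bed_start == T0 + np.timedelta64(23 * 3600, "s")
        assert beds[0].bed_end == T0 + np.timedelta64(31 * 3600, "s")

    def test_afternoon_nap_below_threshold_ignored(self):
        met = [1.2] * 1440
        lying = [0] * 1440
        sleep = [0] * 1440
        for minute in range(14 * 60, 15 * 60):  # 60-min nap
            lying[minute] = 1
            sleep[minute] = 1
        act = minutes_act(0, met, lying, sleep)
        assert ox.detect_bed_intervals(act) == []

    def test_lying_without_sleep_not_a_bed(self):
        met = [0.9] * 400
        act = minutes_act(0, met, [1] * 400, [0] * 400)
        assert ox.detect_bed_intervals(act) == []

    def test_recovery_of_generator_truth_within_one_minute(self):
        pw = ox.generate_patient_week(ox.PatientProfile(seed=11, n_days=3))
        beds = ox.detect_bed_intervals(pw.act)
        assert len(beds) == len(pw.truth.bed_intervals)
        for found, true in zip(beds, pw.truth.bed_intervals):
            assert abs((found.bed_start - true.bed_start).astype("int64")) <= 60
            assert abs((found.bed_end - true.bed_end).astype("int64")) <= 60


class TestSplitDayNight:
    def bed(self, start_h, end_h):
        return ox.BedInterval(
            T0 + np.timedelta64(start_h * 3600, "s"), T0 + np.timedelta64(end_h * 3600, "s")
        )

    def test_sample_at_bed_start_belongs_to_night(self):
        bed = self.bed(23, 31)
        offsets = [23 * 3600 - 1, 23 * 3600]
        segs = ox.split_day_night(spo2_from_offsets(offsets, [95, 95]), [bed])
        kinds = {s.kind: s.n_samples for s in segs}
        assert kinds == {"day": 1, "night": 1}

    def test_no_bed_intervals_gives_unsegmentable_day(self):
        segs = ox.split_day_night(spo2_from_offsets([0, 1, 2], [95, 95, 95]), [])
        assert len(segs) == 1 and segs[0].unsegmentable
        retained, exclusions = ox.apply_retention_rules(segs)
        assert retained == [] and exclusions[0].rule == "unsegmentable"

    def test_every_sample_assigned_exactly_once(self):
        rng = np.random.default_rng(5)
        offsets = np.sort(rng.choice(72 * 3600, size=5000, replace=False))
        spo2 = spo2_from_offsets(offsets, np.full(5000, 95))
        beds = [self.bed(23, 31), self.bed(47, 55)]
        segs = ox.split_day_night(spo2, beds)
        assert sum(s.n_samples for s in segs) == 5000
        # no timestamp appears in two segments
        seen = np.concatenate([s.spo2.seconds for s in segs])
        assert len(np.unique(seen)) == len(seen)


class TestRetentionRules:
    def test_day_under_one_hour_excluded(self):
        seg = ox.Segment(
            "day", T0, T0 + np.timedelta64(10 * 3600, "s"),
            spo2_from_offsets(np.arange(59 * 60), np.full(59 * 60, 95)),
        )
        retained, exclusions = ox.apply_retention_rules([seg])
        assert retained == []
        assert exclusions[0].rule == "under one hour"
        assert exclusions[0].measured == 59 * 60

    def test_night_with_high_coverage_retained(self):
        n = int(0.95 * 8 * 3600)
        bed = ox.BedInterval(T0, T0 + np.timedelta64(8 * 3600, "s"))
        seg = ox.Segment(
            "night", bed.bed_start, bed.bed_end,
            spo2_from_offsets(np.arange(n), np.full(n, 92)), bed=bed,
        )
        retained, _ = ox.apply_retention_rules([seg])
        assert retained == [seg]

    def test_partial_night_excluded_with_coverage_logged(self):
        n = 4 * 3600
        bed = ox.BedInterval(T0, T0 + np.timedelta64(8 * 3600, "s"))
        seg = ox.Segment(
            "night", bed.bed_start, bed.bed_end,
            spo2_from_offsets(np.arange(n), np.full(n, 92)), bed=bed,
        )
        retained, exclusions = ox.apply_retention_rules([seg])
        assert retained == []
        assert exclusions[0].rule == "not full night"
        assert exclusions[0].measured == pytest.approx(0.5)

    def test_retained_counts_match_brute_force_scan(self):
        pw = ox.generate_patient_week(ox.PatientProfile(seed=13, n_days=4))
        beds = ox.detect_bed_intervals(pw.act)
        segs = ox.split_day_night(pw.spo2, beds)
        retained, exclusions = ox.apply_retention_rules(segs)
        expected = 0
        for seg in segs:  # independent per-segment recount
            n = len(seg.spo2)
            if seg.kind == "day":
                keep = n >= 3600
            else:
                keep = n / seg.duration_seconds >= 0.9
            expected += int(keep)
        assert len(retained) == expected
        assert len(retained) + len(exclusions) == len(segs)


class TestActivityPartition:
    def test_met_boundaries(self):
        # three minutes: MET 1.5 awake (rest, inclusive), 3.0 (lipa), 3.01 (mvpa)
        act = minutes_act(0, [1.5, 3.0, 3.01], [0, 0, 0], [0, 0, 0])
        spo2 = spo2_from_offsets(np.arange(180), np.full(180, 95))
        labels = sample_activity_labels(spo2, act)
        assert (labels[:60] == REST).all()
        assert (labels[60:120] == LIPA).all()
        assert (labels[120:180] == MVPA).all()

    def test_sleeping_minute_overrides_met(self):
        act = minutes_act(0, [1.0], [1], [1])
        spo2 = spo2_from_offsets(np.arange(60), np.full(60, 95))
        assert (sample_activity_labels(spo2, act) == ASLEEP).all()

    def test_uncovered_samples_unaligned(self):
        act = minutes_act(0, [1.0], [0], [0])
        spo2 = spo2_from_offsets([30, 90], [95, 95])  # second sample past coverage
        labels = sample_activity_labels(spo2, act)
        assert labels.tolist() == [REST, UNALIGNED]

    def test_labels_match_brute_force_lookup(self):
        rng = np.random.default_rng(21)
        n_min = 60
        met = rng.uniform(0.8, 5.0, n_min)
        sleep = (rng.random(n_min) < 0.2).astype(int)
        lying = np.maximum(sleep, (rng.random(n_min) < 0.3).astype(int))
        # actigraphy with a hole: minutes 20-29 missing
        keep = np.ones(n_min, dtype=bool)
        keep[20:30] = False
        ts = T0 + np.flatnonzero(keep) * np.timedelta64(60, "s")
        act = ox.ActigraphySeries(ts, met[keep], lying[keep], sleep[keep])
        offsets = np.sort(rng.choice(n_min * 60, 500, replace=False))
        spo2 = spo2_from_offsets(offsets, np.full(500, 95))
        labels = sample_activity_labels(spo2, act)
        from oxiweek.segmentation import ACTIVITY_NAMES
        expected = brute_force_activity_labels(
            offsets.tolist(),
            (np.flatnonzero(keep) * 60).tolist(),
            met[keep].tolist(),
            sleep[keep].tolist(),
        )
        assert [ACTIVITY_NAMES[l] for l in labels] == expected

    def test_partition_completeness_on_generated_day(self):
        pw = ox.generate_patient_week(ox.PatientProfile(seed=17, n_days=2))
        beds = ox.detect_bed_intervals(pw.act)
        segs = [s for s in ox.split_day_night(pw.spo2, beds) if s.kind == "day"]
        for seg in segs:
            labels = ox.partition_by_activity(seg, pw.act)
            counts = sum(int((labels == code).sum()) for code in range(5))
            assert counts == seg.n_samples


class TestClockWindows:
    def test_window_bounds_and_eligibility(self):
        # day segment 08:00-23:00 with samples 13:30-20:00
        start = T0 + np.timedelta64(8 * 3600, "s")
        end = T0 + np.timedelta64(23 * 3600, "s")
        offsets = np.arange(int(13.5 * 3600), 20 * 3600)
        seg = ox.Segment("day", start, end, spo2_from_offsets(offsets, np.full(len(offsets), 95)))
        w = clock_windows(seg)
        assert w.afternoon == (T0 + np.timedelta64(13 * 3600, "s"), T0 + np.timedelta64(18 * 3600, "s"))
        assert w.evening == (T0 + np.timedelta64(18 * 3600, "s"), end)
        assert w.afternoon_eligible and w.evening_eligible

    def test_sparse_window_not_eligible(self):
        start = T0 + np.timedelta64(8 * 3600, "s")
        end = T0 + np.timedelta64(23 * 3600, "s")
        offsets = np.arange(13 * 3600, 13 * 3600 + 1800)  # 30 min only
        seg = ox.Segment("day", start, end, spo2_from_offsets(offsets, np.full(1800, 95)))
        w = clock_windows(seg)
        assert not w.afternoon_eligible

    def test_night_segment_rejected(self):
        seg = ox.Segment("night", T0, T0 + np.timedelta64(3600, "s"), spo2_from_offsets([0], [95]))
        with pytest.raises(SegmentationError):
            clock_windows(seg)
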