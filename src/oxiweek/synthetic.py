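"""Synthetic patient-weeks of raw SpO2 and actigraphy with known ground truth.

The study's raw data are not publicly deposited, so every pipeline stage is
exercised against generated patient-weeks that emulate the structure of
week-long home recordings:

* a circadian SpO2 baseline with a lower nocturnal level and a slightly
  lower evening level, plus slow Gaussian AR(1) fluctuation (SD ~1-2
  percentage points) and integer quantisation;
* transient nocturnal desaturation events (half-sine dips of a few
  percentage points lasting minutes);
* artifact episodes in which runs of the 500 error sentinel alternate with
  short runs of spuriously low values, so that invalid data lies *between*
  error values exactly as the block-exclusion rules expect; episode
  frequency scales with activity level (motion artifacts are concentrated
  in MVPA);
* isolated single-sample outliers;
* realistic bed intervals (lying+sleep indications, onset latency, brief
  awakenings that make WASO nonzero) and daytime MET profiles spanning
  rest, LIPA and MVPA, with daytime wear gaps (device off).

Every stochastic draw flows from one ``numpy`` Generator seeded by the
profile, so a fixed seed reproduces the output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .features import classify_desaturator, two_night_vs_week_category
from .io_formats import (
    ERROR_SENTINEL,
    ActigraphySeries,
    Spo2Series,
    write_actigraphy_csv,
    write_spo2_csv,
)
from .segmentation import BedInterval

# per-sample ground-truth labels
LABEL_CLEAN = 0
LABEL_ARTIFACT = 1
LABEL_OUTLIER = 2
LABEL_ERROR = 3

LABEL_NAMES = {LABEL_CLEAN: "clean", LABEL_ARTIFACT: "artifact",
               LABEL_OUTLIER: "outlier", LABEL_ERROR: "error"}


class ProfileError(ValueError):
    """Raised when a profile field is invalid; the message names the field."""


@dataclass(frozen=True)
class PatientProfile:
    """Generator parameters for one synthetic patient-week.

    Units: SpO2 levels and depths in percentage points, rates per hour,
    durations in seconds unless noted, ``time_in_bed_mean`` in minutes,
    ``bed_time_mean`` as a wall-clock ``HH:MM`` string.
    ``nocturnal_baselines`` optionally fixes the per-night baseline (one
    value per night), overriding ``baseline_day_spo2 - nocturnal_drop``;
    ``night_low_fraction`` carves a contiguous block covering that fraction
    of each night down by ``night_low_depth`` points (a deterministic way to
    design a night's CT90).
    """

    baseline_day_spo2: float = 95.0
    nocturnal_drop: float = 2.0
    intraperiod_sd: float = 1.5
    desat_event_rate: float = 1.0
    desat_event_depth: float = 6.0
    desat_event_duration: float = 120.0
    artifact_burst_rate: float = 1.0
    outlier_rate: float = 0.001
    bed_time_mean: str = "23:00"
    time_in_bed_mean: float = 500.0
    n_days: int = 7
    seed: int = 0
    # secondary structure
    nocturnal_baselines: tuple[float, ...] | None = None
    night_low_fraction: float = 0.0
    night_low_depth: float = 4.0
    evening_dip: float = 0.0
    ar1_phi: float = 0.995
    artifact_weights: tuple[float, float, float, float] = (0.25, 1.0, 2.0, 16.0)
    start_date: str = "2017-01-02"

    def __post_init__(self) -> None:
        def require(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ProfileError(f"invalid {name}: {why}")

        require(0 < self.baseline_day_spo2 <= 100, "baseline_day_spo2", "must be in (0, 100]")
        require(self.nocturnal_drop >= 0, "nocturnal_drop", "must be nonnegative")
        require(self.intraperiod_sd >= 0, "intraperiod_sd", "must be nonnegative")
        require(self.desat_event_rate >= 0, "desat_event_rate", "must be nonnegative")
        require(self.desat_event_depth >= 0, "desat_event_depth", "must be nonnegative")
        require(self.desat_event_duration > 0, "desat_event_duration", "must be positive")
        require(self.artifact_burst_rate >= 0, "artifact_burst_rate", "must be nonnegative")
        require(0 <= self.outlier_rate < 1, "outlier_rate", "must be a fraction in [0, 1)")
        require(self.time_in_bed_mean > 0, "time_in_bed_mean", "must be positive")
        require(self.n_days >= 1, "n_days", "must be at least 1")
        require(0 <= self.night_low_fraction <= 1, "night_low_fraction", "must be in [0, 1]")
        require(0 <= self.ar1_phi < 1, "ar1_phi", "must be in [0, 1)")
        parts = self.bed_time_mean.split(":")
        ok = len(parts) == 2 and parts[0].isdigit() and parts[1].isdigit()
        require(ok and 0 <= int(parts[0]) < 24 and 0 <= int(parts[1]) < 60,
                "bed_time_mean", "must be HH:MM")
        if self.nocturnal_baselines is not None:
            require(len(self.nocturnal_baselines) == self.n_days,
                    "nocturnal_baselines", "needs one value per night")

    @property
    def bed_minute_of_day(self) -> int:
        h, m = self.bed_time_mean.split(":")
        return int(h) * 60 + int(m)


@dataclass
class GroundTruth:
    """Designed truth for one patient-week.

    Per-night means/CT90 are computed from the *true* (uncorrupted, integer)
    samples; per-sample labels record each sample's fate; the designed
    desaturator category is derived from the true per-night CT90 via the
    30% rule.
    """

    bed_intervals: list[BedInterval]
    night_dates: list[str]
    night_true_mean: list[float]
    night_true_ct90: list[float]
    day_dates: list[str]
    day_true_mean: list[float]
    labels: np.ndarray
    designed_category: str | None
    designed_two_night_discordant: bool | None

    def label_counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for code, name in LABEL_NAMES.items()}


@dataclass
class PatientWeek:
    patient_id: str
    profile: PatientProfile
    spo2: Spo2Series
    act: ActigraphySeries
    truth: GroundTruth


def generate_patient_week(profile: PatientProfile, patient_id: str = "p01") -> PatientWeek:
    """Generate one patient-week of raw streams plus ground truth."""
    rng = np.random.default_rng(profile.seed)
    t0 = np.datetime64(profile.start_date, "s")
    n_days = profile.n_days

    # --- bed intervals (minute offsets from t0) ---------------------------
    bed_start_min = np.empty(n_days, dtype=np.int64)
    bed_end_min = np.empty(n_days, dtype=np.int64)
    for d in range(n_days):
        jitter = int(np.rint(rng.uniform(-30, 30)))
        start = d * 1440 + profile.bed_minute_of_day + jitter
        duration = int(np.clip(np.rint(rng.normal(profile.time_in_bed_mean, 25)), 400, 650))
        bed_start_min[d] = start
        bed_end_min[d] = start + duration
    n_min = int(bed_end_min[-1])
    n_sec = n_min * 60

    # --- actigraphy -------------------------------------------------------
    met = rng.uniform(1.0, 1.45, n_min)
    lying = np.zeros(n_min, dtype=np.int8)
    sleep = np.zeros(n_min, dtype=np.int8)
    for d in range(n_days):
        getup = 450 if d == 0 else int(bed_end_min[d - 1])
        awake_lo, awake_hi = getup + 60, int(bed_start_min[d]) - 30
        for _ in range(int(rng.integers(2, 5))):  # LIPA bouts
            length = int(rng.integers(10, 41))
            if awake_hi - length <= awake_lo:
                continue
            s = int(rng.integers(awake_lo, awake_hi - length))
            met[s:s + length] = rng.uniform(1.6, 2.8, length)
        for _ in range(int(rng.integers(1, 3))):  # MVPA bouts
            length = int(rng.integers(5, 16))
            if awake_hi - length <= awake_lo:
                continue
            s = int(rng.integers(awake_lo, awake_hi - length))
            met[s:s + length] = rng.uniform(3.2, 5.0, length)
        # in-bed minutes
        a, b = int(bed_start_min[d]), int(bed_end_min[d])
        lying[a:b] = 1
        met[a:b] = 0.9
        latency = int(rng.integers(5, 31))
        sleep[a + latency:b] = 1
        waso_target = int(np.clip(np.rint(rng.normal(74, 36)), 10, 150))
        n_bouts = int(rng.integers(2, 6))
        bout_lengths = rng.multinomial(waso_target, np.full(n_bouts, 1.0 / n_bouts))
        for length in bout_lengths:
            length = int(length)
            lo, hi = a + latency + 5, b - 5 - length
            if length <= 0 or hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            sleep[s:s + length] = 0

    act = ActigraphySeries(
        t0 + np.arange(n_min, dtype="int64") * np.timedelta64(60, "s"),
        met, lying, sleep,
    )

    # --- SpO2 wear mask (seconds) ----------------------------------------
    worn = np.zeros(n_sec, dtype=bool)
    for d in range(n_days):
        worn[bed_start_min[d] * 60:bed_end_min[d] * 60] = True  # nights: full bed interval
        if d == 0:
            wear_start = int(rng.uniform(12 * 3600, 14 * 3600))
        else:
            wear_start = int(bed_end_min[d - 1]) * 60 + int(rng.uniform(5 * 3600, 7 * 3600))
        wear_end = int(bed_start_min[d]) * 60
        if wear_start >= wear_end:
            continue
        worn[wear_start:wear_end] = True
        for _ in range(int(rng.poisson(2))):  # device-off gaps
            gap_len = int(rng.uniform(15, 60)) * 60
            s = int(rng.uniform(wear_start, max(wear_start + 1, wear_end - gap_len)))
            worn[s:min(s + gap_len, wear_end)] = False

    # --- true signal ------------------------------------------------------
    level = np.full(n_sec, profile.baseline_day_spo2)
    if profile.evening_dip:
        sec_of_day = np.arange(n_sec, dtype=np.int64) % 86400
        level[sec_of_day >= 18 * 3600] -= profile.evening_dip
    night_baselines = (
        np.asarray(profile.nocturnal_baselines, dtype=float)
        if profile.nocturnal_baselines is not None
        else np.full(n_days, profile.baseline_day_spo2 - profile.nocturnal_drop)
    )
    for d in range(n_days):
        a, b = int(bed_start_min[d]) * 60, int(bed_end_min[d]) * 60
        level[a:b] = night_baselines[d]
        if profile.night_low_fraction > 0:
            block = int(np.floor(profile.night_low_fraction * (b - a)))
            offset = int(rng.integers(0, (b - a) - block + 1)) if block < (b - a) else 0
            level[a + offset:a + offset + block] -= profile.night_low_depth
        n_events = int(rng.poisson(profile.desat_event_rate * (b - a) / 3600.0))
        for _ in range(n_events):
            dur = max(10, int(np.rint(profile.desat_event_duration * rng.uniform(0.8, 1.2))))
            s = int(rng.integers(a, b))
            e = min(s + dur, b)
            shape = np.sin(np.pi * np.arange(e - s) / dur)
            level[s:e] -= profile.desat_event_depth * shape

    if profile.intraperiod_sd > 0:
        phi = profile.ar1_phi
        innov_sd = profile.intraperiod_sd * np.sqrt(1.0 - phi * phi)
        eps = rng.standard_normal(n_sec) * innov_sd
        x0 = rng.standard_normal() * profile.intraperiod_sd
        noise, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    else:
        noise = np.zeros(n_sec)

    sec_idx = np.flatnonzero(worn)
    v_true = np.clip(np.rint(level[sec_idx] + noise[sec_idx]), 0, 100).astype(np.int16)
    n_worn = len(sec_idx)

    # --- corruption -------------------------------------------------------
    labels = np.zeros(n_worn, dtype=np.int8)
    obs = v_true.copy()
    minute_idx = sec_idx // 60
    asleep_or_bed = (lying[minute_idx] == 1)
    sample_met = met[minute_idx]
    w_bed, w_rest, w_lipa, w_mvpa = profile.artifact_weights
    weights = np.where(
        asleep_or_bed, w_bed,
        np.where(sample_met <= 1.5, w_rest, np.where(sample_met <= 3.0, w_lipa, w_mvpa)),
    )
    if profile.artifact_burst_rate > 0 and n_worn > 0:
        expected = profile.artifact_burst_rate / 3600.0 * float(weights.sum())
        n_ep = int(rng.poisson(expected))
        err_mask = np.zeros(n_worn, dtype=bool)
        dep_mask = np.zeros(n_worn, dtype=bool)
        if n_ep > 0:
            centers = rng.choice(n_worn, size=n_ep, p=weights / weights.sum())
            for c in centers:
                n_dep = int(rng.integers(1, 4))
                err_lens = rng.geometric(0.1, n_dep + 1)
                dep_lens = rng.integers(1, 41, n_dep)
                pos = int(c)
                for i in range(n_dep + 1):
                    e = min(pos + int(err_lens[i]), n_worn)
                    err_mask[pos:e] = True
                    pos = e
                    if i < n_dep:
                        e = min(pos + int(dep_lens[i]), n_worn)
                        dep_mask[pos:e] = True
                        pos = e
        dep_mask &= ~err_mask
        n_dep_total = int(dep_mask.sum())
        obs[dep_mask] = np.maximum(
            v_true[dep_mask] - np.rint(rng.uniform(10, 30, n_dep_total)).astype(np.int16), 0
        )
        obs[err_mask] = ERROR_SENTINEL
        labels[dep_mask] = LABEL_ARTIFACT
        labels[err_mask] = LABEL_ERROR
    if profile.outlier_rate > 0 and n_worn > 0:
        clean_idx = np.flatnonzero(labels == LABEL_CLEAN)
        n_out = int(rng.binomial(len(clean_idx), profile.outlier_rate))
        if n_out > 0:
            chosen = rng.choice(clean_idx, size=n_out, replace=False)
            obs[chosen] = np.maximum(
                v_true[chosen] - np.rint(rng.uniform(5, 25, n_out)).astype(np.int16), 0
            )
            labels[chosen] = LABEL_OUTLIER

    spo2 = Spo2Series(t0 + sec_idx * np.timedelta64(1, "s"), obs)

    # --- ground truth -----------------------------------------------------
    beds = [
        BedInterval(t0 + bed_start_min[d] * np.timedelta64(60, "s"),
                    t0 + bed_end_min[d] * np.timedelta64(60, "s"))
        for d in range(n_days)
    ]
    night_dates, night_mean, night_ct90 = [], [], []
    for d in range(n_days):
        mask = (sec_idx >= bed_start_min[d] * 60) & (sec_idx < bed_end_min[d] * 60)
        vals = v_true[mask]
        night_dates.append(str(beds[d].bed_start.astype("datetime64[D]")))
        night_mean.append(float(vals.mean()))
        night_ct90.append(100.0 * float((vals < 90).mean()))
    day_dates, day_mean = [], []
    in_bed_sample = np.zeros(n_worn, dtype=bool)
    for d in range(n_days):
        in_bed_sample |= (sec_idx >= bed_start_min[d] * 60) & (sec_idx < bed_end_min[d] * 60)
    day_sec = sec_idx[~in_bed_sample]
    day_vals = v_true[~in_bed_sample]
    if len(day_sec):
        day_of = day_sec // 86400
        for d in np.unique(day_of):
            m = day_of == d
            day_dates.append(str((t0 + int(d) * np.timedelta64(86400, "s")).astype("datetime64[D]")))
            day_mean.append(float(day_vals[m].mean()))

    category = classify_desaturator(night_ct90) if n_days >= 2 else None
    discordant = two_night_vs_week_category(night_ct90) if n_days >= 2 else None
    truth = GroundTruth(
        bed_intervals=beds,
        night_dates=night_dates,
        night_true_mean=night_mean,
        night_true_ct90=night_ct90,
        day_dates=day_dates,
        day_true_mean=day_mean,
        labels=labels,
        designed_category=category,
        designed_two_night_discordant=discordant,
    )
    return PatientWeek(patient_id, profile, spo2, act, truth)


def _occasional_sides(rng: np.random.Generator, j: int, n_late: int, n_days: int) -> list[int]:
    """Per-night side pattern (1 = desaturating night) for an occasional patient.

    Patients ``j < n_late`` are concordant over the first two nights and
    cross the threshold only afterwards; the rest are already mixed within
    the first two nights.
    """
    if n_days < 3:
        raise ProfileError("invalid n_days: occasional patients need at least 3 nights")
    if j < n_late:
        side = j % 2
        cross = 2 + int(rng.integers(0, n_days - 2))
        return [side] * cross + [1 - side] * (n_days - cross)
    side = j % 2
    sides = [side, 1 - side]
    sides += [int(rng.integers(0, 2)) for _ in range(n_days - 2)]
    return sides


def simulate_cohort(
    n_consistent_desat: int,
    n_consistent_nondesat: int,
    n_occasional: int,
    seed: int,
    n_days: int = 7,
) -> list[PatientWeek]:
    """Generate a cohort with designed desaturator categories.

    Consistent desaturators receive nocturnal baselines well below 90,
    consistent nondesaturators well above, and occasional desaturators
    alternate per night between levels just below and just above 90 (so
    their nightly mean SpO2 sits near 90).  Within the occasional group,
    60% are designed to cross the threshold only after the first two
    nights.  Within-period SD is inversely tied to the nocturnal baseline,
    emulating the larger fluctuations of more hypoxemic patients.
    """
    for name, n in (("n_consistent_desat", n_consistent_desat),
                    ("n_consistent_nondesat", n_consistent_nondesat),
                    ("n_occasional", n_occasional)):
        if n < 0:
            raise ProfileError(f"invalid {name}: must be nonnegative")
    master = np.random.default_rng(seed)
    n_total = n_consistent_desat + n_consistent_nondesat + n_occasional
    n_late = int(round(0.6 * n_occasional))
    cohort: list[PatientWeek] = []
    for i in range(n_total):
        pseed = int(master.integers(0, 2**31 - 1))
        if i < n_consistent_desat:
            base_night = float(master.uniform(84.5, 87.5))
            nightly = base_night + master.uniform(-0.4, 0.4, n_days)
            base_day = base_night + 2.0
            intended = "consistent_desaturator"
        elif i < n_consistent_desat + n_consistent_nondesat:
            base_night = float(master.uniform(92.5, 94.5))
            nightly = base_night + master.uniform(-0.4, 0.4, n_days)
            base_day = base_night + 2.0
            intended = "consistent_nondesaturator"
        else:
            j = i - n_consistent_desat - n_consistent_nondesat
            sides = _occasional_sides(master, j, n_late, n_days)
            nightly = np.array(
                [88.5 if s else 91.5 for s in sides]
            ) + master.uniform(-0.3, 0.3, n_days)
            base_night = float(nightly.mean())
            base_day = 92.0
            intended = "occasional_desaturator"
        profile = PatientProfile(
            baseline_day_spo2=base_day,
            nocturnal_drop=max(0.0, base_day - base_night),
            intraperiod_sd=float(np.clip(1.5 + 0.15 * (92.0 - base_night), 0.8, 3.0)),
            desat_event_rate=float(master.uniform(0.5, 2.0)),
            desat_event_depth=float(master.uniform(4.0, 8.0)),
            desat_event_duration=float(master.uniform(60.0, 180.0)),
            artifact_burst_rate=1.0,
            outlier_rate=0.001,
            n_days=n_days,
            seed=pseed,
            nocturnal_baselines=tuple(float(b) for b in nightly),
            evening_dip=0.8,
        )
        pw = generate_patient_week(profile, patient_id=f"p{i + 1:02d}")
        if pw.truth.designed_category != intended:
            raise RuntimeError(
                f"cohort design failed for {pw.patient_id}: intended {intended}, "
                f"true CT90 gives {pw.truth.designed_category}"
            )
        cohort.append(pw)
    return cohort


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "designed_category": truth.designed_category,
        "designed_two_night_discordant": truth.designed_two_night_discordant,
        "nights": [
            {
                "date": date,
                "bed_start": str(bed.bed_start),
                "bed_end": str(bed.bed_end),
                "true_mean_spo2": mean,
                "true_ct90": ct90,
            }
            for date, bed, mean, ct90 in zip(
                truth.night_dates, truth.bed_intervals,
                truth.night_true_mean, truth.night_true_ct90,
            )
        ],
        "days": [
            {"date": date, "true_mean_spo2": mean}
            for date, mean in zip(truth.day_dates, truth.day_true_mean)
        ],
        "label_counts": truth.label_counts(),
    }


def write_patient_week(pw: PatientWeek, out_dir: str | Path) -> Path:
    """Write one patient's raw CSV streams plus the ground-truth sidecar."""
    pdir = Path(out_dir) / pw.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    write_spo2_csv(pw.spo2, pdir / "spo2.csv")
    write_actigraphy_csv(pw.act, pdir / "actigraphy.csv")
    with open(pdir / "truth.json", "w") as fh:
        json.dump(truth_to_dict(pw.truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return pdir


def generate_cohort(
    n_consistent_desat: int,
    n_consistent_nondesat: int,
    n_occasional: int,
    seed: int,
    out_dir: str | Path,
    n_days: int = 7,
) -> Path:
    """Generate a cohort and write one directory per patient."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pw in simulate_cohort(
        n_consistent_desat, n_consistent_nondesat, n_occasional, seed, n_days=n_days
    ):
        write_patient_week(pw, out)
    return out
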