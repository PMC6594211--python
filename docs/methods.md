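# Methods

This document specifies the algorithms implemented by `oxiweek`, the model
behind the synthetic generator, all tunable parameters, and the rationale
for the open design decisions.

## 1. Input data

Two time-aligned streams per patient:

- **SpO2**: 1 Hz integer saturation in percent; the device reports the
  sentinel value **500** for samples it could not measure (error values).
  Timestamps are strictly increasing but need not be contiguous (device
  off / not worn).
- **Actigraphy**: one record per minute with energy expenditure in MET,
  and binary *lying* and *sleep* indications (sleep implies lying).

All intervals in the package are half-open `[start, end)`: a sample at a
boundary instant belongs to the interval starting there.

## 2. Artifact cleaning

Cleaning operates independently on each day/night segment; nothing from
one segment influences another. Four steps, in order:

1. **Small-block exclusion.** Within the segment, maximal runs of
   non-error samples *bounded on both sides by error values* and shorter
   than 20 samples are excluded. Runs touching the segment edge are never
   excluded by this rule (they are not bounded by errors on both sides).
2. **Deviating-block exclusion.** Bounded runs of 20–100 samples whose
   mean deviates by **more than** 6 SpO2 points (absolute difference,
   strict inequality) from the segment's *pre-exclusion* mean of all
   non-error samples are excluded. The context mean is computed once,
   before either exclusion step, so exclusion order cannot affect it.
3. **Median down-sampling.** The segment timeline is divided into 20-s
   bins aligned to the segment start. Each bin's value is the median of
   its surviving valid samples (even counts: the mean of the central
   pair). Bins without valid samples are missing. A median tolerates up
   to half-minus-one one-sided outliers per bin without leaving the range
   of the clean samples.
4. **Gap interpolation.** Missing-bin runs of 1–3 bins lying strictly
   between valid bins are filled by linear interpolation between the
   neighbouring bin values. Runs of 4+ bins and runs touching the segment
   edge stay missing. Interpolated bins are flagged and count as data in
   downstream features.

**Quality accounting.** Every raw sample ends in exactly one of three
states: *error* (sentinel), *cleaned-out* (removed by step 1 or 2), or
*valid*. Fractions are reported per period and per activity scope; the
cohort report aggregates them weighted by raw sample count.

**Effective sampling time.** `autocorrelation_sampling_time` estimates the
signal's decorrelation lag as the first lag at which the normalized
autocorrelation drops below 1/e, using a gap-aware estimator that only
multiplies pairs of valid samples. For an AR(1) process with coefficient
φ the theoretical value is −1/ln φ; the estimator is validated against
that closed form. This justifies the 20-s bin width: genuine SpO2
physiology decorrelates far slower than the bin, so down-sampling loses
little information while suppressing single-sample artifact.

## 3. Day/night segmentation

- **Bed detection.** A bed interval is a maximal run of contiguous lying
  minutes of at least **180 min** that contains at least one sleep
  minute. Shorter lying runs (naps) and lying without sleep do not count.
- **Split.** Nights are the bed intervals; days are the gaps between
  consecutive bed intervals (and the leading/trailing gaps). If no bed
  interval exists, the whole record is a single *unsegmentable* period,
  which is excluded with that reason.
- **Retention.** A day is retained when it contains at least **3600**
  SpO2 samples (one hour of data). A night is retained when its sample
  coverage of the in-bed interval is at least **0.9**. Exclusions are
  logged with rule and measured value.
- **Activity classes.** Each SpO2 sample takes the label of the
  actigraphy minute covering it: *asleep* when the minute is scored
  sleep; otherwise *rest* (MET ≤ 1.5), *LIPA* (1.5 < MET ≤ 3), *MVPA*
  (MET > 3). Samples not covered by any actigraphy minute are
  *unaligned*. Binned features map each 20-s bin to the label at the
  bin's midpoint.
- **Clock windows.** Within a day segment, the afternoon window is
  [13:00, 18:00) and the evening window [18:00, bed start). Each is
  eligible when it contains at least one hour of samples; the
  afternoon-vs-evening contrast is computed only for days where both are
  eligible and yield at least one valid rest bin.

## 4. Features

Computed on the cleaned 20-s series, over non-missing bins:

- **mean SpO2**; **SpO2 SD** (sample SD, n−1; zero for a single bin);
- **CT90**: percentage of non-missing bins strictly below 90 % — the
  denominator is *measured* time, not elapsed time, so missing data does
  not dilute the estimate;
- **range** (max − min), reported for days in rest;
- **sleep metrics** per night: TNST (in-bed minutes scored sleep), WASO
  (awake in-bed minutes strictly after the first sleep minute), sleep
  efficiency (100·TNST/time-in-bed). Identity: onset latency + TNST +
  WASO = time in bed.

**Weekly aggregation** reports per feature the average and the range
(max − min) over retained periods, with the period count.

**Desaturator classification.** A night desaturates when CT90 **> 30 %**
(strict, from "below 90 % for more than 30 % of the time"). With at
least two nights: all nights above → *consistent desaturator*; none
above → *consistent nondesaturator*; mixed → *occasional desaturator*.
The **two-night discordance flag** is true when the category computed
from the first two nights (in time order) differs from the weekly
category — i.e. a short recording would have misjudged the patient. A
patient already mixed within the first two nights is not flagged, because
a two-night recording would itself have revealed the inconsistency.

**Cohort statistics.** Paired t test (two-sided, Student t with n−1 df)
for night vs day-rest weekly mean SpO2; Pearson correlation (p via the t
transform, n−2 df) for weekly SpO2 SD vs mean SpO2. Both are computed
from their defining sums and cross-checked against scipy in the tests. No
multiple-testing correction is applied.

## 5. Synthetic generator

`generate_patient_week(PatientProfile)` builds, in order: a bed schedule,
an actigraphy stream, a wear mask, a true SpO2 level curve, AR(1) noise,
integer truth samples, and finally the corrupted observed stream. All
randomness flows from a single `numpy.random.default_rng(seed)`.

### Signal model

- **Level.** Daytime level `baseline_day_spo2`; each night an independent
  baseline (default `baseline_day_spo2 − nocturnal_drop`, or fixed
  per-night via `nocturnal_baselines`). Optional deterministic
  structures: `night_low_fraction` carves a contiguous block covering
  that fraction of each night down by `night_low_depth` points (designing
  a night's CT90 by construction), and `evening_dip` lowers the level
  linearly through the evening hours.
- **Desaturation events.** Poisson-placed half-sine dips of depth
  `desat_event_depth` and duration `desat_event_duration` at rate
  `desat_event_rate` per hour during the night.
- **Noise.** Gaussian AR(1) with coefficient `ar1_phi` (default 0.995)
  scaled to stationary SD `intraperiod_sd`, added to the level; samples
  are rounded to integers and clipped to [0, 100]. These integer samples
  are the ground truth from which per-night true means and true CT90 are
  computed.
- **Corruption.** Artifact *episodes* alternate error bursts (sentinel
  500; geometric lengths, mean 10 s) with depressed runs (uniform 1–40 s,
  10–30 points below truth), so that invalid data lies *between error
  values* — the situation the cleaning rules are defined to detect.
  Episode rate is `artifact_burst_rate` per hour, weighted by activity
  (`artifact_weights` for bed/rest/LIPA/MVPA, default 0.25/1/2/16:
  movement causes artifact). Isolated single-sample outliers occur at
  probability `outlier_rate` per sample. Every sample carries a label
  (clean / artifact / outlier / error) in the ground truth.
- **Behaviour.** Bed start jitters around `bed_time_mean`, time in bed
  around `time_in_bed_mean` (minutes). Within bed: onset latency
  U(5, 30) min awake, then sleep with WASO bouts (multinomial placement,
  total targeted around N(74, 36²) truncated at 0 in the cohort design).
  Days contain LIPA and MVPA bouts over a rest background and brief
  non-wear gaps.

### Parameters (units, defaults)

| Parameter | Unit | Default | Meaning |
| --- | --- | --- | --- |
| `baseline_day_spo2` | % | 95 | daytime SpO2 level |
| `nocturnal_drop` | points | 2 | default day→night level drop |
| `intraperiod_sd` | points | 1.5 | stationary SD of AR(1) noise |
| `ar1_phi` | – | 0.995 | AR(1) coefficient (1 Hz) |
| `desat_event_rate` | /h | 1 | nocturnal desaturation events |
| `desat_event_depth` | points | 6 | event depth (half-sine) |
| `desat_event_duration` | s | 120 | event duration |
| `artifact_burst_rate` | /h | 1 | artifact episodes (activity-weighted) |
| `artifact_weights` | – | (0.25, 1, 2, 16) | episode-rate weights bed/rest/LIPA/MVPA |
| `outlier_rate` | /sample | 0.001 | isolated outliers |
| `bed_time_mean` | HH:MM | 23:00 | mean bed time |
| `time_in_bed_mean` | min | 500 | mean time in bed |
| `night_low_fraction` | – | 0 | fraction of night carved low |
| `night_low_depth` | points | 4 | depth of the carved block |
| `evening_dip` | points | 0 | linear evening decline |
| `n_days` | d | 7 | days per record |
| `seed` | – | 0 | RNG seed |

### Cohort design

`simulate_cohort(n_desat, n_nondesat, n_occasional, seed)` draws night
baselines U(84.5, 87.5) for consistent desaturators and U(92.5, 94.5) for
consistent nondesaturators; occasional patients alternate designed
desaturating (88.5) and non-desaturating (91.5) nights (± 0.3). Of the
occasional patients, `round(0.6·n)` are designed *late crossers*: their
first two nights are concordant and the threshold is crossed only later,
so exactly they raise the two-night discordance flag. `intraperiod_sd` is
set to `clip(1.5 + 0.15·(92 − night baseline), 0.8, 3.0)`, producing the
inverse correlation between SpO2 variability and mean seen in cohort
statistics; cohort profiles use `evening_dip = 0.8`. After generation the
designed categories are verified against the true per-night CT90 and a
mismatch raises an error rather than silently shipping a mislabeled
cohort.

### What the generator emulates — and does not

Emulated: the day/night level structure, sustained and event-like
nocturnal desaturation, movement-dependent artifact, sentinel-coded
errors, device-off gaps, realistic sleep architecture at the
minute-resolution of actigraphy. Not emulated: respiratory-event
periodicity (e.g. apnea cycling), heart-rate coupling, sensor drift or
calibration bias, posture transitions inside a minute, and any
patient-to-patient correlation structure beyond the designed parameters.

## 6. Numerical and design decisions

- **Artifact episodes rather than isolated flanked blocks.** The cleaning
  rules remove runs *between error values*; the generator therefore
  produces corrupted data inside error-bounded episodes. An artifact
  model that deposits bad data away from error values would be
  undetectable by these rules by construction and would make recovery
  criteria meaningless.
- **φ = 0.995 at 1 Hz.** Physiological SpO2 drifts over minutes, not
  seconds. A fast AR(1) would make the 20-s median average away genuine
  variability and bias CT90 near the threshold by several points; with a
  ~200-s decorrelation time the binned series tracks the true curve and
  per-night truth is recoverable to 0.2 points (mean) and 2 points
  (CT90).
- **Strict inequalities.** "More than 30 % of the time below 90 %" makes
  both comparisons strict: SpO2 < 90 counts toward CT90, CT90 > 30
  desaturates. A night at exactly 30 % does not desaturate.
- **CT90 denominator is measured time.** Using elapsed time would let
  missing data masquerade as non-desaturated time.
- **Two-night flag as category discordance.** The flag compares the
  category from the first two nights with the weekly category. Reading it
  as "any occasional desaturator" would make it redundant with the
  category itself; the implemented reading isolates patients a short
  protocol would actually have misjudged.
- **Context mean before exclusion.** Step 2 compares block means against
  the segment's non-error mean computed *before* any exclusion, so the
  result does not depend on the order in which blocks are considered.
- **Bin-midpoint activity labels.** A 20-s bin can straddle two
  actigraphy minutes; the label at the bin midpoint is the
  maximum-overlap assignment for every possible alignment.
- **Exact reproducibility.** All randomness derives from one seeded
  generator; CSV writers fix line terminators and float formatting
  (`repr`, which round-trips doubles exactly), making simulate → run →
  report bit-reproducible and the cohort report a pure function of the
  feature table.
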