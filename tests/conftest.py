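from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oxiweek as ox
from oxiweek.pipeline import feature_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

T0 = np.datetime64("2017-01-05T00:00:00", "s")


def spo2_from_offsets(offsets, values, base=T0):
    """Build an Spo2Series from second offsets relative to ``base``."""
    offsets = np.asarray(offsets, dtype="int64")
    return ox.Spo2Series(base + offsets * np.timedelta64(1, "s"), np.asarray(values))


def minutes_act(start_minute, met, lying, sleep, base=T0):
    """Contiguous per-minute ActigraphySeries starting at ``start_minute``."""
    n = len(met)
    ts = base + (start_minute + np.arange(n, dtype="int64")) * np.timedelta64(60, "s")
    return ox.ActigraphySeries(ts, met, lying, sleep)


@pytest.fixture(scope="session")
def study_cohort():
    """The designed 5/5/10 cohort of week-long patient records."""
    return ox.simulate_cohort(5, 5, 10, seed=1)


@pytest.fixture(scope="session")
def study_cohort_analyzed(study_cohort):
    """(cohort, feature table) after running the full per-patient analysis."""
    rows = []
    for pw in study_cohort:
        r, _ = ox.analyze_patient(pw.patient_id, pw.spo2, pw.act)
        rows += r
    return study_cohort, feature_frame(rows)
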