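"""Cohort-level statistics: paired t test and Pearson correlation.

The statistics are computed directly from their defining sums; only the
p-values go through scipy's Student-t distribution.  Two-sided p-values are
always reported; significance is conventionally read at 0.05 but no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_difference: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    p: float


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired-sample t test on the differences x - y.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample SD; p from Student t
    with n - 1 degrees of freedom.  Zero-variance differences make t
    undefined and are refused.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired test requires two equal-length 1-d samples")
    n = len(x)
    if n < 2:
        raise StatsError("paired test requires at least two pairs")
    d = x - y
    mean_d = float(d.sum()) / n
    ss = float(((d - mean_d) ** 2).sum())
    if ss == 0.0:
        raise StatsError("zero-variance differences: t statistic undefined")
    sd = math.sqrt(ss / (n - 1))
    t = mean_d / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedTestResult(n=n, mean_difference=mean_d, t=t, df=n - 1, p=p)


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p via the t transform.

    r is computed from centred sums; p uses t = r * sqrt((n-2)/(1-r^2))
    with n - 2 degrees of freedom (p = 0 for |r| = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("correlation requires two equal-length 1-d samples")
    n = len(x)
    if n < 3:
        raise StatsError("correlation requires at least three pairs")
    xc = x - x.sum() / n
    yc = y - y.sum() / n
    sxx = float((xc * xc).sum())
    syy = float((yc * yc).sum())
    if sxx == 0.0 or syy == 0.0:
        raise StatsError("zero-variance input: correlation undefined")
    r = float((xc * yc).sum()) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(n=n, r=r, r_squared=r * r, p=p)
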