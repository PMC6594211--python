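"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops and the statistics
module, deliberately sharing no code path with the package (which is
vectorised over numpy/pandas), so that agreement between the two is
meaningful.
"""

from __future__ import annotations

import math
import statistics

SENTINEL = 500


def brute_force_clean(
    offsets: list[int],
    values: list[int],
    duration: int,
    small_max: int = 19,
    dev_min: int = 20,
    dev_max: int = 100,
    dev_threshold: float = 6.0,
    bin_seconds: int = 20,
    max_gap: int = 3,
) -> tuple[list[float | None], list[str], dict[str, int]]:
    """Reference cleaning: returns (bin values, per-sample fates, counts).

    ``offsets`` are sample times in seconds from the segment start (strictly
    increasing, within [0, duration)).  Fates are 'valid' / 'error' /
    'cleaned'.  Bin values are medians of valid samples per 20-s window
    (None when missing and not interpolated).
    """
    n = len(values)
    fate = ["error" if v == SENTINEL else "valid" for v in values]

    # maximal runs of non-error samples, by position in the sample sequence
    runs = []
    i = 0
    while i < n:
        if fate[i] == "error":
            i += 1
            continue
        j = i
        while j < n and fate[j] != "error":
            j += 1
        runs.append((i, j))
        i = j
    nonerror = [values[k] for k in range(n) if fate[k] != "error"]
    context = sum(nonerror) / len(nonerror) if nonerror else None

    for a, b in runs:
        bounded = a > 0 and b < n
        if not bounded:
            continue
        length = b - a
        if length <= small_max:
            for k in range(a, b):
                fate[k] = "cleaned"
        elif dev_min <= length <= dev_max:
            block_mean = sum(values[a:b]) / length
            if abs(block_mean - context) > dev_threshold:
                for k in range(a, b):
                    fate[k] = "cleaned"

    n_bins = math.ceil(duration / bin_seconds)
    bins: list[float | None] = []
    for i in range(n_bins):
        window = [
            values[k]
            for k in range(n)
            if i * bin_seconds <= offsets[k] < (i + 1) * bin_seconds and fate[k] == "valid"
        ]
        bins.append(statistics.median(window) if window else None)

    # interpolate missing runs of <= max_gap strictly between valid bins
    i = 0
    while i < n_bins:
        if bins[i] is not None:
            i += 1
            continue
        j = i
        while j < n_bins and bins[j] is None:
            j += 1
        if i > 0 and j < n_bins and (j - i) <= max_gap:
            left, right = bins[i - 1], bins[j]
            for k in range(i, j):
                bins[k] = left + (right - left) * (k - (i - 1)) / (j - (i - 1))
        i = j

    counts = {
        "valid": sum(1 for f in fate if f == "valid"),
        "error": sum(1 for f in fate if f == "error"),
        "cleaned": sum(1 for f in fate if f == "cleaned"),
    }
    return bins, fate, counts


def brute_force_activity_labels(
    sample_secs: list[int],
    minute_secs: list[int],
    met: list[float],
    sleep: list[int],
) -> list[str]:
    """Per-sample activity label by linear search over actigraphy minutes."""
    labels = []
    for s in sample_secs:
        label = "unaligned"
        for m, met_v, sleep_v in zip(minute_secs, met, sleep):
            if m <= s < m + 60:
                if sleep_v == 1:
                    label = "asleep"
                elif met_v <= 1.5:
                    label = "rest"
                elif met_v <= 3.0:
                    label = "lipa"
                else:
                    label = "mvpa"
                break
        labels.append(label)
    return labels


def brute_force_paired_t(x: list[float], y: list[float]) -> tuple[float, int]:
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    return mean / (sd / math.sqrt(n)), n - 1
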