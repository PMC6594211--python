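"""Pipeline configuration.

Every threshold of the analysis is held here with its default value so that a
run can be reproduced from the logged configuration alone.  Defaults are the
values used throughout the package's reference analysis: the 500 error
sentinel, the <20-sample and 20-100-sample block rules with a 6-percentage-
point deviation threshold, 20-s median down-sampling, interpolation of gaps of
at most 3 bins, a 90% SpO2 desaturation threshold and a 30% CT90 cut-off.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the four-step SpO2 cleaning algorithm.

    Attributes
    ----------
    small_block_max:
        Largest length (in 1-Hz samples) of a non-error run between error
        values that is unconditionally excluded (rule: "less than 20
        samples").
    dev_block_min, dev_block_max:
        Length window (inclusive) of runs between error values that are
        excluded conditionally on their mean deviating from the segment mean.
    dev_threshold:
        Deviation threshold, in SpO2 percentage points (absolute by default).
    dev_relative:
        If True, interpret ``dev_threshold`` as percent of the segment mean
        instead of absolute percentage points.
    bin_seconds:
        Width of the median down-sampling window.
    max_interp_gap_bins:
        Longest run of missing bins (strictly between valid bins) that is
        filled by linear interpolation.
    acf_threshold:
        Autocorrelation level defining the decorrelation lag (default 1/e).
    """

    small_block_max: int = 19
    dev_block_min: int = 20
    dev_block_max: int = 100
    dev_threshold: float = 6.0
    dev_relative: bool = False
    bin_seconds: int = 20
    max_interp_gap_bins: int = 3
    acf_threshold: float = 1.0 / math.e


@dataclass(frozen=True)
class SegmentationConfig:
    """Bed detection and period retention parameters.

    ``min_bed_minutes`` is the shortest lying run accepted as a bed interval
    (naps are shorter).  A night is retained when the SpO2 recording covers at
    least ``night_coverage_fraction`` of the bed interval ("full night"); a
    day is retained when at least ``min_day_seconds`` of SpO2 samples exist.
    """

    min_bed_minutes: int = 180
    night_coverage_fraction: float = 0.9
    min_day_seconds: int = 3600
    min_window_seconds: int = 3600  # afternoon/evening eligibility


@dataclass(frozen=True)
class FeatureConfig:
    spo2_threshold: float = 90.0   # CT90: time with SpO2 < this value
    ct90_threshold: float = 30.0   # desaturator: CT90 > this value
    rest_met_max: float = 1.5
    lipa_met_max: float = 3.0


@dataclass(frozen=True)
class PipelineConfig:
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        try:
            return cls(
                cleaning=CleaningConfig(**data.get("cleaning", {})),
                segmentation=SegmentationConfig(**data.get("segmentation", {})),
                features=FeatureConfig(**data.get("features", {})),
            )
        except TypeError as exc:  # unknown key
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
        try:
            if path.suffix in (".yaml", ".yml"):
                data = yaml.safe_load(text) or {}
            else:
                data = json.loads(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse configuration {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"configuration root must be a mapping: {path}")
        return cls.from_dict(data)


class ConfigError(ValueError):
    """Raised for unreadable or inconsistent configuration input."""
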