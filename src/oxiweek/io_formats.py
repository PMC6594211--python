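"""Readers and writers for the pipeline's CSV/JSON dialects.

Two input streams are defined:

* SpO2 stream, 1 Hz, header ``timestamp,spo2``: integer percent values in
  [0, 100], or the oximeter's error sentinel 500 for samples the device
  itself flagged invalid.
* Actigraphy stream, 1 sample/min, header ``timestamp,met,lying,sleep``:
  energy expenditure in MET plus binary lying-down and sleep indications.

Timestamps are ISO 8601 local wall-clock times at second resolution; no
timezone arithmetic is performed (clock windows such as 13:00-18:00 are
wall-clock by definition).  Within a series timestamps must be strictly
increasing; gaps are allowed (device off).  All intervals in the package are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ERROR_SENTINEL = 500

# per-sample status codes
RAW_VALID = 0
ERROR = 1
CLEANED_OUT = 2

STATUS_NAMES = {RAW_VALID: "raw_valid", ERROR: "error", CLEANED_OUT: "cleaned_out"}

SPO2_COLUMNS = ["timestamp", "spo2"]
ACT_COLUMNS = ["timestamp", "met", "lying", "sleep"]
FEATURE_COLUMNS = ["patient", "period_date", "period_kind", "feature", "value", "units"]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class FormatError(ValueError):
    """Raised when an input file violates the dialect contract."""


@dataclass
class Spo2Series:
    """Timestamped 1-Hz SpO2 samples with per-sample status.

    ``timestamps`` is a ``datetime64[s]`` array, ``values`` the integer
    percent readings (500 for device errors) and ``status`` one of
    ``RAW_VALID``/``ERROR``/``CLEANED_OUT``.  ``value == 500`` iff
    ``status == ERROR`` at load time; cleaning marks further samples
    ``CLEANED_OUT`` downstream.
    """

    timestamps: np.ndarray
    values: np.ndarray
    status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.status is None:
            self.status = np.where(self.values == ERROR_SENTINEL, ERROR, RAW_VALID).astype(np.int8)
        else:
            self.status = np.asarray(self.status, dtype=np.int8)
        if len(self.timestamps) != len(self.values) or len(self.values) != len(self.status):
            raise FormatError("timestamps, values and status must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps.astype("int64")) > 0):
            raise FormatError("SpO2 timestamps must be strictly increasing")
        bad = (self.values != ERROR_SENTINEL) & ((self.values < 0) | (self.values > 100))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"SpO2 value out of range at sample {idx} "
                f"({self.timestamps[idx]}): {int(self.values[idx])}"
            )
        mismatch = (self.values == ERROR_SENTINEL) != (self.status == ERROR)
        if mismatch.any():
            idx = int(np.flatnonzero(mismatch)[0])
            raise FormatError(f"error sentinel/status mismatch at sample {idx}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seconds(self) -> np.ndarray:
        """Timestamps as int64 seconds since the epoch."""
        return self.timestamps.astype("int64")

    def slice(self, mask_or_index: np.ndarray) -> "Spo2Series":
        return Spo2Series(
            self.timestamps[mask_or_index],
            self.values[mask_or_index],
            self.status[mask_or_index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "spo2": self.values})


@dataclass
class ActigraphySeries:
    """Per-minute actigraphy: MET energy expenditure plus lying/sleep flags.

    Minutes are aligned to whole-minute boundaries; ``sleep == 1`` implies
    ``lying == 1`` (a violation is rejected at load time).
    """

    timestamps: np.ndarray
    met: np.ndarray
    lying: np.ndarray
    sleep: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.met = np.asarray(self.met, dtype=np.float64)
        self.lying = np.asarray(self.lying, dtype=np.int8)
        self.sleep = np.asarray(self.sleep, dtype=np.int8)
        n = len(self.timestamps)
        if not (len(self.met) == len(self.lying) == len(self.sleep) == n):
            raise FormatError("actigraphy columns must have equal length")
        secs = self.timestamps.astype("int64")
        if n > 1 and not np.all(np.diff(secs) > 0):
            raise FormatError("actigraphy timestamps must be strictly increasing")
        if n and (secs % 60 != 0).any():
            idx = int(np.flatnonzero(secs % 60 != 0)[0])
            raise FormatError(f"actigraphy timestamp not minute-aligned at row {idx}")
        if (self.met < 0).any():
            idx = int(np.flatnonzero(self.met < 0)[0])
            raise FormatError(f"negative MET at row {idx}")
        for name, col in (("lying", self.lying), ("sleep", self.sleep)):
            if not np.isin(col, (0, 1)).all():
                raise FormatError(f"{name} must be binary")
        bad = (self.sleep == 1) & (self.lying == 0)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"sleep=1 requires lying=1, violated at row {idx} ({self.timestamps[idx]})"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def seconds(self) -> np.ndarray:
        return self.timestamps.astype("int64")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "met": self.met,
                "lying": self.lying,
                "sleep": self.sleep,
            }
        )


def _parse_timestamps(raw: pd.Series, path: Path) -> np.ndarray:
    try:
        ts = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp: {exc}") from exc
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2  # + header + 1-based
        raise FormatError(f"{path}: malformed timestamp at line {line}")
    return ts.to_numpy().astype("datetime64[s]")


def _read_table(path: str | Path, columns: list[str]) -> tuple[pd.DataFrame, Path]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: header must be {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df, path


def _numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    if values.isna().any():
        line = int(np.flatnonzero(values.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: malformed {col} value at line {line}")
    return values


def read_spo2_csv(path: str | Path) -> Spo2Series:
    """Read a 1-Hz SpO2 CSV (``timestamp,spo2``).

    The sentinel 500 is mapped to error status; any other value outside
    [0, 100] is rejected with the offending line number.
    """
    df, path = _read_table(path, SPO2_COLUMNS)
    if df.empty:
        return Spo2Series(np.array([], dtype="datetime64[s]"), np.array([], dtype=np.int16))
    ts = _parse_timestamps(df["timestamp"], path)
    values = _numeric(df, "spo2", path)
    fractional = values != values.astype(int)
    if fractional.any():
        line = int(np.flatnonzero(fractional.to_numpy())[0]) + 2
        raise FormatError(f"{path}: non-integer SpO2 value at line {line}")
    vals = values.astype(int).to_numpy()
    bad = (vals != ERROR_SENTINEL) & ((vals < 0) | (vals > 100))
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise FormatError(
            f"{path}: SpO2 value out of range at line {line}: {int(vals[np.flatnonzero(bad)[0]])}"
        )
    try:
        return Spo2Series(ts, vals.astype(np.int16))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_actigraphy_csv(path: str | Path) -> ActigraphySeries:
    """Read a 1/min actigraphy CSV (``timestamp,met,lying,sleep``)."""
    df, path = _read_table(path, ACT_COLUMNS)
    if df.empty:
        return ActigraphySeries(
            np.array([], dtype="datetime64[s]"),
            np.array([], dtype=float),
            np.array([], dtype=np.int8),
            np.array([], dtype=np.int8),
        )
    ts = _parse_timestamps(df["timestamp"], path)
    met = _numeric(df, "met", path).to_numpy()
    lying = _numeric(df, "lying", path).to_numpy()
    sleep = _numeric(df, "sleep", path).to_numpy()
    try:
        return ActigraphySeries(ts, met, lying, sleep)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _format_timestamps(ts: np.ndarray) -> pd.Series:
    return pd.Series(ts).dt.strftime(_TS_FORMAT)


def write_spo2_csv(series: Spo2Series, path: str | Path) -> None:
    df = pd.DataFrame(
        {"timestamp": _format_timestamps(series.timestamps), "spo2": series.values}
    )
    df.to_csv(path, index=False, lineterminator="\n")


def write_actigraphy_csv(series: ActigraphySeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": _format_timestamps(series.timestamps),
            "met": [f"{m:.3f}" for m in series.met],
            "lying": series.lying,
            "sleep": series.sleep,
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format feature table (one row per patient/period/feature)."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    out = table[FEATURE_COLUMNS].copy()
    # repr round-trips doubles exactly; pandas' default float formatting does not
    out["value"] = [repr(float(v)) for v in out["value"]]
    out.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df, path = _read_table(path, FEATURE_COLUMNS)
    try:
        # Python's float() round-trips repr() output exactly; pandas' numeric
        # parser does not guarantee the last ulp
        df["value"] = np.array([float(s) for s in df["value"]], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed value column: {exc}") from exc
    return df


def convert_vendor_csv(
    path: str | Path,
    column_map: dict[str, str],
    kind: str = "spo2",
) -> pd.DataFrame:
    """Map a vendor CSV export onto the package dialect (converter stub).

    Proprietary oximeter/armband exports are not parsed natively; this helper
    renames the caller-identified vendor columns (``column_map`` maps dialect
    name -> vendor name) and returns a frame with the dialect's column order,
    ready to be written with the package writers.
    """
    wanted = SPO2_COLUMNS if kind == "spo2" else ACT_COLUMNS
    df = pd.read_csv(path)
    missing = [v for v in column_map.values() if v not in df.columns]
    if missing:
        raise FormatError(f"vendor file lacks mapped columns: {missing}")
    renamed = df.rename(columns={v: k for k, v in column_map.items()})
    absent = [c for c in wanted if c not in renamed.columns]
    if absent:
        raise FormatError(f"column map does not cover dialect columns: {absent}")
    return renamed[wanted]
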