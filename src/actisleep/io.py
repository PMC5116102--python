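"""Reading, validating and aggregating raw actigraphy count recordings.

Wrist-worn accelerometers export activity *counts* — non-negative integers
summarizing movement magnitude within a fixed epoch (here ≤ 60 s). Downstream
sleep scoring operates on the vertical axis at minute resolution, so this
module validates raw triaxial epoch CSVs, projects out the vertical axis and
aggregates to one count per minute.

All series are 0-based indexed; intervals are half-open ``[start, end)`` in
minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecording",
    "MinuteSeries",
    "ActigraphyParseError",
    "ActigraphyValidationError",
    "read_epoch_csv",
    "extract_vertical_axis",
    "aggregate_to_minutes",
    "read_minute_csv",
    "write_minute_csv",
]


class ActigraphyParseError(ValueError):
    """A row of an epoch CSV could not be parsed."""


class ActigraphyValidationError(ValueError):
    """A recording violates a structural invariant (gaps, negative counts...)."""


@dataclass(frozen=True)
class ActivityRecording:
    """One subject's contiguous triaxial activity-count time series.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    start_time : pandas.Timestamp
        Timestamp of the first epoch.
    epoch_seconds : int
        Epoch length in seconds; must be positive and divide 60.
    axis_counts : numpy.ndarray of shape (n_epochs, 3)
        Non-negative integer counts per epoch for (vertical, axis2, axis3).
    """

    subject_id: str
    start_time: pd.Timestamp
    epoch_seconds: int
    axis_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.axis_counts)
        if counts.ndim != 2 or counts.shape[1] != 3:
            raise ActigraphyValidationError(
                f"axis_counts must have shape (n, 3), got {counts.shape}"
            )
        if counts.shape[0] < 1:
            raise ActigraphyValidationError("recording must contain at least one epoch")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ActigraphyValidationError("activity counts must be integers")
        if (counts < 0).any():
            raise ActigraphyValidationError("activity counts must be non-negative")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds != 0:
            raise ActigraphyValidationError(
                f"epoch_seconds must be a positive divisor of 60, got {self.epoch_seconds}"
            )
        object.__setattr__(self, "axis_counts", counts)

    def __len__(self) -> int:
        return self.axis_counts.shape[0]


@dataclass(frozen=True)
class MinuteSeries:
    """Vertical-axis activity counts at one value per minute, contiguous."""

    subject_id: str
    start_time: pd.Timestamp
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.shape[0] < 1:
            raise ActigraphyValidationError("counts must be a non-empty 1-d sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ActigraphyValidationError("minute counts must be integers")
        if (counts < 0).any():
            raise ActigraphyValidationError("minute counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[0]


def _infer_epoch_seconds(timestamps: pd.Series, path: Path) -> int:
    deltas = timestamps.diff().dropna().dt.total_seconds()
    if deltas.empty:
        return 60
    step = deltas.iloc[0]
    if step <= 0 or step != int(step):
        raise ActigraphyValidationError(
            f"{path}: non-positive or sub-second sampling interval ({step} s)"
        )
    if not (deltas == step).all():
        bad = int(np.argmax((deltas != step).to_numpy())) + 1
        raise ActigraphyValidationError(
            f"{path}: irregular or gapped timestamps at data row {bad + 1} "
            f"(expected a constant {int(step)} s step)"
        )
    step = int(step)
    if 60 % step != 0:
        raise ActigraphyValidationError(
            f"{path}: sampling interval {step} s does not divide 60 s"
        )
    return step


def read_epoch_csv(path: str | Path) -> ActivityRecording:
    """Read a plain epoch CSV into a validated :class:`ActivityRecording`.

    Expected header ``subject_id,timestamp,axis1,axis2,axis3`` with ISO 8601
    timestamps, one row per epoch, a constant sampling interval dividing 60 s
    and no gaps. Vendor multi-line metadata headers are not parsed; export to
    plain CSV first. A single-axis file (``subject_id,timestamp,counts``) is
    accepted too — axis2/axis3 are then taken as zero.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ActigraphyParseError(f"{path}: {exc}") from exc

    cols = list(df.columns)
    if {"subject_id", "timestamp", "axis1", "axis2", "axis3"}.issubset(cols):
        axis_cols = ["axis1", "axis2", "axis3"]
    elif {"subject_id", "timestamp", "counts"}.issubset(cols):
        axis_cols = ["counts"]
    else:
        raise ActigraphyParseError(
            f"{path}: expected header subject_id,timestamp,axis1,axis2,axis3 "
            f"(or subject_id,timestamp,counts), got {cols}"
        )
    if df.empty:
        raise ActigraphyValidationError(f"{path}: no data rows")

    try:
        timestamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ActigraphyParseError(f"{path}: unparseable timestamp ({exc})") from exc

    counts = np.empty((len(df), 3), dtype=np.int64)
    for j, col in enumerate(axis_cols):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise ActigraphyParseError(
                f"{path}: malformed count in column {col!r} at data row {row + 1}"
            )
        if (values != values.astype(np.int64)).any():
            raise ActigraphyParseError(f"{path}: non-integer counts in column {col!r}")
        counts[:, j] = values.astype(np.int64)
    if len(axis_cols) == 1:
        counts[:, 1:] = 0

    subjects = df["subject_id"].astype(str).unique()
    if len(subjects) != 1:
        raise ActigraphyValidationError(
            f"{path}: expected a single subject per file, found {list(subjects)}"
        )

    epoch_seconds = _infer_epoch_seconds(timestamps, path)
    return ActivityRecording(
        subject_id=subjects[0],
        start_time=timestamps.iloc[0],
        epoch_seconds=epoch_seconds,
        axis_counts=counts,
    )


def extract_vertical_axis(rec: ActivityRecording) -> np.ndarray:
    """Return the per-epoch vertical-axis (axis1) counts.

    On the wrist the vertical axis is the most indicative of physical
    activity; all downstream scoring uses it exclusively.
    """
    return rec.axis_counts[:, 0].copy()


def aggregate_to_minutes(rec: ActivityRecording) -> MinuteSeries:
    """Sum vertical-axis epoch counts into minute-by-minute epochs.

    Each minute's count is the sum of the counts of its constituent epochs.
    A trailing partial minute is dropped with a logged warning.
    """
    vertical = extract_vertical_axis(rec)
    per_minute = 60 // rec.epoch_seconds
    n_minutes = len(vertical) // per_minute
    if n_minutes < 1:
        raise ActigraphyValidationError(
            "recording shorter than one minute after aggregation"
        )
    if len(vertical) % per_minute:
        logger.warning(
            "subject %s: dropping trailing partial minute (%d epoch(s))",
            rec.subject_id,
            len(vertical) % per_minute,
        )
    minutes = vertical[: n_minutes * per_minute].reshape(n_minutes, per_minute).sum(axis=1)
    return MinuteSeries(rec.subject_id, rec.start_time, minutes)


def read_minute_csv(path: str | Path) -> MinuteSeries:
    """Read a single-axis minute-resolution CSV into a :class:`MinuteSeries`."""
    rec = read_epoch_csv(path)
    if rec.epoch_seconds != 60:
        raise ActigraphyValidationError(
            f"{path}: expected minute resolution, got {rec.epoch_seconds} s epochs"
        )
    return MinuteSeries(rec.subject_id, rec.start_time, rec.axis_counts[:, 0])


def write_minute_csv(series: MinuteSeries, path: str | Path) -> None:
    """Write a MinuteSeries as a ``subject_id,timestamp,counts`` CSV."""
    timestamps = pd.date_range(series.start_time, periods=len(series), freq="min")
    pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "timestamp": timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "counts": series.counts,
        }
    ).to_csv(path, index=False)
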