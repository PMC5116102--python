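"""Build model-ready labeled instances from scored recordings.

Each instance pairs the activity of one continuous awake period,
``X = (x_1, ..., x_T)``, with the good/poor quality label of the immediately
following sleep period — awake time forms the prediction input, sleep time
the ground truth. A week of wear typically yields several instances per
subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MinuteSeries
from .scoring import GOOD, SleepPeriod

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledInstance",
    "DataSplit",
    "segment_awake_pairs",
    "stratified_split",
    "pad_or_truncate",
    "time_batch",
    "instances_to_frame",
    "instances_from_frame",
]


@dataclass(frozen=True)
class LabeledInstance:
    """An awake-time activity vector labeled by the following sleep period."""

    subject_id: str
    awake_activity: np.ndarray = field(repr=False)
    label: str = GOOD

    def __post_init__(self) -> None:
        x = np.asarray(self.awake_activity)
        if x.ndim != 1 or len(x) < 1:
            raise ValueError("awake_activity must be a non-empty 1-d vector")
        object.__setattr__(self, "awake_activity", x)

    @property
    def T(self) -> int:
        return len(self.awake_activity)

    @property
    def y(self) -> int:
        """Binary encoding; good sleep is the positive class (1)."""
        return 1 if self.label == GOOD else 0


@dataclass(frozen=True)
class DataSplit:
    """Index sets of a stratified train/validation/test partition."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float]
    seed: int


def segment_awake_pairs(
    periods: list[SleepPeriod],
    series: MinuteSeries,
    min_awake_min: int = 60,
    exclude_nonwear: bool = False,
) -> list[LabeledInstance]:
    """Pair each sleep period's label with the preceding awake activity.

    The awake window runs from the previous period's awakening (or the series
    start) up to this period's bedtime, half-open. Instances shorter than
    ``min_awake_min`` are dropped with a log entry. With
    ``exclude_nonwear=True`` (the practical mode) periods flagged as nonwear
    emit no instance; the next instance's awake window still starts at their
    awakening, so no awake window ever overlaps a sleep period.
    """
    counts = series.counts
    instances: list[LabeledInstance] = []
    prev_awakening = 0
    for p in periods:
        start, end = prev_awakening, p.bedtime_idx
        prev_awakening = p.awakening_idx
        if exclude_nonwear and p.nonwear_flag:
            continue
        if end - start < min_awake_min:
            logger.info(
                "subject %s: dropping %d-min awake window (< %d min)",
                series.subject_id,
                max(end - start, 0),
                min_awake_min,
            )
            continue
        instances.append(
            LabeledInstance(series.subject_id, counts[start:end].copy(), p.label)
        )
    return instances


def stratified_split(
    instances: list[LabeledInstance],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    min_per_class: int = 10,
) -> DataSplit:
    """Randomly partition instances into train/validation/test, stratified by class.

    Each instance is assigned randomly while maintaining an even class
    distribution: within each class the shuffled indices are cut at the
    ratio boundaries, so per-class counts match the ratios to rounding.
    The same seed always yields the same split. ``instances`` may also be a
    plain sequence of labels (good/poor strings or 0/1).
    """
    if len(ratios) != 3 or not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must be three fractions summing to 1")
    if len(instances) and hasattr(instances[0], "y"):
        y = np.array([inst.y for inst in instances])
    else:
        arr = np.asarray(instances)
        y = (arr == GOOD).astype(int) if arr.dtype.kind in "UO" else arr.astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both good and poor classes must be present")
    if counts.min() < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} instances per class, got {counts.min()}"
        )
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = round(ratios[0] * n)
        n_val = round(ratios[1] * n)
        cuts = [0, n_train, n_train + n_val, n]
        for k in range(3):
            parts[k].extend(idx[cuts[k] : cuts[k + 1]])
    train, val, test = (np.sort(np.array(p, dtype=int)) for p in parts)
    return DataSplit(train, val, test, tuple(ratios), seed)


def pad_or_truncate(
    instances: list[LabeledInstance], fixed_length_min: int = 960
) -> tuple[np.ndarray, np.ndarray]:
    """Left-pad with zeros or keep the most recent ``fixed_length_min`` minutes.

    Fixed-input models need a rectangular matrix; the pre-sleep tail of the
    awake window is the retained part when truncating. Returns ``(X, mask)``
    where ``mask`` marks real (unpadded) minutes.
    """
    if fixed_length_min <= 0:
        raise ValueError("fixed_length_min must be positive")
    L = fixed_length_min
    X = np.zeros((len(instances), L))
    mask = np.zeros((len(instances), L), dtype=bool)
    for i, inst in enumerate(instances):
        x = inst.awake_activity[-L:]
        X[i, L - len(x) :] = x
        mask[i, L - len(x) :] = True
    return X, mask


def time_batch(x: np.ndarray, window_min: int = 15) -> np.ndarray:
    """Merge consecutive minutes into non-overlapping window vectors.

    Recurrent models over minute-resolution awake windows face very long,
    low-dimensional sequences; time-batching turns every ``window_min``
    consecutive minutes into one input vector per step. The final partial
    window is zero-padded. Output shape is ``(ceil(T / window_min), window_min)``.
    """
    if window_min < 1:
        raise ValueError("window_min must be >= 1")
    x = np.asarray(x)
    n_steps = -(-len(x) // window_min)
    out = np.zeros((n_steps, window_min), dtype=x.dtype)
    out.ravel()[: len(x)] = x
    return out


def instances_to_frame(instances: list[LabeledInstance], fixed_length_min: int = 960):
    """Serialize instances as a wide table: id, subject, label, x_1..x_L."""
    X, _ = pad_or_truncate(instances, fixed_length_min)
    df = pd.DataFrame(X.astype(int), columns=[f"x_{j + 1}" for j in range(X.shape[1])])
    df.insert(0, "instance_id", np.arange(len(instances)))
    df.insert(1, "subject_id", [inst.subject_id for inst in instances])
    df.insert(2, "label", [inst.label for inst in instances])
    return df


def instances_from_frame(df: pd.DataFrame) -> list[LabeledInstance]:
    """Inverse of :func:`instances_to_frame` (padding retained)."""
    x_cols = [c for c in df.columns if c.startswith("x_")]
    return [
        LabeledInstance(str(row["subject_id"]), row[x_cols].to_numpy(int), row["label"])
        for _, row in df.iterrows()
    ]
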