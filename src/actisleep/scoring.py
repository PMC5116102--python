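"""Rule-based sleep scoring of minute-epoch actigraphy.

The scorer segments a minute-resolution count series into sleep periods and
derives the standard sleep-quality quantities from each:

* **candidate rows** — minutes with (near) no movement, pending confirmation;
* **sleep onset** — first minute of 15 continuous candidate minutes;
* **sleep awakening** — last minute of the last ≥15-minute candidate run
  before 30 continuous minutes of movement close the period;
* **bedtime / latency** — bedtime is inferred as the start of the sedentary
  run immediately preceding and adjacent to onset; its length is the latency;
* **WASO** — wake after sleep onset, the summed length of within-period wake
  bouts each lasting strictly longer than 5 minutes;
* **sleep efficiency** — SE = (duration − WASO) / (latency + duration),
  i.e. total sleep time over total time in bed; SE ≥ 85% labels the period
  *good* quality, otherwise *poor*.

Device nonwear shows up as runs of exact-zero counts (natural sleep retains
micro-movements). Two modes are provided: ``paper_naive`` scores nonwear
blocks as sleep (they trivially achieve SE = 1), ``exclude`` flags periods
overlapping long zero-runs so downstream dataset construction can drop them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io import MinuteSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringConfig",
    "SleepPeriod",
    "classify_candidate_rows",
    "detect_nonwear",
    "detect_sleep_periods",
    "infer_latency",
    "compute_waso",
    "compute_sleep_efficiency",
    "label_quality",
    "score_recording",
    "periods_to_frame",
]

GOOD = "good"
POOR = "poor"


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and run lengths governing sleep scoring.

    Parameters
    ----------
    movement_threshold : int
        Counts/min at or below which a minute is a candidate row (potentially
        asleep). Default 10: sleep retains micro-movements of a few counts,
        while sedentary wakefulness (reading, screen use) produces tens of
        counts — the two concepts need distinct thresholds for latency to be
        observable at all.
    sedentary_threshold : int
        Counts/min at or below which a pre-bed minute counts as sedentary for
        bedtime/latency inference. Default 100.
    onset_run_min : int
        Continuous candidate minutes required to open a sleep period (15).
    awakening_run_min : int
        Minimum candidate-run length whose last minute can be the awakening
        time (15).
    close_movement_min : int
        Continuous movement minutes that close an open sleep period (30);
        shorter movement runs are wake bouts inside the period.
    waso_bout_exclusive_min : int
        Wake bouts must be strictly longer than this to count toward WASO (5).
    efficiency_good_threshold : float
        SE at or above which a period is labeled good quality (0.85).
    nonwear_mode : str
        ``paper_naive`` (nonwear scored as sleep) or ``exclude``.
    nonwear_zero_run_min : int
        Minimum run of exact-zero minutes flagged as nonwear (90).
    """

    movement_threshold: int = 10
    sedentary_threshold: int = 100
    onset_run_min: int = 15
    awakening_run_min: int = 15
    close_movement_min: int = 30
    waso_bout_exclusive_min: int = 5
    efficiency_good_threshold: float = 0.85
    nonwear_mode: str = "paper_naive"
    nonwear_zero_run_min: int = 90

    def __post_init__(self) -> None:
        for name in (
            "sedentary_threshold",
            "onset_run_min",
            "awakening_run_min",
            "close_movement_min",
            "waso_bout_exclusive_min",
            "nonwear_zero_run_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.movement_threshold < 0:
            raise ValueError("movement_threshold must be non-negative")
        if not 0.0 < self.efficiency_good_threshold < 1.0:
            raise ValueError("efficiency_good_threshold must be in (0, 1)")
        if self.nonwear_mode not in ("paper_naive", "exclude"):
            raise ValueError(f"unknown nonwear_mode {self.nonwear_mode!r}")


@dataclass(frozen=True)
class SleepPeriod:
    """One scored sleep interval; minute indices are half-open ``[onset, awakening)``."""

    onset_idx: int
    awakening_idx: int
    bedtime_idx: int
    latency_min: int
    duration_min: int
    waso_min: int
    total_sleep_time_min: int
    time_in_bed_min: int
    efficiency: float
    label: str
    nonwear_flag: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.bedtime_idx <= self.onset_idx < self.awakening_idx:
            raise ValueError("requires bedtime_idx <= onset_idx < awakening_idx")
        if self.latency_min != self.onset_idx - self.bedtime_idx:
            raise ValueError("latency_min must equal onset_idx - bedtime_idx")
        if self.duration_min != self.awakening_idx - self.onset_idx:
            raise ValueError("duration_min must equal awakening_idx - onset_idx")
        if self.total_sleep_time_min != self.duration_min - self.waso_min:
            raise ValueError("TST must equal duration - WASO")
        if self.total_sleep_time_min < 0:
            raise ValueError("TST must be non-negative")
        if self.time_in_bed_min != self.latency_min + self.duration_min:
            raise ValueError("TIB must equal latency + duration")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


def _as_counts(series: MinuteSeries | Sequence[int] | np.ndarray) -> np.ndarray:
    if isinstance(series, MinuteSeries):
        return series.counts
    return np.asarray(series)


def _runs(values: np.ndarray) -> Iterator[tuple[bool, int, int]]:
    """Yield maximal runs of a boolean array as (value, start, end) half-open."""
    n = len(values)
    start = 0
    while start < n:
        end = start + 1
        while end < n and values[end] == values[start]:
            end += 1
        yield bool(values[start]), start, end
        start = end


def classify_candidate_rows(
    series: MinuteSeries | np.ndarray, cfg: ScoringConfig | None = None
) -> np.ndarray:
    """Mark each minute as a candidate row (movement ≤ threshold)."""
    cfg = cfg or ScoringConfig()
    return _as_counts(series) <= cfg.movement_threshold


def detect_nonwear(
    series: MinuteSeries | np.ndarray, cfg: ScoringConfig | None = None
) -> list[tuple[int, int]]:
    """Find maximal runs of exact-zero counts of length ≥ ``nonwear_zero_run_min``.

    Continuous total absence of movement indicates device removal — even
    sleeping wearers register micro-movements. In ``paper_naive`` mode the
    intervals are reported but do not alter scoring.
    """
    cfg = cfg or ScoringConfig()
    counts = _as_counts(series)
    return [
        (start, end)
        for is_zero, start, end in _runs(counts == 0)
        if is_zero and end - start >= cfg.nonwear_zero_run_min
    ]


def detect_sleep_periods(
    series: MinuteSeries | np.ndarray, cfg: ScoringConfig | None = None
) -> list[tuple[int, int, np.ndarray]]:
    """Segment the series into sleep periods via the onset/awakening state machine.

    Returns a list of ``(onset_idx, awakening_idx, asleep)`` triples where
    ``asleep`` is the per-minute sleep(=True)/wake(=False) classification over
    ``[onset_idx, awakening_idx)``. Periods are disjoint and ordered.

    The machine scans maximal candidate/movement runs. While awake, a
    candidate run of length ≥ ``onset_run_min`` opens a period at its first
    minute. While asleep, movement runs shorter than ``close_movement_min``
    are wake bouts inside the period; a movement run of at least that length
    closes the period at the end of the last candidate run of length ≥
    ``awakening_run_min``. The end of the series closes an open period at the
    last candidate minute (logged as truncated).
    """
    cfg = cfg or ScoringConfig()
    counts = _as_counts(series)
    candidate = counts <= cfg.movement_threshold
    periods: list[tuple[int, int, np.ndarray]] = []
    onset = -1
    awakening_end = -1  # exclusive end of last qualifying candidate run
    last_candidate_end = -1

    def close(end: int) -> None:
        periods.append((onset, end, candidate[onset:end].copy()))

    asleep = False
    for is_candidate, start, end in _runs(candidate):
        if not asleep:
            if is_candidate and end - start >= cfg.onset_run_min:
                asleep = True
                onset = start
                awakening_end = end
                last_candidate_end = end
        else:
            if is_candidate:
                last_candidate_end = end
                if end - start >= cfg.awakening_run_min:
                    awakening_end = end
            elif end - start >= cfg.close_movement_min:
                close(awakening_end)
                asleep = False
    if asleep:
        close(last_candidate_end)
        logger.debug("open sleep period truncated at end of series")
    return periods


def infer_latency(
    series: MinuteSeries | np.ndarray,
    onset_idx: int,
    cfg: ScoringConfig | None = None,
    previous_awakening_idx: int = 0,
) -> tuple[int, int]:
    """Infer bedtime and latency for a sleep period starting at ``onset_idx``.

    Without self-reported bedtimes, bedtime is the beginning of the sedentary
    run (counts ≤ ``sedentary_threshold``) immediately preceding and adjacent
    to sleep onset, never extending past the previous period's awakening.
    Latency is the run's length in minutes (0 when the minute before onset is
    above the sedentary threshold).
    """
    cfg = cfg or ScoringConfig()
    counts = _as_counts(series)
    bedtime = onset_idx
    floor = max(previous_awakening_idx, 0)
    while bedtime > floor and counts[bedtime - 1] <= cfg.sedentary_threshold:
        bedtime -= 1
    return bedtime, onset_idx - bedtime


def compute_waso(
    asleep: Sequence[bool] | np.ndarray, cfg: ScoringConfig | None = None
) -> int:
    """Sum the lengths of wake bouts strictly longer than 5 minutes.

    ``asleep`` is the per-minute classification over one sleep period
    (True = asleep). Bouts of 5 minutes or shorter count as sleep by
    definition.
    """
    cfg = cfg or ScoringConfig()
    asleep = np.asarray(asleep, dtype=bool)
    return sum(
        end - start
        for is_sleep, start, end in _runs(asleep)
        if not is_sleep and end - start > cfg.waso_bout_exclusive_min
    )


def compute_sleep_efficiency(
    duration_min: int, waso_min: int, latency_min: int
) -> float:
    """SE = (duration − WASO) / (latency + duration) = TST / TIB, in [0, 1]."""
    if not duration_min >= waso_min >= 0:
        raise ValueError("requires duration >= WASO >= 0")
    if latency_min < 0:
        raise ValueError("latency must be non-negative")
    tib = latency_min + duration_min
    if tib <= 0:
        raise ValueError("time in bed must be positive")
    return (duration_min - waso_min) / tib


def label_quality(efficiency: float, cfg: ScoringConfig | None = None) -> str:
    """Label a sleep period good iff SE ≥ the 85% threshold (inclusive)."""
    cfg = cfg or ScoringConfig()
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    return GOOD if efficiency >= cfg.efficiency_good_threshold else POOR


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def score_recording(
    series: MinuteSeries | np.ndarray, cfg: ScoringConfig | None = None
) -> list[SleepPeriod]:
    """Score every sleep period in a recording.

    Composes candidate classification, the state machine, bedtime/latency
    inference, WASO, sleep efficiency and quality labeling. Nonwear zero-runs
    are always detected and flagged on overlapping periods; in
    ``paper_naive`` mode they are nevertheless scored as sleep (achieving
    SE = 1 for a pure zero-block), matching the naive treatment, while in
    ``exclude`` mode flagged periods are meant to be dropped downstream.
    """
    cfg = cfg or ScoringConfig()
    counts = _as_counts(series)
    nonwear = detect_nonwear(counts, cfg)
    raw = detect_sleep_periods(counts, cfg)

    scored: list[SleepPeriod] = []
    prev_awakening = 0
    for i, (onset, awakening, asleep) in enumerate(raw):
        bedtime, latency = infer_latency(counts, onset, cfg, prev_awakening)
        duration = awakening - onset
        waso = compute_waso(asleep, cfg)
        efficiency = compute_sleep_efficiency(duration, waso, latency)
        # last period is truncated if no closing movement run follows it
        is_truncated = i == len(raw) - 1 and not any(
            not c and e - s >= cfg.close_movement_min
            for c, s, e in _runs(counts[awakening:] <= cfg.movement_threshold)
        )
        scored.append(
            SleepPeriod(
                onset_idx=onset,
                awakening_idx=awakening,
                bedtime_idx=bedtime,
                latency_min=latency,
                duration_min=duration,
                waso_min=waso,
                total_sleep_time_min=duration - waso,
                time_in_bed_min=latency + duration,
                efficiency=efficiency,
                label=label_quality(efficiency, cfg),
                nonwear_flag=any(_overlaps((onset, awakening), nw) for nw in nonwear),
                truncated=is_truncated,
            )
        )
        prev_awakening = awakening
    return scored


def periods_to_frame(periods, series: MinuteSeries, cfg: ScoringConfig | None = None):
    """Serialize scored periods to the sleep-periods table (one row each)."""
    import pandas as pd

    cfg = cfg or ScoringConfig()
    rows = []
    t0 = series.start_time
    for p in periods:
        rows.append(
            {
                "subject_id": series.subject_id,
                "bedtime": (t0 + pd.Timedelta(minutes=p.bedtime_idx)).isoformat(),
                "onset": (t0 + pd.Timedelta(minutes=p.onset_idx)).isoformat(),
                "awakening": (t0 + pd.Timedelta(minutes=p.awakening_idx)).isoformat(),
                "latency_min": p.latency_min,
                "duration_min": p.duration_min,
                "waso_min": p.waso_min,
                "tst_min": p.total_sleep_time_min,
                "tib_min": p.time_in_bed_min,
                "efficiency": round(p.efficiency, 4),
                "label": p.label,
                "nonwear_flag": p.nonwear_flag,
                "nonwear_mode": cfg.nonwear_mode,
            }
        )
    return pd.DataFrame(rows)
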