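"""Synthetic actigraphy cohorts with known sleep ground truth.

Real wrist-actigraphy cohorts of the kind the scoring pipeline targets are
rarely public, so this generator emulates multi-day minute-epoch recordings
with every feature the scorer keys on, plus a plantable daytime→sleep-quality
signal for the prediction models:

* active daytime counts from a zero-inflated right-skewed (gamma–Poisson)
  count process, interleaved with idle (sedentary-range) minutes;
* a pre-bed sedentary run whose length is the planted latency;
* a sleep block of 360–540 min of near-zero counts with sparse
  micro-movements, and planted wake bouts sized so the realized sleep
  efficiency lands in the class's target range (good on/above 85%, poor
  below);
* occasional short (≤5 min) wake bouts that by definition do not count
  toward WASO;
* optional exact-zero nonwear blocks during the day;
* a ``coupling_strength`` knob that shifts three interpretable daytime
  channels with the upcoming night's class — total activity volume,
  fragmentation (idle-minute rate) and evening-hour activity — so
  feature-free sequence models can plausibly detect the class. Coupling 0
  makes daytime activity distributions identical across classes.

Every planted quantity is recorded per night, making the scorer
oracle-testable: in the noise-free setting (micro-movement rate 0) onset,
awakening, latency and WASO are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MinuteSeries
from .scoring import GOOD, POOR

__all__ = [
    "SimConfig",
    "NightTruth",
    "GroundTruth",
    "GenerationError",
    "generate_cohort",
    "class_balance",
]

MINUTES_PER_DAY = 1440


class GenerationError(ValueError):
    """The configured sleep-efficiency target cannot be realized."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator parameters (defaults emulate a week-long teen cohort)."""

    n_subjects: int = 92
    days_per_subject: int = 7
    seed: int = 0
    start_time: str = "2026-01-05T12:00:00"  # noon start keeps each night within one day
    # daytime activity
    wake_activity_mean: float = 600.0
    wake_activity_dispersion: float = 1.5
    wake_idle_prob: float = 0.25
    # pre-bed behavior
    sedentary_run_min_range: tuple[int, int] = (5, 40)
    bedtime_offset_range: tuple[int, int] = (560, 680)  # minutes after series/day start
    # sleep block
    sleep_duration_range: tuple[int, int] = (360, 540)
    sleep_micro_movement_rate: float = 0.3
    sleep_micro_movement_tail_prob: float = 0.1
    good_se_range: tuple[float, float] = (0.85, 0.98)
    poor_se_range: tuple[float, float] = (0.55, 0.85)
    p_good: float = 0.5
    short_bout_prob: float = 0.3
    # daytime-activity -> class coupling
    coupling_strength: float = 1.0
    # nonwear
    p_nonwear: float = 0.05
    nonwear_duration_range: tuple[int, int] = (100, 180)
    # thresholds the planted structure must respect (mirror ScoringConfig)
    movement_threshold: int = 10
    sedentary_threshold: int = 100
    run_min: int = 15  # onset/awakening candidate-run requirement

    def __post_init__(self) -> None:
        # the two class ranges must sit on opposite sides of the 85% cut
        if self.good_se_range[0] < 0.85 or self.poor_se_range[1] > 0.85:
            raise ValueError("class SE ranges must sit on opposite sides of 0.85")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        for name in ("sleep_micro_movement_rate", "p_good", "p_nonwear", "wake_idle_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class NightTruth:
    """Planted values for one night (absolute minute indices, half-open)."""

    subject_id: str
    day_index: int
    bedtime_idx: int
    onset_idx: int
    awakening_idx: int
    latency_min: int
    duration_min: int
    bouts: tuple[tuple[int, int], ...]  # (start_idx, length) incl. short decoys
    waso_min: int
    efficiency: float
    label: str


@dataclass(frozen=True)
class GroundTruth:
    nights: list[NightTruth]
    nonwear: list[tuple[str, int, int]] = field(default_factory=list)


def class_balance(truth: GroundTruth) -> float:
    """Empirical fraction of good-quality nights."""
    if not truth.nights:
        raise ValueError("ground truth contains no nights")
    return sum(n.label == GOOD for n in truth.nights) / len(truth.nights)


# --------------------------------------------------------------------- #


def _wake_counts(
    rng: np.random.Generator,
    n: int,
    cfg: SimConfig,
    label: str,
    evening: bool = False,
) -> np.ndarray:
    """Daytime activity with class-coupled volume/fragmentation/evening shifts."""
    c = cfg.coupling_strength
    sign = 1.0 if label == GOOD else -1.0
    mu = cfg.wake_activity_mean * max(1.0 + 0.10 * c * sign, 0.1)
    p_idle = float(np.clip(cfg.wake_idle_prob * (1.0 - 0.15 * c * sign), 0.02, 0.9))
    if evening:
        mu *= max(1.0 - 0.12 * c * sign, 0.05)
    idle = rng.random(n) < p_idle
    counts = np.empty(n, dtype=np.int64)
    n_idle = int(idle.sum())
    counts[idle] = rng.integers(cfg.movement_threshold + 1, cfg.sedentary_threshold + 1, n_idle)
    r = cfg.wake_activity_dispersion
    lam = rng.gamma(r, mu / r, n - n_idle)
    counts[~idle] = np.maximum(rng.poisson(lam), cfg.movement_threshold + 1)
    return counts


def _sleep_counts(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Within-sleep counts: mostly zero, sparse micro-movements, rare larger twitches.

    Micro-movements stay at or below the candidate-row threshold. A small
    fraction of them are larger twitches (1-minute supra-threshold counts);
    those are kept away from the first/last ``run_min`` minutes of the block
    so they read as brief awakenings inside sleep, not as a delayed onset or
    an early awakening.
    """
    counts = np.zeros(n, dtype=np.int64)
    moving = rng.random(n) < cfg.sleep_micro_movement_rate
    idx = np.flatnonzero(moving)
    if idx.size:
        mags = np.minimum(1 + rng.poisson(2.0, idx.size), cfg.movement_threshold)
        interior = (idx >= cfg.run_min) & (idx < n - cfg.run_min)
        tail = (rng.random(idx.size) < cfg.sleep_micro_movement_tail_prob) & interior
        mags[tail] = rng.integers(cfg.movement_threshold + 1, 36, int(tail.sum()))
        counts[idx] = mags
    return counts


def _plan_waso(
    duration: int, latency: int, target_se: float, label: str, margin: float = 0.005
) -> int:
    """WASO minutes realizing the target SE on the correct side of 85%.

    The realized SE is kept at least ``margin`` away from the 0.85 cut so
    that micro-movement noise (worth at most a couple of WASO minutes) can
    never flip a planted label.
    """
    tib = latency + duration
    waso = int(round(duration - target_se * tib))
    if waso < 0:
        raise GenerationError(
            f"SE target {target_se:.3f} infeasible for duration {duration}, latency {latency}"
        )
    if 0 < waso <= 5:
        waso = 0 if label == GOOD else 6  # WASO in 1..5 is unrealizable as >5-min bouts
    # integer rounding can land the realized SE on the wrong side of the cut
    for _ in range(20):
        realized = (duration - waso) / tib
        if (realized >= 0.85 + margin) if label == GOOD else (realized < 0.85 - margin):
            return waso
        waso += 1 if label == POOR else -1
        if waso < 0 or waso > duration:
            break
    raise GenerationError(f"could not realize SE target {target_se:.3f} for label {label}")


def _split_bouts(rng: np.random.Generator, waso: int) -> list[int]:
    """Split WASO into bout lengths, each strictly >5 and at most 28 minutes.

    The cap keeps every bout safely below the 30-minute movement run that
    would close the sleep period, even if a supra-threshold micro-movement
    lands adjacent to a bout.
    """
    lengths: list[int] = []
    remaining = waso
    while remaining > 28:
        take = int(rng.integers(20, 29))
        if 0 < remaining - take <= 5:  # avoid an unusable leftover
            take = remaining - 6
        lengths.append(take)
        remaining -= take
    if remaining:
        if remaining >= 6:
            lengths.append(remaining)
        else:  # fold into the previous bout, splitting if it would exceed the cap
            total = lengths.pop() + remaining
            if total > 28:
                lengths.extend([total // 2, total - total // 2])
            else:
                lengths.append(total)
    return lengths


def _place_bouts(
    rng: np.random.Generator, duration: int, lengths: list[int], run_min: int
) -> list[tuple[int, int]]:
    """Place bouts inside [0, duration) with ≥ run_min sleep flanking each."""
    k = len(lengths)
    sleep_total = duration - sum(lengths)
    spare = sleep_total - run_min * (k + 1)
    if spare < 0:
        raise GenerationError("sleep block too short to separate planted wake bouts")
    # distribute the spare sleep minutes over the k+1 gaps
    extra = rng.multinomial(spare, np.full(k + 1, 1.0 / (k + 1)))
    placed = []
    pos = 0
    for j, length in enumerate(lengths):
        pos += run_min + int(extra[j])
        placed.append((pos, length))
        pos += length
    return placed


def _generate_day(
    rng: np.random.Generator,
    cfg: SimConfig,
    subject_id: str,
    day_index: int,
    offset: int,
) -> tuple[np.ndarray, NightTruth, tuple[int, int] | None]:
    label = GOOD if rng.random() < cfg.p_good else POOR
    se_lo, se_hi = cfg.good_se_range if label == GOOD else cfg.poor_se_range
    target_se = float(rng.uniform(se_lo, se_hi))
    duration = int(rng.integers(cfg.sleep_duration_range[0], cfg.sleep_duration_range[1] + 1))
    bedtime_offset = int(rng.integers(*cfg.bedtime_offset_range))

    lat_lo, lat_hi = cfg.sedentary_run_min_range
    # latency cannot exceed what keeps WASO >= 0 at the target SE (including
    # the label-robustness margin enforced by _plan_waso)
    se_eff = max(target_se, 0.856) if label == GOOD else target_se
    lat_cap = int(duration * (1.0 - se_eff) / se_eff)
    if lat_cap < lat_lo:
        raise GenerationError(
            f"SE target {target_se:.3f} leaves no room for latency >= {lat_lo}"
        )
    latency = int(rng.integers(lat_lo, min(lat_hi, lat_cap) + 1))

    waso = _plan_waso(duration, latency, target_se, label)
    lengths = _split_bouts(rng, waso) if waso else []
    bouts = _place_bouts(rng, duration, lengths, cfg.run_min)

    day = np.empty(MINUTES_PER_DAY, dtype=np.int64)
    evening_start = max(bedtime_offset - 120, 0)
    day[:evening_start] = _wake_counts(rng, evening_start, cfg, label)
    day[evening_start:bedtime_offset] = _wake_counts(
        rng, bedtime_offset - evening_start, cfg, label, evening=True
    )
    if bedtime_offset:
        # the minute before bed must exceed the sedentary threshold so the
        # inferred bedtime is exactly the start of the planted sedentary run
        day[bedtime_offset - 1] = max(day[bedtime_offset - 1], cfg.sedentary_threshold + 1)
    onset_offset = bedtime_offset + latency
    day[bedtime_offset:onset_offset] = rng.integers(
        cfg.movement_threshold + 1, cfg.sedentary_threshold + 1, latency
    )
    sleep_end = onset_offset + duration
    day[onset_offset:sleep_end] = _sleep_counts(rng, duration, cfg)
    all_bouts = list(bouts)
    for start, length in bouts:
        day[onset_offset + start : onset_offset + start + length] = rng.integers(
            110, 600, length
        )
    # occasional short awakenings (<=5 min): wake movement that adds nothing to WASO
    if bouts and rng.random() < cfg.short_bout_prob:
        length = int(rng.integers(1, 6))
        gaps = [(0, bouts[0][0])] + [
            (bouts[j][0] + bouts[j][1], bouts[j + 1][0]) for j in range(len(bouts) - 1)
        ]
        room = [g for g in gaps if g[1] - g[0] >= 2 * cfg.run_min + length]
        if room:
            g0, g1 = room[int(rng.integers(len(room)))]
            start = (g0 + g1 - length) // 2
            day[onset_offset + start : onset_offset + start + length] = rng.integers(
                110, 600, length
            )
            all_bouts.append((start, length))
    day[sleep_end:] = _wake_counts(rng, MINUTES_PER_DAY - sleep_end, cfg, label)
    # the minute after awakening must be above the movement threshold
    day[sleep_end] = max(day[sleep_end], cfg.sedentary_threshold + 1)

    nonwear = None
    if rng.random() < cfg.p_nonwear:
        nw_len = int(rng.integers(*cfg.nonwear_duration_range))
        latest = evening_start - nw_len - 30
        if latest > 60:
            nw_start = int(rng.integers(60, latest))
            day[nw_start : nw_start + nw_len] = 0
            nonwear = (offset + nw_start, offset + nw_start + nw_len)

    realized_se = (duration - waso) / (latency + duration)
    truth = NightTruth(
        subject_id=subject_id,
        day_index=day_index,
        bedtime_idx=offset + bedtime_offset,
        onset_idx=offset + onset_offset,
        awakening_idx=offset + sleep_end,
        latency_min=latency,
        duration_min=duration,
        bouts=tuple((offset + onset_offset + s, l) for s, l in sorted(all_bouts)),
        waso_min=waso,
        efficiency=realized_se,
        label=label,
    )
    return day, truth, nonwear


def generate_cohort(cfg: SimConfig | None = None) -> tuple[list[MinuteSeries], GroundTruth]:
    """Generate a seed-reproducible cohort of minute series plus ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_time)
    series: list[MinuteSeries] = []
    nights: list[NightTruth] = []
    nonwear: list[tuple[str, int, int]] = []
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:03d}"
        days = []
        for d in range(cfg.days_per_subject):
            day, truth, nw = _generate_day(rng, cfg, subject_id, d, d * MINUTES_PER_DAY)
            days.append(day)
            nights.append(truth)
            if nw is not None:
                nonwear.append((subject_id, nw[0], nw[1]))
        series.append(MinuteSeries(subject_id, start, np.concatenate(days)))
    return series, GroundTruth(nights=nights, nonwear=nonwear)
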