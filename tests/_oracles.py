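"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's run-length-scan code paths: the state
machine oracle tests every index against the verbatim 15/30-minute window
rules, the WASO oracle enumerates bouts positionally, and the AUC oracle sums
over all positive–negative pairs.
"""

from __future__ import annotations

import numpy as np


def brute_force_sleep_periods(counts, cfg):
    """Index-by-index application of the onset/awakening window rules."""
    counts = np.asarray(counts)
    n = len(counts)
    cand = [int(c) <= cfg.movement_threshold for c in counts]
    periods = []
    i = 0
    while i + cfg.onset_run_min <= n:
        if all(cand[i : i + cfg.onset_run_min]):
            onset = i
            # first 30-minute all-movement window after onset closes the period
            close = None
            for k in range(onset, n - cfg.close_movement_min + 1):
                if not any(cand[k : k + cfg.close_movement_min]):
                    close = k
                    break
            limit = close if close is not None else n
            # awakening: end of the last candidate run of length >= 15 before the close
            awakening = None
            j = onset
            while j < limit:
                if cand[j]:
                    run_start = j
                    while j < limit and cand[j]:
                        j += 1
                    if j - run_start >= cfg.awakening_run_min:
                        awakening = j
                else:
                    j += 1
            if close is None:
                # truncated by end of series: last candidate minute closes it
                last = max(idx for idx in range(onset, n) if cand[idx])
                awakening = last + 1
            periods.append((onset, awakening, np.array(cand[onset:awakening])))
            i = awakening if close is None else close + cfg.close_movement_min
        else:
            i += 1
    return periods


def brute_force_waso(asleep, cfg) -> int:
    """Enumerate wake bouts positionally; count those strictly longer than 5."""
    asleep = list(asleep)
    total = 0
    i = 0
    while i < len(asleep):
        if not asleep[i]:
            j = i
            while j < len(asleep) and not asleep[j]:
                j += 1
            if j - i > cfg.waso_bout_exclusive_min:
                total += j - i
            i = j
        else:
            i += 1
    return total


def pairwise_auc(labels, scores) -> float:
    """AUC as the positive-vs-negative rank statistic, ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_run_series(rng: np.random.Generator, max_len: int = 200) -> np.ndarray:
    """Run-structured random count series exercising the scoring rules.

    Alternates low/high blocks with geometric lengths around the scoring
    constants so onset runs, inside-sleep wake bouts, closing movement runs
    and truncation all occur with useful frequency.
    """
    n = int(rng.integers(1, max_len + 1))
    out = []
    low = bool(rng.integers(2))
    while len(out) < n:
        run = int(rng.integers(1, 45))
        if low:
            values = rng.choice([0, 2, 8], size=run)
        else:
            values = rng.choice([15, 60, 300, 900], size=run)
        out.extend(values.tolist())
        low = not low
    return np.asarray(out[:n], dtype=np.int64)
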