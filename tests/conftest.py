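from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actisleep import MinuteSeries, ScoringConfig, SimConfig, generate_cohort


@pytest.fixture
def cfg() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture
def t0() -> pd.Timestamp:
    return pd.Timestamp("2026-01-05T12:00:00")


@pytest.fixture
def make_series(t0):
    def _make(counts, subject_id="S001"):
        return MinuteSeries(subject_id, t0, np.asarray(counts, dtype=np.int64))

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects, three days each, default (moderate) coupling."""
    cfg = SimConfig(n_subjects=2, days_per_subject=3, seed=11, p_nonwear=0.0)
    return generate_cohort(cfg)


def day_pattern(active_before=600, candidate=480, active_after=360, level=500):
    """Concatenate an active / zero-count / active block pattern."""
    return np.concatenate(
        [
            np.full(active_before, level, dtype=np.int64),
            np.zeros(candidate, dtype=np.int64),
            np.full(active_after, level, dtype=np.int64),
        ]
    )
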