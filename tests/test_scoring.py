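from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep import (
    ScoringConfig,
    classify_candidate_rows,
    compute_sleep_efficiency,
    compute_waso,
    detect_nonwear,
    detect_sleep_periods,
    infer_latency,
    label_quality,
    score_recording,
)

from _oracles import brute_force_sleep_periods, brute_force_waso, random_run_series
from conftest import day_pattern


class TestCandidateRows:
    def test_thresholding(self):
        cfg = ScoringConfig(movement_threshold=100)
        out = classify_candidate_rows(np.array([500, 3, 0, 800]), cfg)
        np.testing.assert_array_equal(out, [False, True, True, False])

    def test_all_above_threshold(self, cfg):
        assert not classify_candidate_rows(np.full(20, 900), cfg).any()

    def test_all_zero(self, cfg):
        assert classify_candidate_rows(np.zeros(20, int), cfg).all()


class TestNonwear:
    def test_embedded_zero_block_found(self, cfg):
        counts = np.concatenate([np.full(50, 400), np.zeros(120, int), np.full(50, 400)])
        assert detect_nonwear(counts, ScoringConfig(nonwear_zero_run_min=90)) == [(50, 170)]

    def test_short_zero_run_ignored(self):
        counts = np.concatenate([np.full(50, 400), np.zeros(30, int), np.full(50, 400)])
        assert detect_nonwear(counts, ScoringConfig(nonwear_zero_run_min=90)) == []

    def test_no_zeros(self, cfg):
        assert detect_nonwear(np.full(200, 5), cfg) == []


class TestStateMachine:
    def test_fully_active_series(self, cfg):
        assert detect_sleep_periods(np.full(300, 600), cfg) == []

    def test_single_clean_period(self, cfg):
        periods = detect_sleep_periods(day_pattern(60, 480, 60), cfg)
        assert [(p[0], p[1]) for p in periods] == [(60, 540)]
        assert periods[0][2].all()

    def test_fourteen_minute_run_never_opens(self, cfg):
        counts = np.concatenate(
            [
                np.full(60, 600),
                np.zeros(14, int),
                np.full(1, 600),
                np.zeros(15, int),
                np.full(40, 600),
            ]
        )
        periods = detect_sleep_periods(counts, cfg)
        assert [(p[0], p[1]) for p in periods] == [(75, 90)]

    def test_short_movement_keeps_period_open(self, cfg):
        counts = np.concatenate(
            [np.full(60, 600), np.zeros(120, int), np.full(10, 600), np.zeros(120, int), np.full(40, 600)]
        )
        periods = detect_sleep_periods(counts, cfg)
        assert [(p[0], p[1]) for p in periods] == [(60, 310)]

    def test_series_shorter_than_onset_run(self, cfg):
        assert detect_sleep_periods(np.zeros(10, int), cfg) == []

    def test_equals_brute_force_on_random_series(self, cfg):
        rng = np.random.default_rng(2024)
        for _ in range(400):
            counts = random_run_series(rng, max_len=200)
            got = detect_sleep_periods(counts, cfg)
            want = brute_force_sleep_periods(counts, cfg)
            assert [(p[0], p[1]) for p in got] == [(p[0], p[1]) for p in want]
            for g, w in zip(got, want):
                np.testing.assert_array_equal(g[2], w[2])

    def test_periods_disjoint_sorted_long_enough(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(200):
            counts = random_run_series(rng, max_len=200)
            periods = detect_sleep_periods(counts, cfg)
            prev_end = -1
            for onset, awakening, asleep in periods:
                assert onset > prev_end
                assert awakening - onset >= cfg.onset_run_min
                assert len(asleep) == awakening - onset
                prev_end = awakening


class TestLatency:
    def test_active_minutes_before_onset_give_zero(self, cfg):
        counts = day_pattern(60, 480, 60)
        assert infer_latency(counts, 60, cfg) == (60, 0)

    def test_sedentary_run_measured(self, cfg):
        counts = np.concatenate(
            [np.full(40, 600), np.full(20, 40), np.zeros(480, int), np.full(60, 600)]
        )
        assert infer_latency(counts, 60, cfg) == (40, 20)

    def test_truncated_at_previous_awakening(self, cfg):
        # sedentary minutes abut the previous period's awakening at minute 100
        counts = np.concatenate([np.full(30, 40), np.zeros(480, int), np.full(30, 40), np.zeros(480, int)])
        assert infer_latency(counts, 540, cfg, previous_awakening_idx=510) == (510, 30)


class TestWaso:
    def test_no_wake_bouts(self, cfg):
        assert compute_waso(np.ones(480, bool), cfg) == 0

    def test_only_bouts_longer_than_five_counted(self, cfg):
        asleep = np.ones(200, bool)
        asleep[20:23] = False  # 3 min
        asleep[60:66] = False  # 6 min
        asleep[120:130] = False  # 10 min
        assert compute_waso(asleep, cfg) == 16

    def test_exactly_five_minutes_excluded(self, cfg):
        asleep = np.ones(100, bool)
        asleep[50:55] = False
        assert compute_waso(asleep, cfg) == 0

    @given(st.lists(st.booleans(), min_size=1, max_size=150))
    @settings(max_examples=300, deadline=None)
    def test_equals_brute_force_enumeration(self, asleep):
        cfg = ScoringConfig()
        assert compute_waso(np.array(asleep), cfg) == brute_force_waso(asleep, cfg)


class TestEfficiency:
    @pytest.mark.parametrize(
        "duration,waso,latency,expected",
        [(480, 0, 0, 1.0), (460, 30, 20, 430 / 480), (420, 63, 60, 357 / 480)],
    )
    def test_ratio_of_sleep_to_time_in_bed(self, duration, waso, latency, expected):
        assert compute_sleep_efficiency(duration, waso, latency) == pytest.approx(expected, abs=1e-12)

    def test_zero_time_in_bed_rejected(self):
        with pytest.raises(ValueError):
            compute_sleep_efficiency(0, 0, 0)

    @given(
        st.integers(30, 600), st.integers(0, 200), st.integers(0, 120)
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, duration, waso, latency):
        waso = min(waso, duration)
        se = compute_sleep_efficiency(duration, waso, latency)
        assert 0.0 <= se <= 1.0
        if waso < duration:  # with zero sleep time SE is pinned at 0
            assert compute_sleep_efficiency(duration, waso + 1, latency) < se
            assert compute_sleep_efficiency(duration, waso, latency + 1) < se


class TestQualityLabel:
    @pytest.mark.parametrize(
        "efficiency,expected",
        [(0.85, "good"), (0.8499, "poor"), (1.0, "good"), (0.0, "poor")],
    )
    def test_inclusive_85_percent_boundary(self, efficiency, expected, cfg):
        assert label_quality(efficiency, cfg) == expected


class TestScoreRecording:
    def test_nonwear_block_scores_perfect_efficiency_in_naive_mode(self, make_series):
        series = make_series(day_pattern(600, 480, 360))
        (p,) = score_recording(series, ScoringConfig(nonwear_mode="paper_naive"))
        assert p.efficiency == 1.0
        assert p.label == "good"
        assert p.nonwear_flag  # flagged, but still scored as sleep

    def test_exclude_mode_flags_for_downstream_removal(self, make_series):
        series = make_series(day_pattern(600, 480, 360))
        (p,) = score_recording(series, ScoringConfig(nonwear_mode="exclude"))
        assert p.nonwear_flag

    def test_planted_structure_recovered_exactly(self, make_series, cfg):
        # 20 min sedentary, sleep with one 10-min bout, closed by movement
        counts = np.concatenate(
            [
                np.full(100, 600),
                np.full(20, 50),  # latency
                np.zeros(200, int),
                np.full(10, 300),  # wake bout
                np.zeros(190, int),
                np.full(60, 600),
            ]
        )
        (p,) = score_recording(make_series(counts), cfg)
        assert (p.bedtime_idx, p.onset_idx, p.awakening_idx) == (100, 120, 520)
        assert (p.latency_min, p.waso_min, p.duration_min) == (20, 10, 400)
        assert p.efficiency == pytest.approx(390 / 420)
        assert not p.truncated

    def test_scaling_counts_above_thresholds_is_invariant(self, make_series, cfg):
        rng = np.random.default_rng(3)
        counts = random_run_series(rng, max_len=200)
        scaled = counts.copy()
        above = counts > max(cfg.movement_threshold, cfg.sedentary_threshold)
        scaled[above] = counts[above] * 7
        original = score_recording(make_series(counts), cfg)
        rescored = score_recording(make_series(scaled), cfg)
        assert [(p.onset_idx, p.awakening_idx, p.waso_min, p.efficiency) for p in original] == [
            (p.onset_idx, p.awakening_idx, p.waso_min, p.efficiency) for p in rescored
        ]

    def test_truncated_final_period_marked(self, make_series, cfg):
        counts = np.concatenate([np.full(60, 600), np.zeros(100, int)])
        (p,) = score_recording(make_series(counts), cfg)
        assert p.truncated
        assert p.awakening_idx == 160
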