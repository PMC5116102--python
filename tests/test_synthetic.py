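from __future__ import annotations


import numpy as np
import pytest

from actisleep import (
    ScoringConfig,
    SimConfig,
    class_balance,
    generate_cohort,
    score_recording,
)
from actisleep.simulate import GenerationError


def _score_all(series_list, cfg=None):
    cfg = cfg or ScoringConfig()
    periods = []
    for series in series_list:
        periods.extend(score_recording(series, cfg))
    return periods


class TestDeterminism:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(n_subjects=2, days_per_subject=1, seed=7)
        (a, ta) = generate_cohort(cfg)
        (b, tb) = generate_cohort(cfg)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.counts, s2.counts)
        assert ta == tb

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SimConfig(n_subjects=1, days_per_subject=1, seed=1))
        b, _ = generate_cohort(SimConfig(n_subjects=1, days_per_subject=1, seed=2))
        assert not np.array_equal(a[0].counts, b[0].counts)


class TestClassBalance:
    def test_even_balance_within_binomial_error(self):
        _, truth = generate_cohort(
            SimConfig(n_subjects=60, days_per_subject=7, seed=21, p_nonwear=0.0)
        )
        assert len(truth.nights) == 420
        assert 0.44 <= class_balance(truth) <= 0.56

    def test_all_good_configuration(self):
        _, truth = generate_cohort(SimConfig(n_subjects=5, days_per_subject=2, seed=3, p_good=1.0))
        assert class_balance(truth) == 1.0

    def test_all_poor_configuration(self):
        _, truth = generate_cohort(SimConfig(n_subjects=5, days_per_subject=2, seed=3, p_good=0.0))
        assert class_balance(truth) == 0.0


class TestPlantedStructure:
    def test_class_se_ranges_sit_on_opposite_sides_of_cut(self):
        _, truth = generate_cohort(SimConfig(n_subjects=20, days_per_subject=7, seed=5))
        for night in truth.nights:
            if night.label == "good":
                assert night.efficiency >= 0.85
            else:
                assert night.efficiency < 0.85

    def test_long_bouts_make_up_waso_short_bouts_do_not(self):
        _, truth = generate_cohort(SimConfig(n_subjects=20, days_per_subject=3, seed=13))
        for night in truth.nights:
            long_total = sum(l for _, l in night.bouts if l > 5)
            assert long_total == night.waso_min
            assert all(l <= 28 for _, l in night.bouts)

    def test_truth_consistent_with_counts(self):
        cfg = SimConfig(n_subjects=3, days_per_subject=2, seed=17, p_nonwear=0.0)
        series_list, truth = generate_cohort(cfg)
        by_subject = {s.subject_id: s.counts for s in series_list}
        for night in truth.nights:
            counts = by_subject[night.subject_id]
            for start, length in night.bouts:
                assert (counts[start : start + length] > cfg.movement_threshold).all()
            latency_run = counts[night.bedtime_idx : night.onset_idx]
            assert (latency_run > cfg.movement_threshold).all()
            assert (latency_run <= cfg.sedentary_threshold).all()

    def test_infeasible_se_target_raises(self):
        cfg = SimConfig(
            n_subjects=1,
            days_per_subject=1,
            seed=0,
            good_se_range=(0.999, 0.9999),
            p_good=1.0,
            sedentary_run_min_range=(30, 40),
        )
        with pytest.raises(GenerationError):
            generate_cohort(cfg)


class TestScoringRecovery:
    def test_noise_free_recovery_is_exact(self):
        cfg = SimConfig(
            n_subjects=10, days_per_subject=3, seed=29,
            sleep_micro_movement_rate=0.0, p_nonwear=0.0,
        )
        series_list, truth = generate_cohort(cfg)
        periods = _score_all(series_list)
        assert len(periods) == len(truth.nights)
        for p, night in zip(periods, truth.nights):
            assert (p.onset_idx, p.awakening_idx) == (night.onset_idx, night.awakening_idx)
            assert p.latency_min == night.latency_min
            assert p.waso_min == night.waso_min
            assert p.efficiency == pytest.approx(night.efficiency, abs=1e-12)
            assert p.label == night.label

    def test_default_noise_recovery_within_tolerance(self):
        cfg = SimConfig(n_subjects=10, days_per_subject=3, seed=31, p_nonwear=0.0)
        series_list, truth = generate_cohort(cfg)
        periods = _score_all(series_list)
        assert len(periods) == len(truth.nights)
        errors = [abs(p.efficiency - n.efficiency) for p, n in zip(periods, truth.nights)]
        assert np.mean(np.array(errors) <= 0.02) >= 0.95

    def test_coupling_zero_daytime_distributions_match(self):
        cfg = SimConfig(
            n_subjects=29, days_per_subject=7, seed=37, coupling_strength=0.0, p_nonwear=0.0
        )
        series_list, truth = generate_cohort(cfg)
        good_means, poor_means = [], []
        by_subject = {s.subject_id: s.counts for s in series_list}
        for night in truth.nights:
            counts = by_subject[night.subject_id]
            day_start = night.day_index * 1440
            daytime = counts[day_start : night.bedtime_idx]
            (good_means if night.label == "good" else poor_means).append(daytime.mean())
        g, p = np.array(good_means), np.array(poor_means)
        pooled_se = np.sqrt(g.var(ddof=1) / len(g) + p.var(ddof=1) / len(p))
        assert abs(g.mean() - p.mean()) < 2 * pooled_se

    def test_coupling_separates_daytime_means(self):
        cfg = SimConfig(
            n_subjects=29, days_per_subject=7, seed=37, coupling_strength=2.0, p_nonwear=0.0
        )
        series_list, truth = generate_cohort(cfg)
        by_subject = {s.subject_id: s.counts for s in series_list}
        good, poor = [], []
        for night in truth.nights:
            counts = by_subject[night.subject_id]
            daytime = counts[night.day_index * 1440 : night.bedtime_idx]
            (good if night.label == "good" else poor).append(daytime.mean())
        assert np.mean(good) > np.mean(poor) * 1.1


class TestNonwear:
    def test_nonwear_blocks_recorded_and_zero(self):
        cfg = SimConfig(n_subjects=10, days_per_subject=7, seed=41, p_nonwear=0.5)
        series_list, truth = generate_cohort(cfg)
        assert truth.nonwear  # some blocks planted at this rate
        by_subject = {s.subject_id: s.counts for s in series_list}
        for subject_id, start, end in truth.nonwear:
            assert (by_subject[subject_id][start:end] == 0).all()
            assert end - start >= 100
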