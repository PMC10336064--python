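"""Synthetic-cohort generator: response models, covariate links, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audphon import (
    CohortConfig,
    cohort_to_frames,
    generate_cohort,
    make_observer,
    p_correct_rtd,
    p_da,
    simulate_identification,
    simulate_rtd_trial,
)
from audphon.observers import ConfigurationError, GroupParams


class TestRtdResponseModel:
    def test_chance_at_reference(self, make_profile):
        """A deviant identical to the 15 ms reference is at 3AFC chance."""
        obs = make_profile()
        assert p_correct_rtd(obs, 15.0) == pytest.approx(1 / 3)

    def test_anchored_at_threshold(self, make_profile):
        """p equals 0.707 exactly at the observer's 70.7%-point, for any width."""
        for w in (0.1, 0.3, 0.6):
            obs = make_profile(rtd_x707_ms=60.0, rtd_width_log=w)
            assert p_correct_rtd(obs, 60.0) == pytest.approx(0.707)

    def test_asymptote(self, make_profile):
        obs = make_profile(rtd_x707_ms=60.0)
        assert p_correct_rtd(obs, 600.0) > 0.99

    def test_below_reference_rejected(self, make_profile):
        with pytest.raises(ValueError):
            p_correct_rtd(make_profile(), 10.0)

    @given(st.floats(min_value=16.0, max_value=690.0),
           st.floats(min_value=1.001, max_value=1.5),
           st.floats(min_value=0.1, max_value=0.8))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rise_time(self, rise, factor, width):
        from audphon import ObserverProfile

        obs = ObserverProfile(
            participant_id="h", group="control", rtd_x707_ms=80.0,
            rtd_width_log=width, id_midpoint=5.5, id_width=1.0,
            id_guess=0.0, id_lapse=0.0, hearing_fletcher_db=30.0,
            cognition_z=0.0, phonology_screeling=20.0, fluency_count=15)
        assert p_correct_rtd(obs, rise * factor) >= p_correct_rtd(obs, rise) - 1e-12

    def test_bernoulli_rate_at_chance(self, make_profile, rng):
        """At the reference the correct fraction is ~1/3 (binomial bound)."""
        obs = make_profile()
        hits = sum(simulate_rtd_trial(obs, 15.0, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(1 / 3, abs=0.02)

    def test_trial_sequence_deterministic(self, make_profile):
        obs = make_profile()
        seqs = []
        for _ in range(2):
            r = np.random.default_rng(7)
            seqs.append([simulate_rtd_trial(obs, 40.0, r) for _ in range(50)])
        assert seqs[0] == seqs[1]


class TestIdentificationModel:
    def test_midpoint_is_half(self, make_profile):
        obs = make_profile(id_guess=0.0, id_lapse=0.0, id_midpoint=5.5)
        assert p_da(obs, 5.5) == pytest.approx(0.5)

    def test_asymptotes_are_guess_and_one_minus_lapse(self, make_profile):
        obs = make_profile(id_guess=0.1, id_lapse=0.05, id_midpoint=5.5,
                           id_width=0.2)
        assert p_da(obs, 1) == pytest.approx(0.1, abs=1e-6)
        assert p_da(obs, 10) == pytest.approx(0.95, abs=1e-6)

    def test_formula_value(self, make_profile):
        """psi = gamma + (1-gamma-lambda) * S at an S = 0.75 point."""
        width = 1.5 / math.log(3.0)  # logistic hits 0.75 at z = ln 3
        obs = make_profile(id_guess=0.2, id_lapse=0.1, id_midpoint=5.5,
                           id_width=width)
        assert p_da(obs, 7.0) == pytest.approx(0.2 + 0.7 * 0.75)

    def test_step_out_of_range(self, make_profile):
        with pytest.raises(ValueError):
            p_da(make_profile(), 11)

    def test_counts_shape_and_total(self, make_profile, rng):
        data = simulate_identification(make_profile(), rng)
        assert len(data.steps) == 10 and data.reps_per_step == 8
        assert sum(data.reps_per_step for _ in data.steps) == 80
        assert all(0 <= c <= 8 for c in data.da_counts)

    def test_step_function_observer(self, make_profile, rng):
        obs = make_profile(id_guess=0.0, id_lapse=0.0, id_midpoint=5.5,
                           id_width=1e-9)
        data = simulate_identification(obs, rng)
        assert data.da_counts == (0, 0, 0, 0, 0, 8, 8, 8, 8, 8)

    def test_counts_match_probabilities(self, make_profile, rng):
        """Mean count/reps across cohorts within 3 binomial SEs of p_da."""
        obs = make_profile(id_guess=0.1, id_lapse=0.05)
        reps, n_cohorts = 200, 100
        totals = np.zeros(10)
        for _ in range(n_cohorts):
            totals += np.asarray(
                simulate_identification(obs, rng, reps_per_step=reps).da_counts)
        phat = totals / (reps * n_cohorts)
        for i, step in enumerate(range(1, 11)):
            p = p_da(obs, step)
            se = math.sqrt(p * (1 - p) / (reps * n_cohorts))
            assert abs(phat[i] - p) <= 3 * se + 1e-12


class TestCohortGeneration:
    def test_phonology_link_slope(self):
        """With noise off, a +1 difference in log threshold shifts
        phonology by the generating slope -2.70."""
        cfg = CohortConfig(
            control=GroupParams(mean_log_x707=4.0, sd_log_x707=1e-12,
                                mean_id_width=1.2, sd_id_width=0.15,
                                hearing_sd_db=1e-12, cognition_sd=1e-12),
            phonology_noise_sd=1e-12,
        )
        cfg2 = cfg.model_copy(deep=True)
        cfg2.control.mean_log_x707 = 5.0
        rng = np.random.default_rng(0)
        a = make_observer("control", cfg, rng)
        b = make_observer("control", cfg2, np.random.default_rng(0))
        assert b.phonology_screeling - a.phonology_screeling == pytest.approx(
            -2.70, abs=1e-6)

    def test_degenerate_variance_gives_identical_observers(self):
        gp = GroupParams(mean_log_x707=4.0, sd_log_x707=1e-12,
                         mean_id_width=1.2, sd_id_width=1e-12,
                         sd_rtd_width_log=1e-12, sd_id_midpoint=1e-12,
                         guess_range=(0.05, 0.05 + 1e-12),
                         lapse_range=(0.02, 0.02 + 1e-12),
                         hearing_sd_db=1e-12, cognition_sd=1e-12)
        cfg = CohortConfig(control=gp, phonology_noise_sd=1e-12,
                           fluency_noise_sd=1e-12)
        rng = np.random.default_rng(3)
        obs = [make_observer("control", cfg, rng) for _ in range(5)]
        for o in obs[1:]:
            assert o.rtd_x707_ms == pytest.approx(obs[0].rtd_x707_ms)
            assert o.id_width == pytest.approx(obs[0].id_width)
            assert o.phonology_screeling == pytest.approx(obs[0].phonology_screeling)

    def test_latent_mean_recovers_generating_mean(self):
        """Monte-Carlo: sample mean of log x707 within 3 SEs of mu = 4.0."""
        cfg = CohortConfig(control=GroupParams(
            mean_log_x707=4.0, sd_log_x707=0.5,
            mean_id_width=1.2, sd_id_width=0.15))
        rng = np.random.default_rng(11)
        logs = [math.log(make_observer("control", cfg, rng).rtd_x707_ms)
                for _ in range(1000)]
        se = 0.5 / math.sqrt(1000)
        assert abs(np.mean(logs) - 4.0) <= 3 * se

    def test_invalid_group_label(self):
        with pytest.raises(ConfigurationError):
            make_observer("patients", CohortConfig(), np.random.default_rng(0))

    def test_cohort_sizes_match_study_design(self):
        cohort = generate_cohort(CohortConfig(), seed=0)
        assert len(cohort.by_group("control")) == 23
        assert len(cohort.by_group("aphasia")) == 29

    def test_same_seed_same_serialized_cohort(self):
        frames_a = cohort_to_frames(generate_cohort(CohortConfig(), seed=5))
        frames_b = cohort_to_frames(generate_cohort(CohortConfig(), seed=5))
        assert frames_a[0].equals(frames_b[0])
        assert frames_a[1].equals(frames_b[1])

    def test_group_shift_detected_by_ranksum(self):
        """Power check: +1.0 log-threshold shift, n=200/200, Wilcoxon
        rejects at alpha = 0.001 in >= 95% of replicates."""
        from scipy.stats import mannwhitneyu

        cfg = CohortConfig(n_control=200, n_aphasia=200)
        cfg.aphasia.mean_log_x707 = cfg.control.mean_log_x707 + 1.0
        cfg.aphasia.sd_log_x707 = cfg.control.sd_log_x707
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            cohort = generate_cohort(cfg, seed=1000 + rep)
            a = [math.log(o.rtd_x707_ms) for o in cohort.by_group("aphasia")]
            c = [math.log(o.rtd_x707_ms) for o in cohort.by_group("control")]
            if mannwhitneyu(a, c, alternative="two-sided").pvalue < 0.001:
                rejections += 1
        assert rejections >= 95

    def test_observer_invariants_hold_across_draws(self):
        cohort = generate_cohort(CohortConfig(), seed=42)
        for o in cohort.observers:
            assert o.rtd_x707_ms > 15
            assert 0 <= o.phonology_screeling <= 24
            assert o.id_guess + o.id_lapse < 1
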