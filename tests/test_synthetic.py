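"""Synthetic-data generator: sampler correctness, schedules, cohort tables."""

import numpy as np
import pytest
from scipy.stats import kstest

from arcwalk.macro_metrics import fit_powerlaw_alpha
from arcwalk.synthetic import (
    PROFILES,
    GaitProfile,
    draw_bout_durations,
    make_bout,
    simulate_cohort_outcomes,
    simulate_recording,
    simulate_schedule,
    synthesize_signal,
    truncated_powerlaw_cdf,
)


class TestBoutDurationSampler:
    def test_degenerate_support_collapses_to_x_min(self):
        d = draw_bout_durations(4, alpha=1.67, x_min=3.0, x_max=3.0 + 1e-9, seed=0)
        assert np.allclose(d, 3.0, atol=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            draw_bout_durations(10, alpha=1.0, x_min=3, x_max=600)
        with pytest.raises(ValueError):
            draw_bout_durations(10, alpha=1.67, x_min=600, x_max=3)
        with pytest.raises(ValueError):
            draw_bout_durations(0, alpha=1.67, x_min=3, x_max=600)

    def test_mle_reestimates_alpha(self):
        d = draw_bout_durations(5000, alpha=1.67, x_min=3, x_max=600, seed=1)
        alpha_hat = fit_powerlaw_alpha(d, x_max=600.0)
        assert abs(alpha_hat - 1.67) < 0.05

    def test_short_bout_fraction_matches_closed_form_cdf(self):
        d = draw_bout_durations(5000, alpha=1.67, x_min=3, x_max=600, seed=2)
        frac = float(np.mean(d < 10))
        assert 0.55 < frac < 0.75
        expected = truncated_powerlaw_cdf(10.0, 1.67, 3.0, 600.0)
        assert abs(frac - expected) < 0.03

    def test_ks_distance_to_closed_form_cdf(self):
        d = draw_bout_durations(10_000, alpha=1.67, x_min=3, x_max=600, seed=3)
        ks = kstest(d, lambda x: truncated_powerlaw_cdf(x, 1.67, 3.0, 600.0)).statistic
        assert ks < 0.02

    def test_determinism(self):
        a = draw_bout_durations(100, 1.67, 3, 600, seed=9)
        b = draw_bout_durations(100, 1.67, 3, 600, seed=9)
        assert a.tobytes() == b.tobytes()


class TestGaitProfile:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GaitProfile(bout_alpha=0.9)
        with pytest.raises(ValueError):
            GaitProfile(cadence_hz=1.8, bout_min_s=1.0)  # < 3 steps at cadence
        with pytest.raises(ValueError):
            GaitProfile(rest_mean_s=1.0)  # below the 2.5 s rest floor
        with pytest.raises(ValueError):
            GaitProfile(active_hours_per_day=25)


class TestSchedule:
    def test_inactive_profile_has_no_bouts_signal_is_gravity_plus_noise(self):
        prof = GaitProfile(active_hours_per_day=0.0, noise_sd_g=0.0)
        rec, truth = simulate_recording(prof, days=1, fs=50.0, seed=0)
        assert truth.n_bouts == 0 and not truth.step_times_s
        assert np.allclose(rec.az, -1.0) and np.allclose(rec.ax, 0.0)

    def test_forced_60s_bout_step_count(self):
        interval, steps = make_bout(0.0, 60.0, cadence_hz=1.8)
        assert len(steps) == round(60 * 1.8) == 108
        assert all(interval[0] <= s < interval[1] for s in steps)

    def test_every_bout_has_at_least_three_steps_inside_its_interval(self):
        truth = simulate_schedule(PROFILES["rest_home"], days=1, seed=4)
        for s, e in truth.bout_intervals:
            assert len(truth.steps_in(s, e)) >= 3

    def test_intervals_sorted_nonoverlapping_with_rest_gaps(self):
        truth = simulate_schedule(PROFILES["hospital"], days=2, seed=5)
        iv = truth.bout_intervals
        for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
            assert e0 <= s1
            if int(s0 // 86400) == int(s1 // 86400):
                assert s1 - e0 >= 2.5  # rest rule floor: never mergeable

    def test_dementia_profile_walk_minutes_near_calibration_target(self):
        truth = simulate_schedule(PROFILES["dementia"], days=7, seed=7)
        per_day = np.mean(truth.per_day_walk_min)
        assert abs(per_day - 137) / 137 < 0.20

    def test_schedule_determinism(self):
        a = simulate_schedule(PROFILES["rest_home"], days=1, seed=11)
        b = simulate_schedule(PROFILES["rest_home"], days=1, seed=11)
        assert a.bout_intervals == b.bout_intervals
        assert a.step_times_s == b.step_times_s


class TestCohortOutcomes:
    SPEC_H = ("hospital", 117, {"walk": 58.0}, {"walk": 37.0})
    SPEC_D = ("dementia", 25, {"walk": 137.0}, {"walk": 59.0})

    def test_identical_groups_give_near_zero_effect(self):
        from arcwalk.cohort_stats import hedges_g

        specs = [
            ("a", 200, {"y": 50.0}, {"y": 10.0}),
            ("b", 200, {"y": 50.0}, {"y": 10.0}),
        ]
        tab = simulate_cohort_outcomes(specs, seed=0)
        a, b = tab[tab.group == "a"].y, tab[tab.group == "b"].y
        g = hedges_g(a.mean(), a.std(ddof=1), 200, b.mean(), b.std(ddof=1), 200)
        assert g < 0.15

    def test_group_moments_match_request(self):
        tab = simulate_cohort_outcomes([self.SPEC_H], seed=1)
        w = tab.walk
        assert (w >= 0).all()
        assert abs(w.mean() - 58) < 12 and abs(w.std(ddof=1) - 37) < 10

    def test_recovered_effect_size_in_published_band(self):
        from arcwalk.cohort_stats import hedges_g

        gs = []
        for seed in range(10):
            tab = simulate_cohort_outcomes([self.SPEC_H, self.SPEC_D], seed=seed)
            h, d = tab[tab.group == "hospital"].walk, tab[tab.group == "dementia"].walk
            gs.append(
                hedges_g(h.mean(), h.std(ddof=1), len(h), d.mean(), d.std(ddof=1), len(d))
            )
        assert 1.0 <= np.median(gs) <= 2.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort_outcomes([("a", 10, {"y": 5.0}, {"y": 0.0})])

    def test_determinism(self):
        a = simulate_cohort_outcomes([self.SPEC_H], seed=3)
        b = simulate_cohort_outcomes([self.SPEC_H], seed=3)
        assert a.equals(b)


class TestSignalSynthesis:
    def test_recording_matches_ground_truth_events(self, quiet_profile):
        interval, steps = make_bout(10.0, 6 / 1.8, 1.8)
        from arcwalk.synthetic import GroundTruth

        truth = GroundTruth([interval], steps, [])
        rec = synthesize_signal(truth, quiet_profile, 30.0, fs=100.0, seed=0)
        # vertical dips below baseline exactly near each step
        for s in steps:
            i = int(s * 100)
            assert rec.az[i - 2 : i + 3].min() < -1.1
        # rest region is pure gravity
        assert np.allclose(rec.az[:800], -1.0)

    def test_signal_determinism(self):
        prof = PROFILES["rest_home"]
        truth = simulate_schedule(prof, 1, seed=2)
        a = synthesize_signal(truth, prof, 60.0, fs=100.0, seed=2, t0=8 * 3600)
        b = synthesize_signal(truth, prof, 60.0, fs=100.0, seed=2, t0=8 * 3600)
        assert a.az.tobytes() == b.az.tobytes()
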