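import numpy as np
import pandas as pd
import pytest

import reachadapt as ra
from reachadapt.cohort import (
    AdaptationState,
    implicit_closed_form,
    simulate_localization,
    simulate_reach,
    update_state,
)
from reachadapt.config import SimulationConfig
from reachadapt.kinematics import angular_deviation


def make_cfg(**kw):
    return SimulationConfig(**kw)


class TestUpdateState:
    def test_three_noise_free_trials_match_closed_form(self):
        """With A=1, B=0.2, r=30: implicit follows 30*(1-0.8^t) = 6, 10.8, 14.64."""
        cfg = make_cfg(retention_A=1.0, learn_rate_B=0.2, rotation_deg=30)
        state = AdaptationState()
        seen = []
        for _ in range(3):
            error = state.implicit_deg - 30.0  # hand deviation − rotation
            state = update_state(state, error, cfg)
            seen.append(state.implicit_deg)
        assert seen == pytest.approx([6.0, 10.8, 14.64], abs=1e-12)

    def test_zero_learning_rate_freezes_state(self, rng):
        cfg = make_cfg(retention_A=1.0, learn_rate_B=0.0)
        state = AdaptationState(implicit_deg=5.0)
        for error in rng.normal(0, 10, 20):
            state = update_state(state, error, cfg)
        assert state.implicit_deg == 5.0

    def test_one_shot_correction(self):
        cfg = make_cfg(retention_A=1.0, learn_rate_B=1.0, rotation_deg=30)
        state = update_state(AdaptationState(), -30.0, cfg)
        assert state.implicit_deg == pytest.approx(30.0)
        # error is now zero; state stays put
        state = update_state(state, state.implicit_deg - 30.0, cfg)
        assert state.implicit_deg == pytest.approx(30.0)

    def test_recursion_matches_step_oracle_for_random_parameters(self, rng):
        """Closed form u_t = r·B·Σ (A−B)^k vs an independent step-by-step loop."""
        for _ in range(100):
            a, b = rng.uniform(0.5, 1.0), rng.uniform(0.0, 0.5)
            r = float(rng.choice([30.0, 60.0]))
            n = int(rng.integers(1, 60))
            cfg = make_cfg(retention_A=a, learn_rate_B=b, rotation_deg=r)
            # oracle: literal recursion
            u = 0.0
            for _ in range(n):
                u = a * u + b * (r - u)
            assert implicit_closed_form(n, cfg) == pytest.approx(u, rel=1e-10, abs=1e-10)

    def test_implicit_bounded_by_rotation_noise_free(self, rng):
        for _ in range(20):
            cfg = make_cfg(
                retention_A=float(rng.uniform(0.8, 1.0)),
                learn_rate_B=float(rng.uniform(0.0, 1.0)),
                rotation_deg=60.0,
            )
            state = AdaptationState()
            for _ in range(200):
                state = update_state(state, state.implicit_deg - 60.0, cfg)
                assert 0.0 <= state.implicit_deg <= 60.0 + 1e-9


class TestSimulateReach:
    def test_on_target_reach_has_zero_deviation(self):
        cfg = make_cfg(motor_noise_sd_deg=0.0)
        trial = simulate_reach(90.0, 90.0, cfg)
        dev = angular_deviation(trial.t_s, trial.x_cm, trial.y_cm, 90.0)
        assert dev.deviation_deg == pytest.approx(0.0, abs=1e-9)

    def test_aimed_reach_deviation_equals_aim_minus_target(self):
        cfg = make_cfg(motor_noise_sd_deg=0.0)
        trial = simulate_reach(120.0, 90.0, cfg)
        dev = angular_deviation(trial.t_s, trial.x_cm, trial.y_cm, 90.0)
        assert dev.deviation_deg == pytest.approx(30.0, abs=1e-9)

    def test_fixed_seed_reproduces_samples(self):
        cfg = make_cfg(motor_noise_sd_deg=3.0)
        t1 = simulate_reach(90.0, 90.0, cfg, np.random.default_rng(5))
        t2 = simulate_reach(90.0, 90.0, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(t1.x_cm, t2.x_cm)
        np.testing.assert_array_equal(t1.y_cm, t2.y_cm)

    def test_reach_ends_at_target_distance(self):
        cfg = make_cfg(motor_noise_sd_deg=0.0)
        trial = simulate_reach(45.0, 45.0, cfg)
        assert np.hypot(trial.x_cm[-1], trial.y_cm[-1]) == pytest.approx(12.0)

    def test_invalid_sampling_rejected(self):
        with pytest.raises(Exception):
            simulate_reach(90.0, 90.0, make_cfg(reach_duration_s=0.6).replace(sample_rate_hz=1.0))


class TestSimulateLocalization:
    def test_rotated_active_tap_carries_both_shifts(self):
        cfg = make_cfg(afferent_shift_deg=5.6, efferent_shift_deg=2.2, tap_noise_sd_deg=0.0)
        trial = simulate_localization(90.0, "active", "rotated", cfg)
        assert trial.tap_deg == pytest.approx(82.2)

    def test_aligned_tap_is_identity_without_bias(self):
        cfg = make_cfg(tap_noise_sd_deg=0.0)
        trial = simulate_localization(130.0, "passive", "aligned", cfg)
        assert trial.tap_deg == pytest.approx(130.0)

    def test_rotated_passive_tap_carries_afferent_only(self):
        cfg = make_cfg(afferent_shift_deg=5.6, efferent_shift_deg=2.2, tap_noise_sd_deg=0.0)
        trial = simulate_localization(50.0, "passive", "rotated", cfg)
        assert trial.tap_deg == pytest.approx(50.0 - 5.6)

    def test_outside_workspace_rejected(self):
        with pytest.raises(ValueError, match="workspace"):
            simulate_localization(190.0, "active", "aligned", make_cfg())


class TestSimulateCohort:
    def test_counts_and_determinism(self, default_configs, small_cohort, tmp_path):
        counts = small_cohort.questionnaire.groupby("group").size()
        assert (counts == 4).all() and len(counts) == 4
        again = ra.simulate_cohort(default_configs, trajectories=False, seed=7)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        small_cohort.to_csv(d1)
        again.to_csv(d2)
        for name in ("reaches", "localization", "questionnaire"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()

    def test_unaware_arm_equal_cue_means_zero_noise(self, zero_noise_cohort):
        """Without instructions and a small rotation there is no strategy to switch."""
        nc = zero_noise_cohort.reaches.query(
            "group == 'noninstr30' and session == 'rotated' and task == 'nocursor'"
        )
        means = nc.groupby("strategy_cue")["deviation_deg"].mean()
        assert means["with"] == pytest.approx(means["without"], abs=1e-6)

    def test_aware_arm_contrast_equals_explicit_zero_noise(self, zero_noise_cohort):
        cfg = next(c for c in zero_noise_cohort.configs if c.group == "instr30")
        nc = zero_noise_cohort.reaches.query(
            "group == 'instr30' and session == 'rotated' and task == 'nocursor'"
        )
        means = nc.groupby("strategy_cue")["deviation_deg"].mean()
        assert means["with"] - means["without"] == pytest.approx(
            cfg.explicit_deg, abs=1e-4
        )

    def test_awareness_scores_in_closed_set(self, small_cohort):
        assert set(small_cohort.questionnaire["awareness_score"]) <= {0, 1, 3}

    def test_duplicate_group_config_rejected(self):
        cfg = SimulationConfig(rotation_deg=30, instructed=False, n_participants=1)
        with pytest.raises(ValueError, match="duplicate"):
            ra.simulate_cohort([cfg, cfg], trajectories=False)

    def test_trajectory_samples_encode_trial_deviation(self):
        """Deviation recomputed from materialized paths equals the trial table."""
        cfgs = ra.default_study_configs(seed=3, n_per_group=1)[:1]
        cohort = ra.simulate_cohort(cfgs, trajectories=True, seed=3)
        devs = ra.compute_reach_deviations(cohort.samples)
        merged = devs.merge(
            cohort.reaches,
            on=["participant", "session", "block", "task", "strategy_cue", "trial"],
            suffixes=("_path", "_table"),
        )
        assert len(merged) == len(cohort.reaches)
        np.testing.assert_allclose(
            merged["deviation_deg_path"], merged["deviation_deg_table"], atol=1e-9
        )
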