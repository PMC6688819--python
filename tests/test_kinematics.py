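import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reachadapt as ra
from reachadapt.cohort import min_jerk_profile, simulate_reach
from reachadapt.config import SimulationConfig
from reachadapt.kinematics import (
    DegenerateTrialError,
    angular_deviation,
    baseline_biases,
    correct_and_normalize,
    learning_trial_sets,
    peak_velocity_index,
    wrap_angle,
)


def straight_path(direction_deg, n=61, duration=0.6, distance=12.0, profile="minjerk"):
    t = np.linspace(0, duration, n)
    if profile == "minjerk":
        tau = t / duration
        frac = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    else:  # constant speed
        frac = t / duration
    r = distance * frac
    th = np.deg2rad(direction_deg)
    return t, r * np.cos(th), r * np.sin(th)


class TestPeakVelocity:
    def test_minimum_jerk_peaks_at_midpoint(self):
        t, x, y = straight_path(90.0)
        idx = peak_velocity_index(t, x, y)
        assert t[idx] == pytest.approx(0.3, abs=t[1] - t[0])

    def test_constant_speed_tie_breaks_to_first_interior_sample(self):
        t, x, y = straight_path(45.0, profile="constant")
        assert peak_velocity_index(t, x, y) == 1

    def test_inserted_speed_burst_wins(self):
        """A single displaced sample mid-path creates the speed maximum there."""
        t, x, y = straight_path(90.0, profile="constant")
        x = x.copy()
        x[30] += 5.0
        # oracle: brute-force argmax over central differences
        speeds = [
            np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
            for i in range(1, len(t) - 1)
        ]
        expected = 1 + int(np.argmax(speeds))
        assert peak_velocity_index(t, x, y) == expected
        assert expected in (29, 31)  # burst shows up at a neighbour of sample 30

    def test_degenerate_trial_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(DegenerateTrialError):
            peak_velocity_index(t, np.zeros(10), np.zeros(10))


class TestAngularDeviation:
    def test_straight_on_target_reach(self):
        t, x, y = straight_path(90.0)
        assert angular_deviation(t, x, y, 90.0).deviation_deg == pytest.approx(0.0, abs=1e-9)

    def test_full_compensation_of_30deg_cw_rotation(self):
        """Heading 120 deg at a 90 deg target is the +30 deg counter-deviation."""
        t, x, y = straight_path(120.0)
        assert angular_deviation(t, x, y, 90.0).deviation_deg == pytest.approx(30.0)

    def test_wrap_across_zero(self):
        t, x, y = straight_path(10.0)
        assert angular_deviation(t, x, y, 350.0).deviation_deg == pytest.approx(20.0)

    def test_wrap_matches_oracle_on_degree_grid(self):
        grid = np.arange(-360.0, 361.0)
        for a in grid[::7]:
            w = wrap_angle(a)
            # oracle: shift by 360 until in (-180, 180]
            b = float(a)
            while b <= -180.0:
                b += 360.0
            while b > 180.0:
                b -= 360.0
            assert w == pytest.approx(b)
            assert -180.0 < w <= 180.0

    @settings(max_examples=50, deadline=None)
    @given(
        direction=st.floats(-180, 180),
        delta=st.floats(-170, 170),
        scale=st.floats(0.2, 5.0),
    )
    def test_rotation_equivariance_and_duration_invariance(self, direction, delta, scale):
        """Rotating path and target together, or rescaling time, keeps the deviation."""
        t, x, y = straight_path(direction)
        target = direction - delta
        base = angular_deviation(t, x, y, target)
        rot = np.deg2rad(33.0)
        xr = x * np.cos(rot) - y * np.sin(rot)
        yr = x * np.sin(rot) + y * np.cos(rot)
        rotated = angular_deviation(t, xr, yr, target + 33.0)
        assert rotated.deviation_deg == pytest.approx(base.deviation_deg, abs=1e-7)
        stretched = angular_deviation(t * scale, x, y, target)
        assert stretched.peak_index == base.peak_index
        assert stretched.deviation_deg == pytest.approx(base.deviation_deg, abs=1e-9)


class TestBaselineAndNormalization:
    def _devs(self, rows):
        return pd.DataFrame(
            rows, columns=["participant", "trial", "target_deg", "deviation_deg"]
        )

    def test_constant_deviations_give_constant_biases(self):
        rows = [("p1", i + 1, t, 2.0 if t == 45 else -1.0)
                for i, t in enumerate([45, 90, 135] * 3)]
        rows = [(p, i, t, 2.0 if t == 45 else (-1.0 if t == 90 else 0.0))
                for (p, i, t, _) in rows]
        biases = baseline_biases(self._devs(rows))
        b = biases.set_index("target_deg")["bias_deg"]
        assert b[45.0] == pytest.approx(2.0)
        assert b[90.0] == pytest.approx(-1.0)
        assert b[135.0] == pytest.approx(0.0)

    def test_biases_match_groupby_oracle(self, rng):
        rows = []
        for i in range(45):
            t = [45, 90, 135][i % 3]
            rows.append(("p1", i + 1, float(t), float(rng.normal())))
        df = self._devs(rows)
        biases = baseline_biases(df).set_index("target_deg")["bias_deg"]
        oracle = df.groupby("target_deg")["deviation_deg"].mean()
        for t in (45.0, 90.0, 135.0):
            assert biases[t] == pytest.approx(oracle[t], rel=1e-12)

    def test_missing_target_is_named(self):
        rows = [("p1", i + 1, 45.0, 0.0) for i in range(10)]
        with pytest.raises(ValueError, match="90"):
            baseline_biases(self._devs(rows))

    def test_correct_and_normalize_arithmetic(self):
        devs = pd.DataFrame(
            {"participant": ["p1"], "trial": [1], "target_deg": [90.0],
             "deviation_deg": [42.0]}
        )
        biases = pd.DataFrame(
            {"participant": ["p1"] * 3, "target_deg": [45.0, 90.0, 135.0],
             "bias_deg": [0.0, 3.0, 0.0]}
        )
        out = correct_and_normalize(devs, biases, rotation_deg=60.0)
        assert out["corrected_deg"].iloc[0] == pytest.approx(39.0)
        assert out["normalized"].iloc[0] == pytest.approx(0.65)

    def test_full_compensation_normalizes_to_one(self):
        devs = pd.DataFrame(
            {"participant": ["p1"], "trial": [1], "target_deg": [90.0],
             "deviation_deg": [30.0]}
        )
        biases = pd.DataFrame(
            {"participant": ["p1"], "target_deg": [90.0], "bias_deg": [0.0]}
        )
        out = correct_and_normalize(devs, biases, rotation_deg=30.0)
        assert out["normalized"].iloc[0] == pytest.approx(1.0)

    def test_zero_rotation_rejected(self):
        devs = pd.DataFrame(
            {"participant": ["p1"], "trial": [1], "target_deg": [90.0],
             "deviation_deg": [30.0]}
        )
        biases = pd.DataFrame(
            {"participant": ["p1"], "target_deg": [90.0], "bias_deg": [0.0]}
        )
        with pytest.raises(ValueError, match="rotation"):
            correct_and_normalize(devs, biases, rotation_deg=0.0)

    def test_corrected_aligned_deviations_average_to_zero(self, small_cohort):
        """Baseline correction zeroes per-target means over its own window."""
        aligned = small_cohort.reaches.query(
            "session == 'aligned' and task == 'reach_target' and block == 1"
        )
        biases = baseline_biases(aligned)
        corrected = correct_and_normalize(aligned, biases, rotation_deg=30.0)
        per_target = corrected.groupby(["participant", "target_deg"])["corrected_deg"].mean()
        assert np.allclose(per_target, 0.0, atol=1e-10)


class TestTrialSets:
    def _training(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "participant": ["p1"] * n,
                "group": ["g"] * n,
                "trial": np.arange(1, n + 1),
                "corrected_deg": values,
                "normalized": np.asarray(values) / 30.0,
            }
        )

    def test_constant_series_gives_constant_sets(self):
        sets = learning_trial_sets(self._training([0.87 * 30] * 90))
        assert np.allclose(sets["normalized"], 0.87)
        assert sorted(sets["set"]) == ["final", "set1", "set2"]

    def test_windows_are_first3_next3_last9(self):
        values = np.arange(90, dtype=float)
        sets = learning_trial_sets(self._training(values)).set_index("set")
        assert sets.loc["set1", "corrected_deg"] == pytest.approx(np.mean(values[:3]))
        assert sets.loc["set2", "corrected_deg"] == pytest.approx(np.mean(values[3:6]))
        assert sets.loc["final", "corrected_deg"] == pytest.approx(np.mean(values[-9:]))

    def test_only_final_set_sees_late_trials(self):
        base = np.zeros(90)
        changed = base.copy()
        changed[81:] = 5.0
        a = learning_trial_sets(self._training(base)).set_index("set")
        b = learning_trial_sets(self._training(changed)).set_index("set")
        assert a.loc["set1", "corrected_deg"] == b.loc["set1", "corrected_deg"]
        assert a.loc["set2", "corrected_deg"] == b.loc["set2", "corrected_deg"]
        assert b.loc["final", "corrected_deg"] == pytest.approx(5.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="90"):
            learning_trial_sets(self._training([0.0] * 50))


class TestScreening:
    def test_short_movement_and_large_deviation_are_flagged(self):
        cfg = SimulationConfig(motor_noise_sd_deg=0.0)
        good = simulate_reach(90.0, 90.0, cfg)
        frames = []
        for trial_id, (scale, direction) in enumerate(
            [(1.0, 90.0), (0.2, 90.0), (1.0, 200.0)], start=1
        ):
            t, frac = min_jerk_profile(cfg.reach_duration_s, cfg.sample_rate_hz)
            r = 12.0 * frac * scale
            th = np.deg2rad(direction)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": "p1", "session": "aligned", "block": 1,
                        "task": "reach_target", "strategy_cue": "", "trial": trial_id,
                        "target_deg": 90.0, "t_s": t,
                        "x_cm": r * np.cos(th), "y_cm": r * np.sin(th),
                    }
                )
            )
        devs = ra.compute_reach_deviations(pd.concat(frames, ignore_index=True))
        by_trial = devs.set_index("trial")
        assert bool(by_trial.loc[1, "valid"])
        assert by_trial.loc[2, "exclude_reason"] == "short_movement"
        assert by_trial.loc[3, "exclude_reason"] == "large_deviation"
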