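import math

import numpy as np
import pytest

from invbehave import (
    AssayDesign,
    SleepBout,
    ValidationError,
    aggregate_startle,
    arcsin_sqrt,
    baseline_speed,
    binarize_activity,
    detect_sleep_bouts,
    phenotype_fly,
    sleep_minutes_per_hour,
    startle_duration,
    startle_magnitude,
    zone_occupancy,
)

from conftest import brute_force_bouts, make_trajectory


class TestBinarizeActivity:
    def test_stationary_fly_all_inactive(self):
        traj = make_trajectory(np.full(601, 10.0))
        flags = binarize_activity(traj, epsilon_mm=1.0)
        assert len(flags) == 10
        assert not flags.any()

    def test_mover_all_active(self):
        # 5 mm of displacement every minute via a 2.5 mm zig-zag each 30 s
        pos = np.tile([0.0, 2.5], 301)[:601]
        traj = make_trajectory(pos, dt_s=30.0)
        flags = binarize_activity(traj, epsilon_mm=1.0)
        assert flags.all()

    def test_matches_brute_force_minute_sums(self):
        rng = np.random.default_rng(8)
        pos = np.cumsum(rng.normal(0, 0.1, 1201))
        pos -= pos.min()
        traj = make_trajectory(pos)
        flags = binarize_activity(traj, epsilon_mm=1.0)
        for m in range(20):
            seg = pos[m * 60 : (m + 1) * 60 + 1]
            assert flags[m] == (np.sum(np.abs(np.diff(seg))) > 1.0)

    def test_negative_epsilon_rejected(self):
        traj = make_trajectory(np.zeros(121))
        with pytest.raises(ValidationError):
            binarize_activity(traj, epsilon_mm=-0.1)


class TestSleepBouts:
    def test_five_minute_run_is_one_bout(self):
        # "at least five minutes" is inclusive
        flags = [True, True, True, False, False, False, False, False, True, True]
        bouts = detect_sleep_bouts(np.array(flags))
        assert len(bouts) == 1
        assert bouts[0].duration_min == pytest.approx(5.0)
        assert bouts[0].start_s == pytest.approx(180.0)

    def test_all_active_no_bouts(self):
        assert detect_sleep_bouts(np.ones(30, dtype=bool)) == []

    def test_four_minute_run_below_threshold(self):
        flags = np.array([False] * 4 + [True] * 6)
        assert detect_sleep_bouts(flags) == []

    def test_min_bout_below_one_rejected(self):
        with pytest.raises(ValidationError):
            detect_sleep_bouts(np.ones(5, dtype=bool), min_bout_min=0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            flags = rng.random(rng.integers(1, 40)) < 0.5
            got = [
                (int(b.start_s // 60), int(b.end_s // 60))
                for b in detect_sleep_bouts(flags)
            ]
            assert got == brute_force_bouts(flags, 5)


class TestSleepMinutes:
    def test_thirty_bout_minutes_in_two_hours(self):
        bouts = [SleepBout(0.0, 1200.0), SleepBout(3000.0, 3600.0)]
        assert sleep_minutes_per_hour(bouts, 7200.0) == pytest.approx(15.0)

    def test_fully_inactive_hour_is_sixty(self):
        assert sleep_minutes_per_hour([SleepBout(0.0, 3600.0)], 3600.0) == pytest.approx(60.0)

    def test_bout_outside_window_rejected(self):
        with pytest.raises(ValidationError):
            sleep_minutes_per_hour([SleepBout(3000.0, 4000.0)], 3600.0)


class TestBaselineSpeed:
    def test_constant_speed(self):
        pos = np.cumsum(np.full(3701, 2.0))
        traj = make_trajectory(pos - pos[0])
        assert baseline_speed(traj, 3600.0) == pytest.approx(2.0, abs=1e-3)

    def test_half_still_half_moving(self):
        pos = np.concatenate([np.zeros(1801), np.cumsum(np.full(1900, 4.0))])
        traj = make_trajectory(pos)
        # 1800 still steps + 1799 in-window moving steps of 4 mm
        assert baseline_speed(traj, 3600.0) == pytest.approx(2.0, abs=5e-3)

    def test_matches_path_length_oracle(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.normal(0, 1, 3800))
        traj = make_trajectory(pos)
        oracle = np.sum(np.abs(np.diff(pos[:3600]))) / 3600.0
        assert baseline_speed(traj, 3600.0) == pytest.approx(oracle, abs=1e-9)

    def test_insufficient_prestimulus_data_rejected(self):
        traj = make_trajectory(np.zeros(100))
        with pytest.raises(ValidationError):
            baseline_speed(traj, 3600.0)


class TestStartle:
    def _traj_with_post_speeds(self, post_speeds, dt=10.0, pre=5):
        """Trajectory whose derived speeds after the 'stimulus' sample equal
        post_speeds exactly (monotone position ramp)."""
        speeds = np.concatenate([np.zeros(pre), post_speeds])
        pos = np.concatenate([[0.0], np.cumsum(speeds[1:] * dt)])
        return make_trajectory(pos, dt_s=dt), (pre - 1) * dt

    def test_first_crossing_rule_by_hand(self):
        # smoothed post-stimulus speeds 3, 2.5, 2, 1.5, 1.0 on a 10-s grid
        # with baseline 1.0 return at the fifth sample: 50 s
        traj, stim = self._traj_with_post_speeds(
            np.array([3.0, 2.5, 2.0, 1.5, 1.0, 1.0]), dt=10.0
        )
        dur, censored = startle_duration(traj, stim, baseline=1.0, smooth_window_s=10.0)
        assert dur == pytest.approx(50.0)
        assert not censored

    def test_already_below_baseline_is_zero(self):
        traj, stim = self._traj_with_post_speeds(np.array([0.5, 0.4, 0.3, 0.2]))
        dur, censored = startle_duration(traj, stim, baseline=1.0)
        assert dur == 0.0 and not censored

    def test_never_returns_is_censored_at_cap(self):
        traj, stim = self._traj_with_post_speeds(np.full(20, 5.0))
        dur, censored = startle_duration(traj, stim, baseline=1.0, cap_s=100.0)
        assert dur == pytest.approx(100.0)
        assert censored

    def test_negative_baseline_rejected(self):
        traj, stim = self._traj_with_post_speeds(np.full(5, 1.0))
        with pytest.raises(ValidationError):
            startle_duration(traj, stim, baseline=-0.1)

    def test_magnitude_post_minute_minus_baseline(self):
        speeds = np.concatenate([np.zeros(10), np.full(70, 4.0)])
        pos = np.concatenate([[0.0], np.cumsum(speeds[1:])])
        traj = make_trajectory(pos)
        assert startle_magnitude(traj, 10.0, baseline=1.0) == pytest.approx(3.0)

    def test_magnitude_unchanged_speed_is_zero(self):
        pos = np.cumsum(np.full(200, 2.0))
        traj = make_trajectory(pos - pos[0])
        mag = startle_magnitude(traj, 60.0, baseline=2.0)
        assert mag == pytest.approx(0.0, abs=1e-2)

    def test_magnitude_truncated_window_rejected(self):
        traj = make_trajectory(np.zeros(100))
        with pytest.raises(ValidationError):
            startle_magnitude(traj, 60.0, baseline=0.0)

    def test_aggregate(self):
        assert aggregate_startle([10.0, 20.0]) == pytest.approx(15.0)
        assert aggregate_startle([7.5]) == pytest.approx(7.5)
        rng = np.random.default_rng(1)
        vals = rng.exponential(30, 17)
        assert aggregate_startle(list(vals)) == pytest.approx(float(np.mean(vals)))
        with pytest.raises(ValidationError):
            aggregate_startle([])


class TestZoneOccupancy:
    def test_uniform_spread_is_one_eighth_each(self):
        x = np.linspace(0.0, 65.0, 800, endpoint=False)
        props = zone_occupancy(x, 65.0)
        np.testing.assert_allclose(props, 1.0 / 8.0)

    def test_all_at_food_end(self):
        props = zone_occupancy(np.zeros(50), 65.0)
        assert props[0] == 1.0
        assert props[-1] == 0.0

    def test_half_open_convention_at_zone_edge(self):
        # x exactly at L/8 belongs to zone 1, not zone 0; x = L to the last
        L = 65.0
        props = zone_occupancy(np.array([L / 8.0]), L)
        assert props[1] == 1.0
        assert zone_occupancy(np.array([L]), L)[-1] == 1.0

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(2)
        L = 65.0
        x = np.concatenate([rng.uniform(0, L, 500), [0.0, L, L / 8.0, 7 * L / 8.0]])
        props = zone_occupancy(x, L)
        brute = np.zeros(8)
        for xi in x:
            z = 7 if xi == L else int(xi // (L / 8.0))
            brute[z] += 1
        np.testing.assert_allclose(props, brute / len(x))

    def test_invalid_tube_length_rejected(self):
        with pytest.raises(ValidationError):
            zone_occupancy(np.zeros(3), 0.0)


class TestArcsinSqrt:
    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0.0), (1.0, math.pi / 2), (0.5, math.pi / 4)]
    )
    def test_reference_points(self, p, expected):
        assert arcsin_sqrt(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            arcsin_sqrt(1.2)


class TestPhenotypeFly:
    def test_stationary_fly_full_sleep_zero_speed(self, design):
        traj = make_trajectory(np.full(design.n_samples, 5.0))
        rec = phenotype_fly(traj, design)
        assert rec.sleep_min_per_hour == pytest.approx(60.0)
        assert rec.base_speed_mm_s == 0.0
        assert rec.startle_duration_s == 0.0
        assert rec.prop_near_food == 1.0
        assert rec.prop_far_food == 0.0
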