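"""Track metrics: speeds, periods, normalisation, confinement, statistics."""

import numpy as np
import pandas as pd
import pytest

from optoscreen.metrics import (RegionTrajectory, Track, expected_occupancy,
                                instantaneous_speed, larval_length,
                                mean_x_velocity, normalised_metric,
                                period_mean, position_gaussian, prisoner_index,
                                rolling_fraction, t_statistics)
from optoscreen.stimulus import build_colour_sequence, schedule_of


def make_track(times, heads, animal_id="a", **kw):
    return Track(animal_id=animal_id, times_s=np.asarray(times, float),
                 head_mm=np.asarray(heads, float), **kw)


def piecewise_track(speeds_by_period, period_s=60.0, dt=1.0):
    """Straight-line track whose speed is constant within each period."""
    times = [0.0]
    xs = [0.0]
    for speed in speeds_by_period:
        for _ in range(int(period_s / dt)):
            times.append(times[-1] + dt)
            xs.append(xs[-1] + speed * dt)
    return make_track(times, np.column_stack([xs, np.zeros(len(xs))]))


class TestSpeedAndLength:
    def test_stationary_track_has_zero_speed(self):
        tr = make_track([0, 1, 2], [[5, 5]] * 3)
        _, v = instantaneous_speed(tr)
        assert np.all(v == 0)

    def test_three_four_five_displacement(self):
        tr = make_track([0, 1], [[0, 0], [3, 4]])
        _, v = instantaneous_speed(tr)
        assert v[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("n", [6, 12, 48])
    def test_circular_motion_chord_speed(self, n):
        """Sampling a circle of radius r at n points yields chord speed
        n * 2r * sin(pi/n) / T, approaching 2 pi r / T as n grows."""
        r, T = 7.0, 60.0
        ang = 2 * np.pi * np.arange(n + 1) / n
        tr = make_track(T * np.arange(n + 1) / n,
                        np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        _, v = instantaneous_speed(tr)
        assert np.allclose(v, n * 2 * r * np.sin(np.pi / n) / T)

    def test_head_tail_length_and_contraction_scaling(self):
        heads = np.array([[0.0, 0.0], [1.0, 1.0]])
        tails = np.array([[3.0, 4.0], [1.0, 1.0]])
        tr = make_track([0, 1], heads, tail_mm=tails)
        _, length = larval_length(tr)
        assert length[0] == pytest.approx(5.0) and length[1] == 0.0
        shrunk = make_track([0, 1], heads, tail_mm=heads + 0.4 * (tails - heads))
        _, l2 = larval_length(shrunk)
        assert np.allclose(l2, 0.4 * length)

    def test_missing_tail_raises(self):
        with pytest.raises(ValueError, match="tail"):
            larval_length(make_track([0, 1], [[0, 0], [1, 0]]))


class TestPeriodBookkeeping:
    schedule = schedule_of(build_colour_sequence(20, 60, ["red", "green"]))

    def test_piecewise_speeds_recovered_exactly(self):
        """Speeds aligned to period boundaries average to themselves."""
        sched = schedule_of(build_colour_sequence(60, 60, ["red"]))
        tr = piecewise_track([1.0, 0.2, 1.0])  # black, red, black
        pm = period_mean(tr, sched, "speed")
        assert pm["mean_value"].tolist() == pytest.approx([1.0, 0.2, 1.0])
        assert pm["valid"].all()

    def test_constant_speed_in_every_period(self):
        tr = piecewise_track([0.5] * 4, period_s=40)
        sched = schedule_of(build_colour_sequence(20, 60, ["red"]))
        pm = period_mean(tr, sched, "speed")
        assert np.allclose(pm["mean_value"].dropna(), 0.5)

    def test_window_restricts_to_final_seconds(self):
        # 60 s black then 20 s red; speed jumps at t = 58 within the black period
        times = np.arange(0.0, 81.0)
        x = np.concatenate([np.zeros(58), np.cumsum(np.ones(23) * 2.0)])
        tr = make_track(times, np.column_stack([x, np.zeros_like(x)]))
        sched = schedule_of(build_colour_sequence(20, 60, ["red"],
                                                  trailing_black=False))
        pm = period_mean(tr, sched, "speed", window_s=2.0)
        # only intervals [58,59) and [59,60) count for the black period
        assert pm.loc[0, "mean_value"] == pytest.approx(2.0)

    def test_window_equal_to_period_matches_unwindowed(self):
        tr = piecewise_track([0.7, 0.3], period_s=60)
        sched = schedule_of(build_colour_sequence(60, 60, ["red"],
                                                  trailing_black=False))
        full = period_mean(tr, sched, "speed")
        windowed = period_mean(tr, sched, "speed", window_s=60.0)
        pd.testing.assert_frame_equal(full, windowed)

    def test_empty_period_flagged_invalid_not_error(self):
        tr = make_track([0, 1, 2], [[0, 0], [1, 0], [2, 0]])
        pm = period_mean(tr, self.schedule, "speed")
        assert not pm.loc[pm["label"] == "green", "valid"].any()


class TestNormalisedMetric:
    sched = schedule_of(build_colour_sequence(20, 60, ["red"]))

    def test_unchanged_behaviour_gives_unity(self):
        pm = period_mean(piecewise_track([0.5], period_s=140, dt=1.0),
                         self.sched, "speed")
        # constant speed across black and red periods
        norm = normalised_metric(pm)
        assert norm["ratio"].tolist() == pytest.approx([1.0])

    def test_speed_drop_to_half(self):
        sched = schedule_of(build_colour_sequence(60, 60, ["red"]))
        pm = period_mean(piecewise_track([1.0, 0.5, 1.0]), sched, "speed")
        norm = normalised_metric(pm)
        assert norm["ratio"].tolist() == pytest.approx([0.5])

    def test_zero_baseline_flagged_invalid(self):
        sched = schedule_of(build_colour_sequence(60, 60, ["red"]))
        pm = period_mean(piecewise_track([0.0, 0.5, 0.0]), sched, "speed")
        norm = normalised_metric(pm)
        assert not norm["valid"].any()
        assert norm["ratio"].isna().all()

    def test_missing_preceding_black_raises(self):
        p = build_colour_sequence(20, 60, ["red"], initial_black=False)
        pm = period_mean(piecewise_track([0.5], period_s=80), schedule_of(p), "speed")
        with pytest.raises(ValueError, match="black"):
            normalised_metric(pm)

    def test_unit_rescaling_invariance(self):
        """Normalised ratios are unchanged when mm become µm throughout."""
        sched = schedule_of(build_colour_sequence(60, 60, ["red"]))
        tr = piecewise_track([0.8, 0.3, 0.8])
        tr_um = make_track(tr.times_s, tr.head_mm * 1000.0)
        a = normalised_metric(period_mean(tr, sched, "speed"))["ratio"]
        b = normalised_metric(period_mean(tr_um, sched, "speed"))["ratio"]
        assert a.tolist() == pytest.approx(b.tolist())


class TestXVelocity:
    def test_static_and_drift(self):
        static = make_track([0, 10], [[3, 3], [3, 3]])
        assert mean_x_velocity(static) == 0.0
        drift = make_track(np.arange(0, 11.0),
                           np.column_stack([0.17 * np.arange(0, 11.0), np.zeros(11)]))
        assert mean_x_velocity(drift) == pytest.approx(0.17)

    def test_sinusoid_over_whole_periods_is_zero(self):
        t = np.linspace(0, 10, 101)
        tr = make_track(t, np.column_stack([np.sin(2 * np.pi * t / 5), t]))
        assert mean_x_velocity(tr, 0.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_not_rotation_invariant_by_definition(self):
        drift = make_track([0, 10], [[0, 0], [10, 0]])
        rot = make_track([0, 10], [[0, 0], [0, 10]])  # same motion, rotated 90 deg
        assert mean_x_velocity(drift) != mean_x_velocity(rot)


class TestPrisonerIndex:
    def test_always_inside_is_one(self):
        region = RegionTrajectory.disc(8.5, (30, 30))
        tr = make_track([0, 1, 2, 3], [[30, 30], [31, 31], [29, 30], [30, 29]])
        assert prisoner_index(tr, region) == 1.0

    def test_half_time_inside(self):
        region = RegionTrajectory.disc(1.0, (0, 0))
        heads = [[0, 0], [0, 0], [5, 5], [5, 5], [5, 5]]  # inside for 2 of 4 intervals
        tr = make_track([0, 1, 2, 3, 4], heads)
        assert prisoner_index(tr, region) == 0.5

    def test_moving_region_follows_its_centre(self):
        region = RegionTrajectory.disc(1.0, (0, 0), velocity_mm_s=(1.0, 0.0))
        tr = make_track([0, 1, 2], [[0, 0], [1, 0], [10, 0]])
        # head tracks the moving centre for both counted intervals' starts
        assert prisoner_index(tr, region) == pytest.approx(1.0)

    def test_random_tracks_match_brute_force_oracle(self, rng):
        """Index equals an independent per-interval point-in-region count."""
        for _ in range(100):
            n = rng.integers(5, 40)
            times = np.cumsum(rng.uniform(0.5, 2.0, n))
            heads = rng.uniform(-10, 10, (n, 2))
            cx, cy = rng.uniform(-5, 5, 2)
            vx, vy = rng.uniform(-0.5, 0.5, 2)
            r = rng.uniform(1.0, 8.0)
            region = RegionTrajectory.disc(r, (cx, cy), (vx, vy))
            tr = make_track(times, heads)
            # brute force: loop over intervals, test the head at each start
            num = 0.0
            for i in range(n - 1):
                hx, hy = heads[i]
                t = times[i]
                if (hx - cx - vx * t) ** 2 + (hy - cy - vy * t) ** 2 <= r ** 2:
                    num += times[i + 1] - times[i]
            assert prisoner_index(tr, region) == pytest.approx(
                num / (times[-1] - times[0]))

    def test_concatenation_is_duration_weighted_average(self):
        region = RegionTrajectory.disc(2.0, (0, 0))
        times = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 8.0])
        heads = np.array([[0, 0], [3, 0], [1, 1], [5, 5], [0, 1], [9, 9]])
        full = prisoner_index(make_track(times, heads), region)
        k = 3
        a = prisoner_index(make_track(times[:k + 1], heads[:k + 1]), region)
        b = prisoner_index(make_track(times[k:], heads[k:]), region)
        da, db = times[k] - times[0], times[-1] - times[k]
        assert full == pytest.approx((a * da + b * db) / (da + db))

    def test_translation_rotation_invariance(self, rng):
        times = np.arange(20.0)
        heads = rng.uniform(-5, 5, (20, 2))
        region = RegionTrajectory.disc(3.0, (1.0, -2.0))
        base = prisoner_index(make_track(times, heads), region)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        region_rot = RegionTrajectory.disc(3.0, tuple(rot @ [1.0, -2.0]))
        moved = prisoner_index(make_track(times, heads @ rot.T), region_rot)
        assert moved == pytest.approx(base)


class TestExpectedOccupancy:
    def test_degenerate_ratios(self):
        chamber = np.ones((10, 20), bool)
        assert expected_occupancy(chamber, chamber) == 1.0
        half = chamber.copy()
        half[:, 10:] = False
        assert expected_occupancy(half, chamber) == 0.5

    def test_synthetic_maze_matches_pixel_count_oracle(self):
        from optoscreen.simulator import maze_lit_mask

        lit = maze_lit_mask()
        safe = lit == 0
        chamber = np.ones_like(lit, bool)
        # independent count: dark channel is 20 mm of a 64 mm wide chamber
        assert expected_occupancy(safe, chamber) == pytest.approx(
            int(safe.sum()) / safe.size)
        assert expected_occupancy(safe, chamber) == pytest.approx(20 / 64)

    def test_empty_chamber_rejected(self):
        with pytest.raises(ValueError):
            expected_occupancy(np.zeros((4, 4)), np.zeros((4, 4)))


class TestRollingFraction:
    def _tracks(self, flags):
        return [make_track([0, 1, 2], [[0, 0]] * 3,
                           rolling=np.array(f, dtype=bool), animal_id=str(i))
                for i, f in enumerate(flags)]

    def test_counts(self):
        none = rolling_fraction(self._tracks([[0, 0, 0]] * 5))
        assert (none["pct_rolling"] == 0).all()
        all_ = rolling_fraction(self._tracks([[1, 1, 1]] * 5))
        assert (all_["pct_rolling"] == 100).all()
        mixed = rolling_fraction(self._tracks([[1, 0, 0]] * 3 + [[0, 0, 0]] * 7))
        assert mixed["pct_rolling"].tolist() == [30.0, 0.0, 0.0]

    def test_missing_labels_raise(self):
        with pytest.raises(ValueError, match="rolling"):
            rolling_fraction([make_track([0, 1], [[0, 0], [1, 1]])])


class TestPositionGaussian:
    segment = ((0.0, 0.0), (20.0, 0.0))

    def test_parameter_recovery(self, rng):
        xs = rng.normal(10.0, 2.0, 500)
        tr = make_track(np.arange(500.0), np.column_stack([xs, rng.uniform(0, 5, 500)]))
        fit = position_gaussian([tr], self.segment, bin_mm=1.0)
        assert fit.mean_mm == pytest.approx(10.0, abs=0.2)
        assert fit.sd_mm == pytest.approx(2.0, abs=0.2)
        lo, hi = fit.ci95_mm
        assert fit.margin_mm == pytest.approx((lo, 20.0 - hi))

    def test_identical_positions_degenerate(self):
        tr = make_track(np.arange(40.0), np.tile([10.0, 1.0], (40, 1)))
        fit = position_gaussian([tr], self.segment)
        assert fit.degenerate and fit.sd_mm == 0.0

    def test_uniform_interval_wider_than_quantile_range(self, rng):
        """For uniform data 1.96 sd overestimates the central 95% range."""
        xs = rng.uniform(0, 20, 1000)
        tr = make_track(np.arange(1000.0), np.column_stack([xs, np.zeros(1000)]))
        fit = position_gaussian([tr], self.segment)
        lo_q, hi_q = np.quantile(xs, [0.025, 0.975])
        assert (fit.ci95_mm[1] - fit.ci95_mm[0]) > (hi_q - lo_q)


class TestTStatistics:
    def test_symmetric_sample_t_zero(self):
        t, df, p = t_statistics([0.9, 1.1, 0.8, 1.2], 1.0)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_one_sample(self):
        data = np.array([1.2, 1.1, 1.3, 1.2])
        # independent hand formula: t = (xbar - mu) / (s / sqrt(n))
        s = np.sqrt(((data - data.mean()) ** 2).sum() / 3)
        expect = (data.mean() - 1.0) / (s / 2.0)
        t, df, p = t_statistics(data, 1.0)
        assert t == pytest.approx(expect) and df == 3

    def test_two_sample_identical_gives_zero(self):
        t, _, p = t_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="two_sample")
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        t, _, p = t_statistics([2.0, 2.0, 2.0], 1.0)
        assert np.isinf(t) and p == 0.0
        t, _, p = t_statistics([2.0, 2.0, 2.0], 2.0)
        assert t == 0.0 and p == 1.0
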