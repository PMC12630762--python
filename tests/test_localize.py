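"""DOA inversion, association, cross-fix, jackknife CIs, smoothing, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import whaletrack as wt
from whaletrack.localize import (
    TDOASet,
    Track,
    associate_click_trains,
    calibrate_receivers,
    cross_fix,
    estimate_doa,
    jackknife_ci,
    jackknife_localize_batch,
    measure_tdoa,
    plane_wave_tdoas,
    smooth_track,
)
from whaletrack.scene import true_tdoas

C = 1500.0


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestMeasureTdoa:
    def test_integer_shift_of_noise_signal(self, env):
        rng = np.random.default_rng(0)
        s = np.zeros(400)
        s[100:300] = rng.normal(size=200)
        ch = np.stack([s, np.roll(s, 7), np.roll(s, 3), np.roll(s, -2)])
        m = measure_tdoa(ch, env.sample_rate, highpass_cutoff=0.0)
        # channel 2 delayed by 7 samples => tau_12 = t1 - t2 = -70 us
        assert m.tdoas[0] == pytest.approx(-70e-6, abs=1e-7)
        assert m.tdoas[1] == pytest.approx(-30e-6, abs=1e-7)

    def test_identical_channels_give_zero_lags(self, env):
        rng = np.random.default_rng(1)
        s = rng.normal(size=256)
        m = measure_tdoa(np.stack([s] * 4), env.sample_rate, highpass_cutoff=0.0)
        assert np.allclose(m.tdoas, 0.0, atol=1e-9)

    def test_flat_signal_rejected(self, env):
        with pytest.raises(ValueError):
            measure_tdoa(np.zeros((4, 128)), env.sample_rate)

    def test_too_short_window_rejected(self, env):
        with pytest.raises(ValueError):
            measure_tdoa(np.ones((4, 3)), env.sample_rate)

    def test_closure_residual_reported(self, env):
        rng = np.random.default_rng(2)
        s = np.zeros(300)
        s[50:250] = rng.normal(size=200)
        ch = np.stack([s, np.roll(s, 4), np.roll(s, 9), np.roll(s, -5)])
        m = measure_tdoa(ch, env.sample_rate, highpass_cutoff=0.0)
        assert abs(m.closure_residual) < 1e-6


class TestEstimateDoa:
    def test_zenith_source_over_horizontal_base(self, tetra):
        tau = plane_wave_tdoas([0.0, 0.0, -1.0], tetra, C)
        # base phones (1,2,3) are horizontal: their pairwise TDOAs vanish
        assert np.allclose(tau[[0, 1, 3]], 0.0, atol=1e-15)
        est = estimate_doa(TDOASet("A", 0.0, tau), tetra, C)
        assert est.elevation == pytest.approx(90.0)

    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_on_unit_sphere(self, seed):
        tetra = wt.default_array_pair()[0]
        rng = np.random.default_rng(seed)
        u = _unit(rng.normal(size=3))
        est = estimate_doa(TDOASet("A", 0.0, plane_wave_tdoas(u, tetra, C)), tetra, C)
        ang = np.arccos(np.clip(np.dot(est.unit_vector, u), -1, 1))
        assert ang < 1e-6
        assert np.linalg.norm(est.unit_vector) == pytest.approx(1.0, abs=1e-9)

    def test_azimuth_convention_is_compass(self, tetra):
        est = estimate_doa(
            TDOASet("A", 0.0, plane_wave_tdoas([1.0, 0.0, 0.0], tetra, C)), tetra, C)
        assert est.azimuth == pytest.approx(90.0, abs=1e-6)  # east
        assert est.elevation == pytest.approx(0.0, abs=1e-6)

    def test_coplanar_valid_pairs_rejected(self, tetra):
        tau = plane_wave_tdoas([0.0, 0.0, -1.0], tetra, C)
        # keep only pairs among the three horizontal base phones
        valid = np.array([True, True, False, True, False, False])
        with pytest.raises(ValueError):
            estimate_doa(TDOASet("A", 0.0, tau, valid), tetra, C)

    def test_fewer_than_three_valid_pairs_rejected(self, tetra):
        tau = plane_wave_tdoas([1.0, 0.0, 0.0], tetra, C)
        valid = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError):
            estimate_doa(TDOASet("A", 0.0, tau, valid), tetra, C)


class TestAssociateClickTrains:
    def test_offset_train_recovered_at_lag(self):
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(0, 300, 500))
        out = associate_click_trains({"a": base}, {"b": base + 0.7})
        assert len(out) == 1
        ka, kb, lag, peak = out[0]
        assert (ka, kb) == ("a", "b")
        assert lag == pytest.approx(0.7, abs=0.02)
        assert peak > 0.9

    def test_independent_poisson_trains_not_associated(self):
        rng = np.random.default_rng(3)
        rejected = 0
        for _ in range(20):
            a = np.cumsum(rng.exponential(0.4, 1500))
            b = np.cumsum(rng.exponential(0.4, 1500))
            out = associate_click_trains({"a": a}, {"b": b})
            rejected += not out
        assert rejected >= 19

    def test_two_whales_pair_one_to_one(self):
        rng = np.random.default_rng(4)
        w1 = np.sort(rng.uniform(0, 280, 400))
        w2 = np.sort(rng.uniform(320, 600, 400))
        out = associate_click_trains({"a1": w1, "a2": w2},
                                     {"b1": w1 + 0.3, "b2": w2 - 0.2})
        assert sorted((ka, kb) for ka, kb, _, _ in out) == [("a1", "b1"), ("a2", "b2")]

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            associate_click_trains({"a": []}, {"b": [1.0]})


class TestCrossFix:
    OA = np.array([-500.0, 0.0, 1294.0])
    OB = np.array([500.0, 0.0, 1294.0])

    def test_exactly_intersecting_rays(self):
        p = np.array([500.0, 800.0, -1100.0]) + self.OA  # arbitrary offset point
        fix = cross_fix(_unit(p - self.OA), _unit(p - self.OB), self.OA, self.OB)
        assert np.allclose(fix, p, atol=1e-9)

    def test_skew_rays_mutual_perpendicular_midpoint(self):
        # closed-form oracle: rays along x and y, offset 10 in z and 4 in y/x
        o1 = np.array([0.0, -4.0, 0.0])
        d1 = np.array([1.0, 0.0, 0.0])
        o2 = np.array([-3.0, 0.0, 10.0])
        d2 = np.array([0.0, 1.0, 0.0])
        # closest points: (-3, -4, 0) on ray 1 and (-3, -4, 10) on ray 2
        # (shift the origins back so both ray parameters are >= 0)
        fix = cross_fix(d1, d2, o1 - 5 * d1, o2 - 6 * d2)
        assert np.allclose(fix, [-3.0, -4.0, 5.0], atol=1e-9)

    def test_symmetric_in_ray_order(self, rng):
        for _ in range(20):
            p = rng.uniform(-1000, 1000, 3) + np.array([0, 1500.0, 0])
            da = _unit(p - self.OA + rng.normal(0, 1e-3, 3))
            db = _unit(p - self.OB + rng.normal(0, 1e-3, 3))
            f1 = cross_fix(da, db, self.OA, self.OB)
            f2 = cross_fix(db, da, self.OB, self.OA)
            assert np.allclose(f1, f2, atol=1e-9)

    def test_antiparallel_rays_rejected(self):
        with pytest.raises(ValueError):
            cross_fix([1.0, 0, 0], [-1.0, 0, 0], self.OA, self.OB)

    def test_source_behind_array_rejected(self):
        p = np.array([0.0, 1500.0, 500.0])
        with pytest.raises(ValueError):
            cross_fix(_unit(self.OA - p), _unit(p - self.OB), self.OA, self.OB)


class TestJackknife:
    def _sets(self, whale, array_pair, sigma, rng):
        a, b = array_pair
        ta = true_tdoas(whale, a, C)
        tb = true_tdoas(whale, b, C)
        if sigma > 0:
            ta = ta + rng.normal(0, sigma, 6)
            tb = tb + rng.normal(0, sigma, 6)
        return TDOASet("A", 0.0, ta), TDOASet("B", 0.0, tb)

    def test_noiseless_ci_is_zero_with_six_subsets(self, array_pair):
        whale = np.array([0.0, 1280.6, 694.0])
        sa, sb = self._sets(whale, array_pair, 0.0, None)
        pt = jackknife_ci((sa, sb), array_pair, C)
        assert pt.n_jackknife == 6
        assert np.allclose(pt.ci95, 0.0, atol=1e-6)
        # sub-metre plane-wave curvature bias at 1.5 km range, 1 m aperture
        assert np.allclose(pt.position, whale, atol=1.0)

    def test_per_array_strategy_uses_twelve_subsets(self, array_pair):
        whale = np.array([0.0, 1280.6, 694.0])
        sa, sb = self._sets(whale, array_pair, 0.0, None)
        pt = jackknife_ci((sa, sb), array_pair, C, strategy="per_array")
        assert pt.n_jackknife == 12

    def test_ci_width_monotone_in_tdoa_noise(self, array_pair):
        whale = np.array([0.0, 1280.6, 694.0])
        widths = []
        for sigma in (0.0, 1e-6, 5e-6, 10e-6):
            rng = np.random.default_rng(11)
            mean_w = np.mean([
                jackknife_ci(self._sets(whale, array_pair, sigma, rng),
                             array_pair, C).ci95.mean()
                for _ in range(40)
            ])
            widths.append(mean_w)
        assert np.all(np.diff(widths) > 0)


class TestSmoothTrack:
    def test_constant_velocity_recovered_in_interior(self):
        t = np.arange(200.0)
        pos = np.column_stack([1.2 * t, -0.5 * t, 800 + 0.3 * t])
        sm = smooth_track(Track("w", t, pos))
        dev = np.linalg.norm(sm.smoothed_positions[20:-3] - pos[20:-3], axis=1)
        assert dev.max() < 0.1

    def test_noise_reduction_on_simulated_dives(self, flat_bathy):
        ratios = []
        for seed in range(10):
            traj = wt.simulate_dive(wt.DiveConfig(duration_s=1200.0), flat_bathy,
                                    seed=seed)
            rng = np.random.default_rng(900 + seed)
            noisy = traj.positions + rng.normal(0, 20.0, traj.positions.shape)
            tr = Track("w", traj.times, noisy, ci95=np.full_like(noisy, 1.96 * 20))
            sm = smooth_track(tr)
            raw = np.sqrt(np.mean((noisy - traj.positions) ** 2))
            smo = np.sqrt(np.mean((sm.smoothed_positions - traj.positions) ** 2))
            ratios.append(smo / raw)
        assert np.mean(ratios) <= 0.7
        assert max(ratios) <= 0.8

    def test_point_count_preserved(self):
        t = np.arange(50.0)
        pos = np.column_stack([t, t, t + 500])
        sm = smooth_track(Track("w", t, pos))
        assert len(sm) == 50
        assert np.array_equal(sm.positions, pos)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            Track("w", [0.0, 2.0, 1.0], np.zeros((3, 3)))


class TestCalibrateReceivers:
    TRUTH = np.array([[-500.0, 0.0, 1294.0], [500.0, 0.0, 1294.0],
                      [0.0, 400.0, 1290.0]])

    def _ship_circle(self, n=20, r=2000.0):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])

    def _tdoas(self, receivers, ship):
        tt = np.linalg.norm(ship[:, None, :] - receivers[None, :, :], axis=2) / C
        pairs = list(itertools.combinations(range(len(receivers)), 2))
        return np.stack([tt[:, i] - tt[:, j] for i, j in pairs], axis=1)

    def test_recovery_from_offset_guess(self, rng):
        ship = self._ship_circle()
        td = self._tdoas(self.TRUTH, ship)
        guess = self.TRUTH + rng.normal(0, 50 / np.sqrt(3), self.TRUTH.shape)
        pos, rms = calibrate_receivers(ship, td, guess, sound_speed=C)
        assert np.all(np.linalg.norm(pos - self.TRUTH, axis=1) < 1.0)
        assert rms < 1e-9

    def test_truth_guess_is_fixed_point(self):
        ship = self._ship_circle()
        td = self._tdoas(self.TRUTH, ship)
        pos, rms = calibrate_receivers(ship, td, self.TRUTH, sound_speed=C)
        assert np.array_equal(pos, self.TRUTH)
        assert rms == 0.0

    def test_collinear_ship_track_rejected(self):
        ship = np.column_stack([np.linspace(-2000, 2000, 10),
                                np.linspace(-2000, 2000, 10), np.zeros(10)])
        td = self._tdoas(self.TRUTH, ship)
        with pytest.raises(ValueError, match="collinear"):
            calibrate_receivers(ship, td, self.TRUTH, sound_speed=C)


class TestEndToEndLocalization:
    def test_median_error_under_jitter(self, array_pair):
        # simulated whale 1.5 km from both arrays, 10 us TDOA jitter, 500 clicks
        whale = np.array([0.0, 1280.6, 694.0])
        a, b = array_pair
        rng = np.random.default_rng(21)
        ta = true_tdoas(whale, a, C)[None, :] + rng.normal(0, 10e-6, (500, 6))
        tb = true_tdoas(whale, b, C)[None, :] + rng.normal(0, 10e-6, (500, 6))
        pos, _, _ = jackknife_localize_batch(ta, tb, a, b, C)
        err = np.linalg.norm(pos - whale[None, :], axis=1)
        assert np.median(err) < 50.0
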