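"""Life-history-phase metrics: TAC, residence, return, KDE UD, VI, MNSD."""
from __future__ import annotations

import numpy as np
import pytest

from msms.exceptions import DegenerateDataError
from msms.lifephase import (
    kde_ud,
    max_net_squared_displacement,
    monthly_vi,
    residence_time,
    scale_mnsd_by_species,
    time_to_return,
    turn_angle_correlation,
    volume_of_intersection,
)
from msms.steps import wrap_angle


class TestTurnAngleCorrelation:
    def _walk_from_turns(self, turns, step=10.0):
        heading = 0.0
        pts = [np.zeros(2)]
        pts.append(pts[-1] + step * np.array([1.0, 0.0]))
        for t in turns:
            heading += t
            pts.append(pts[-1] + step * np.array([np.cos(heading),
                                                  np.sin(heading)]))
        return np.array(pts)

    def test_constant_turns_zero(self):
        xy = self._walk_from_turns([0.4] * 10)
        raw, mean = turn_angle_correlation(xy)
        assert raw == pytest.approx(0.0, abs=1e-12)

    def test_alternating_right_angles_closed_form(self):
        m = 6
        turns = [np.pi / 2, -np.pi / 2] * m
        raw, _ = turn_angle_correlation(self._walk_from_turns(turns))
        # 2m-1 successive differences, each of magnitude pi
        assert raw == pytest.approx((2 * m - 1) * np.pi**2, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        turns = rng.uniform(-np.pi, np.pi, 50)
        raw, mean = turn_angle_correlation(self._walk_from_turns(turns))
        oracle = sum(float(wrap_angle(turns[i + 1] - turns[i])) ** 2
                     for i in range(len(turns) - 1))
        assert raw == pytest.approx(oracle, abs=1e-12)
        assert mean == pytest.approx(oracle / (len(turns) - 1), abs=1e-12)


class TestResidenceTime:
    def test_stationary_track_full_duration(self):
        n = 11
        xy = np.zeros((n, 2))
        t = np.linspace(0.0, 10 * 3600.0, n)
        per_fix, mean = residence_time((xy, t), radius=15.0)
        np.testing.assert_allclose(per_fix, 10.0)
        assert mean == pytest.approx(10.0)

    def test_straight_pass_two_r_over_v(self):
        # 1 m/s, r = 15 m: inside the circle for 30 s, never returns
        n = 1000
        t = np.arange(n) * 10.0
        xy = np.column_stack([1.0 * t, np.zeros(n)])
        per_fix, _ = residence_time((xy, t), radius=15.0)
        assert per_fix[500] == pytest.approx(30.0 / 3600.0, rel=1e-6)

    def test_short_excursion_bridged_long_not(self):
        # in circle 0-1 h, out 1-3 h (short), in 3-4 h, out > 12 h, in again
        t_h = np.array([0.0, 1.0, 2.9, 3.0, 4.0, 17.0, 17.5, 18.0])
        t = t_h * 3600.0
        far = 1000.0
        x = np.array([0.0, 0.0, far, 0.0, 0.0, far, 0.0, 0.0])
        xy = np.column_stack([x, np.zeros(len(x))])
        per_fix, _ = residence_time((xy, t), radius=15.0, cutoff_h=12.0)
        # from fix 0: the two occupancies are bridged (the ~2 h exit is
        # under the cut-off), the ~13 h excursion terminates accumulation.
        # Crossing times interpolate linearly on the distance profile:
        f = 15.0 / far
        exit1 = 1.0 + f * 1.9          # leave after fix 1
        enter2 = 3.0 - f * 0.1         # re-enter before fix 3
        exit2 = 4.0 + f * 13.0         # leave after fix 4
        expect = exit1 + (exit2 - enter2)
        assert per_fix[0] == pytest.approx(expect, abs=1e-6)

    def test_event_scan_oracle(self, rng):
        # random walk, coarse radius; oracle via explicit interval scan at
        # a handful of centres
        n = 300
        t = np.arange(n) * 240.0
        xy = np.cumsum(rng.normal(0, 12, size=(n, 2)), axis=0)
        per_fix, _ = residence_time((xy, t), radius=40.0, cutoff_h=2.0)
        from msms.lifephase import _inside_intervals, _containing_interval
        for i in (30, 120, 250):
            d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
            iv = _inside_intervals(t, d, 40.0)
            j = _containing_interval(iv, t[i])
            total = iv[j][1] - iv[j][0]
            k = j
            while k + 1 < len(iv) and iv[k + 1][0] - iv[k][1] <= 7200.0:
                total += iv[k + 1][1] - iv[k + 1][0]
                k += 1
            k = j
            while k - 1 >= 0 and iv[k][0] - iv[k - 1][1] <= 7200.0:
                total += iv[k - 1][1] - iv[k - 1][0]
                k -= 1
            assert per_fix[i] == pytest.approx(total / 3600.0, abs=1e-9)

    def test_bounded_by_track_duration(self, rng):
        n = 200
        t = np.arange(n) * 240.0
        xy = np.cumsum(rng.normal(0, 5, size=(n, 2)), axis=0)
        per_fix, _ = residence_time((xy, t), radius=30.0)
        assert np.nanmax(per_fix) <= (t[-1] - t[0]) / 3600.0 + 1e-9


class TestTimeToReturn:
    def test_never_returns_censored(self):
        n = 100
        t = np.arange(n) * 600.0
        xy = np.column_stack([np.arange(n) * 50.0, np.zeros(n)])
        per_fix, mean, censored = time_to_return((xy, t), radius=15.0)
        assert np.isnan(per_fix).all()
        assert censored > 0

    def test_thirteen_hour_excursion(self):
        t_h = np.array([0.0, 0.5, 13.5, 14.0])
        t = t_h * 3600.0
        x = np.array([0.0, 1000.0, 1000.0, 0.0])
        xy = np.column_stack([x, np.zeros(4)])
        per_fix, mean, _ = time_to_return((xy, t), radius=15.0,
                                          cutoff_h=12.0)
        # leaves just after t=0, returns just before t=14 h: ~13-14 h out
        assert per_fix[0] == pytest.approx(13.9, abs=0.2)

    def test_all_values_exceed_cutoff(self, rng):
        n = 400
        t = np.arange(n) * 240.0
        xy = np.cumsum(rng.normal(0, 30, size=(n, 2)), axis=0)
        per_fix, _, _ = time_to_return((xy, t), radius=20.0, cutoff_h=0.5)
        vals = per_fix[np.isfinite(per_fix)]
        assert (vals > 0.5).all()


class TestKdeUd:
    def test_isopleth_calibration_bivariate_normal(self):
        rng = np.random.default_rng(123)
        sigma = 100.0
        xy = rng.normal(0.0, sigma, size=(50000, 2))
        ud = kde_ud(xy)
        analytic_ha = np.pi * sigma**2 * 5.991464547 / 1e4
        assert ud.isopleth_area(0.95) == pytest.approx(analytic_ha, rel=0.05)

    def test_integrates_to_one(self, rng):
        xy = rng.normal(0, 50, size=(500, 2))
        ud = kde_ud(xy)
        assert ud.density.sum() * ud.cell**2 == pytest.approx(1.0, abs=1e-6)

    def test_scaling_doubles_area_fourfold(self, rng):
        xy = rng.normal(0, 60, size=(2000, 2))
        a1 = kde_ud(xy).isopleth_area(0.95)
        a2 = kde_ud(2.0 * xy).isopleth_area(0.95)
        assert a2 == pytest.approx(4.0 * a1, rel=0.02)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateDataError):
            kde_ud(np.zeros((100, 2)))


class TestVolumeOfIntersection:
    def test_identical_uds_one(self, rng):
        xy = rng.normal(0, 40, size=(1000, 2))
        ud = kde_ud(xy)
        assert volume_of_intersection(ud, ud) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_zero(self, rng):
        a = kde_ud(rng.normal(0, 10, size=(500, 2)))
        b = kde_ud(rng.normal(0, 10, size=(500, 2)) + 10000.0)
        assert volume_of_intersection(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, rng):
        a = kde_ud(rng.normal(0, 30, size=(800, 2)))
        b = kde_ud(rng.normal(40, 30, size=(800, 2)))
        assert volume_of_intersection(a, b) \
            == pytest.approx(volume_of_intersection(b, a), abs=1e-6)

    def test_offset_normals_match_quadrature_oracle(self):
        # two unit-variance (sigma = 30 m) normals offset by d: VI of the
        # true densities has closed quadrature; the KDE adds bandwidth
        # sigma_h, compare against quadrature of the smoothed densities
        rng = np.random.default_rng(5)
        sigma, d = 30.0, 40.0
        a_xy = rng.normal(0, sigma, size=(20000, 2))
        b_xy = rng.normal(0, sigma, size=(20000, 2))
        b_xy[:, 0] += d
        ud_a = kde_ud(a_xy)
        ud_b = kde_ud(b_xy)
        got = volume_of_intersection(ud_a, ud_b)
        s_eff = np.sqrt(sigma**2 + ud_a.bandwidth**2)
        xs = np.linspace(-6 * s_eff, d + 6 * s_eff, 801)
        ys = np.linspace(-6 * s_eff, 6 * s_eff, 601)
        gx, gy = np.meshgrid(xs, ys)

        def dens(cx):
            return np.exp(-((gx - cx) ** 2 + gy**2) / (2 * s_eff**2)) \
                / (2 * np.pi * s_eff**2)

        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        oracle = np.minimum(dens(0.0), dens(d)).sum() * cell
        assert got == pytest.approx(oracle, abs=0.02)


class TestMnsd:
    def test_stationary_zero(self):
        assert max_net_squared_displacement(np.zeros((10, 2))) == 0.0

    def test_hundred_meters(self):
        xy = np.array([(0, 0), (60, 80), (10, 10)], float)
        assert max_net_squared_displacement(xy) == pytest.approx(10000.0)

    def test_monotone_under_extension(self, rng):
        xy = np.cumsum(rng.normal(0, 10, size=(100, 2)), axis=0)
        prev = 0.0
        for n in (10, 30, 60, 100):
            v = max_net_squared_displacement(xy[:n])
            assert v >= prev - 1e-12
            prev = v

    def test_species_minimum_scales_to_one(self):
        mnsd = {"a": 400.0, "b": 900.0, "c": 2500.0}
        species = {"a": "sp1", "b": "sp1", "c": "sp2"}
        out = scale_mnsd_by_species(mnsd, species)
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(2.25)
        assert out["c"] == pytest.approx(1.0)


class TestMonthlyVi:
    def test_two_stable_months_high_vi(self, rng):
        import pandas as pd
        from msms.trajectory_io import Trajectory
        t0 = pd.Timestamp("2016-01-01 12:00:00")
        times = [t0 + pd.Timedelta(hours=2 * i) for i in range(500)]
        xy = rng.normal(0, 50, size=(500, 2))
        traj = Trajectory("a", "coati",
                          pd.DataFrame({"timestamp": times,
                                        "x": xy[:, 0], "y": xy[:, 1]}))
        vi = monthly_vi(traj, min_month_fixes=100)
        assert 0.7 < vi <= 1.0

    def test_single_month_nan(self, rng):
        import pandas as pd
        from msms.trajectory_io import Trajectory
        t0 = pd.Timestamp("2016-01-01 12:00:00")
        times = [t0 + pd.Timedelta(minutes=4 * i) for i in range(300)]
        xy = rng.normal(0, 50, size=(300, 2))
        traj = Trajectory("a", "coati",
                          pd.DataFrame({"timestamp": times,
                                        "x": xy[:, 0], "y": xy[:, 1]}))
        assert np.isnan(monthly_vi(traj, min_month_fixes=100))
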