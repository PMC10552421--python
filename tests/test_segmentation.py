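"""FPT behaviour classification, CVM fitting, and edge-label imputation."""
from __future__ import annotations

import numpy as np
import pytest

from msms.segmentation import (
    ARS,
    CLUSTER,
    CvmParams,
    TRAVEL,
    classify_fpt,
    first_passage_time,
    fit_cvm,
    fpt_records,
    impute_edge_labels,
    segment_path,
)


def straight_track(v=1.0, dt=60.0, n=121):
    """Constant-velocity track along x at v m/s with dt-second fixes."""
    t = np.arange(n) * dt
    xy = np.column_stack([v * t, np.zeros(n)])
    return xy, t


class TestFirstPassageTime:
    def test_stationary_censored_at_duration(self):
        xy = np.zeros((11, 2))
        t = np.arange(11) * 240.0
        fpt, cens = first_passage_time(xy, 15.0, 5, times_s=t)
        assert cens
        assert fpt == pytest.approx(2400.0)

    def test_constant_velocity_two_r_over_v(self):
        xy, t = straight_track(v=1.0, dt=10.0, n=100)
        fpt, cens = first_passage_time(xy, 15.0, 50, times_s=t)
        assert not cens
        assert fpt == pytest.approx(30.0)   # 2 r / v

    def test_matches_fine_grid_oracle(self, rng):
        # random walk; oracle: resample at 1 s by linear interpolation and
        # scan for the first exit on the dense grid
        n = 500
        dt = 60.0
        xy = np.cumsum(rng.normal(0, 8, size=(n, 2)), axis=0)
        t = np.arange(n) * dt
        tt = np.arange(0.0, t[-1] + 0.5, 1.0)
        dense = np.column_stack([np.interp(tt, t, xy[:, 0]),
                                 np.interp(tt, t, xy[:, 1])])
        for idx in rng.choice(np.arange(50, n - 50), size=20, replace=False):
            radius = 25.0
            got, cens = first_passage_time(xy, radius, int(idx), times_s=t)
            d = np.hypot(dense[:, 0] - xy[idx, 0], dense[:, 1] - xy[idx, 1])
            i0 = int(idx * dt)
            fw = np.flatnonzero(d[i0 + 1:] > radius)
            fw_t = fw[0] + 1 if len(fw) else len(tt) - 1 - i0
            bw = np.flatnonzero(d[:i0][::-1] > radius)
            bw_t = bw[0] + 1 if len(bw) else i0
            oracle = fw_t + bw_t
            assert got == pytest.approx(oracle, abs=dt)

    def test_monotone_in_radius(self, rng):
        xy = np.cumsum(rng.normal(0, 5, size=(200, 2)), axis=0)
        t = np.arange(200) * 240.0
        for idx in (50, 100, 150):
            prev = -np.inf
            for r in (5.0, 10.0, 20.0, 40.0):
                fpt, _ = first_passage_time(xy, r, idx, times_s=t)
                assert fpt >= prev - 1e-9
                prev = fpt

    def test_fpt30_at_least_fpt15(self, separated_study):
        traj, _ = separated_study
        from msms.trajectory_io import select_burst_last_fix, \
            assemble_daily_paths
        path = assemble_daily_paths(select_burst_last_fix(traj))[0]
        for r in fpt_records(path)[:50]:
            if not (r.censored15 or r.censored30):
                assert r.fpt30 >= r.fpt15 - 1e-9


class TestClassifyFpt:
    def test_slow_wiggle_is_cluster(self):
        # stays within ~10 m of home for the whole 12-min-plus track
        xy = 5.0 * np.column_stack([np.sin(np.arange(40.0)),
                                    np.cos(np.arange(40.0) * 0.7)])
        t = np.arange(40) * 240.0
        labels, _ = classify_fpt((xy, t))
        assert all(l == CLUSTER for l in labels[10:30])

    def test_steady_drift_is_ars(self):
        # exits the 15 m circle inside the window but not the 30 m one
        xy, t = straight_track(v=0.0625, dt=240.0, n=40)  # 15 m per fix
        labels, recs = classify_fpt((xy, t))
        i = 20
        assert recs[i].fpt15 < 720.0 <= recs[i].fpt30
        assert labels[i] == ARS

    def test_fast_travel(self):
        xy, t = straight_track(v=1.0, dt=240.0, n=40)
        labels, _ = classify_fpt((xy, t))
        assert labels[20] == TRAVEL

    def test_edge_fixes_left_unlabeled(self):
        # 3-fix stationary snippet: every window truncated before 720 s
        xy = np.column_stack([np.arange(3) * 2.0, np.zeros(3)])
        labels, _ = classify_fpt((xy, np.arange(3) * 240.0))
        assert all(l is None for l in labels)

    def test_tight_neighborhood_is_cluster(self, rng):
        # any fix whose full 12-min neighborhood fits in a 7.5 m ball
        xy = np.cumsum(rng.normal(0, 30, size=(60, 2)), axis=0)
        xy[25:32] = xy[25] + rng.uniform(-3.0, 3.0, size=(7, 2))  # tight knot
        t = np.arange(60) * 240.0
        labels, _ = classify_fpt((xy, t))
        # fixes 27..29 have their whole +/- 720 s window inside the knot
        for i in (27, 28, 29):
            assert labels[i] == CLUSTER


class TestFitCvm:
    @staticmethod
    def simulate_cvm(eta, tau, n, dt, rng):
        """Exact discrete-time simulation of the integrated OU velocity."""
        sv = eta / np.sqrt(2.0)
        x = dt / tau
        phi = np.exp(-x)
        q11 = sv**2 * tau**2 * (2 * x - 3 + 4 * np.exp(-x) - np.exp(-2 * x))
        q12 = sv**2 * tau * (1 - phi) ** 2
        q22 = sv**2 * (1 - phi**2)
        L = np.linalg.cholesky(np.array([[q11, q12], [q12, q22]])
                               + 1e-15 * np.eye(2))
        pos = np.zeros((n, 2))
        vel = rng.normal(0, sv, 2)
        for k in range(1, n):
            for d in range(2):
                e = L @ rng.normal(size=2)
                pos[k, d] = pos[k - 1, d] + tau * (1 - phi) * vel[d] + e[0]
                vel[d] = phi * vel[d] + e[1]
        return pos

    def test_simulation_recovery(self, rng):
        etas, taus = [], []
        for _ in range(30):
            xy = self.simulate_cvm(0.5, 300.0, 200, 240.0, rng)
            p = fit_cvm(xy, times_s=np.arange(200) * 240.0)
            assert p.converged
            etas.append(p.eta)
            taus.append(p.tau)
        assert np.median(etas) == pytest.approx(0.5, rel=0.10)
        assert np.median(taus) == pytest.approx(300.0, rel=0.25)

    def test_stationary_with_jitter_tiny_eta(self, rng):
        xy = rng.normal(0, 0.05, size=(50, 2))
        p = fit_cvm(xy, times_s=np.arange(50) * 240.0)
        assert p.eta < 0.01

    def test_scaling_property(self, rng):
        xy = self.simulate_cvm(0.3, 600.0, 150, 240.0, rng)
        t = np.arange(150) * 240.0
        a = fit_cvm(xy, times_s=t)
        b = fit_cvm(2.0 * xy, times_s=t)
        assert b.eta == pytest.approx(2.0 * a.eta, rel=1e-3)
        assert b.tau == pytest.approx(a.tau, rel=1e-3)

    def test_too_few_fixes_flagged(self):
        p = fit_cvm(np.zeros((4, 2)), times_s=np.arange(4.0))
        assert not p.converged


class TestImputeEdgeLabels:
    def _params(self, etas, taus=None):
        taus = taus if taus is not None else [300.0] * len(etas)
        return {i: CvmParams(e, t, 31)
                for i, (e, t) in enumerate(zip(etas, taus))}

    def test_three_separated_groups_map_by_eta(self, rng):
        etas = ([0.01 * np.exp(rng.normal(0, 0.1)) for _ in range(10)]
                + [0.1 * np.exp(rng.normal(0, 0.1)) for _ in range(10)]
                + [1.0 * np.exp(rng.normal(0, 0.1)) for _ in range(10)])
        out = impute_edge_labels(self._params(etas))
        assert all(out[i] == CLUSTER for i in range(10))
        assert all(out[i] == ARS for i in range(10, 20))
        assert all(out[i] == TRAVEL for i in range(20, 30))

    def test_identical_records_single_cluster_warns(self):
        with pytest.warns(UserWarning):
            out = impute_edge_labels(self._params([0.2] * 5))
        assert len(out) == 5
        assert len(set(out.values())) == 1

    def test_matches_brute_force_ward_oracle(self, rng):
        # 300 records; oracle: naive O(n^3) Ward agglomeration (Lance-
        # Williams) run to 3 clusters
        z = np.vstack([rng.normal([-2, 0], 0.3, size=(100, 2)),
                       rng.normal([0, 1], 0.3, size=(100, 2)),
                       rng.normal([2.5, -1], 0.3, size=(100, 2))])
        etas = np.exp(z[:, 0])
        taus = np.exp(z[:, 1])
        out = impute_edge_labels(self._params(etas, taus))

        # brute-force Ward on the standardized log features
        feats = np.column_stack([np.log(etas), np.log(taus)])
        feats = (feats - feats.mean(0)) / feats.std(0)
        clusters = [[i] for i in range(len(feats))]
        centroids = [feats[i].copy() for i in range(len(feats))]
        sizes = [1] * len(feats)
        while len(clusters) > 3:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d2 = np.sum((centroids[a] - centroids[b]) ** 2)
                    cost = sizes[a] * sizes[b] / (sizes[a] + sizes[b]) * d2
                    if best is None or cost < best[0]:
                        best = (cost, a, b)
            _, a, b = best
            new = clusters[a] + clusters[b]
            cen = (sizes[a] * centroids[a] + sizes[b] * centroids[b]) \
                / (sizes[a] + sizes[b])
            for idx in sorted((a, b), reverse=True):
                del clusters[idx], centroids[idx], sizes[idx]
            clusters.append(new)
            centroids.append(cen)
            sizes.append(len(new))
        oracle_sets = [frozenset(c) for c in clusters]
        got_sets = [frozenset(i for i, l in out.items() if l == lab)
                    for lab in (CLUSTER, ARS, TRAVEL)]
        assert set(got_sets) == set(oracle_sets)

    def test_fallback_nearest_labeled_neighbor(self):
        unl = self._params([0.05, 0.8])
        labeled = {10: (CvmParams(0.04, 300.0, 31), CLUSTER),
                   11: (CvmParams(1.0, 300.0, 31), TRAVEL)}
        out = impute_edge_labels(unl, labeled=labeled)
        assert out[0] == CLUSTER
        assert out[1] == TRAVEL


class TestSegmentPath:
    def test_label_completeness(self, separated_study):
        traj, _ = separated_study
        from msms.trajectory_io import select_burst_last_fix, \
            assemble_daily_paths
        path = assemble_daily_paths(select_burst_last_fix(traj))[0]
        labels, basis = segment_path(path)
        assert len(labels) == path.n_fixes
        assert all(l in (CLUSTER, ARS, TRAVEL) for l in labels)
        assert all(b in ("FPT", "CVM_CLUSTER") for b in basis)

    def test_state_recovery_balanced_accuracy(self, separated_study):
        traj, truth = separated_study
        from msms.trajectory_io import select_burst_last_fix, \
            assemble_daily_paths
        t = select_burst_last_fix(traj)
        true_state = dict(zip(truth.per_fix["timestamp"],
                              truth.per_fix["state"]))
        conf: dict = {}
        for path in assemble_daily_paths(t):
            labels, _ = classify_fpt(path)
            for ts, lab in zip(path.fixes["timestamp"], labels):
                if lab is not None:
                    key = (true_state[ts], lab)
                    conf[key] = conf.get(key, 0) + 1
        recalls = []
        for s in (CLUSTER, ARS, TRAVEL):
            tot = sum(conf.get((s, l), 0) for l in (CLUSTER, ARS, TRAVEL))
            recalls.append(conf.get((s, s), 0) / tot)
        assert np.mean(recalls) > 0.8
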