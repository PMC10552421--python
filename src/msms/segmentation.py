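"""Behavioural segmentation: cluster / ARS / travel labels per fix.

Primary rule: first passage time (FPT).  Centred on each fix, the time the
trajectory spends inside circles of radius 15 m and 30 m decides the label
for a 12-min feeding-bout window — net movement under 15 m is a (feeding/
resting) cluster, 15-30 m is area-restricted search, beyond 30 m is
travel.  Fixes near the start or end of a daily path, where the window is
truncated before the circle is exited, cannot be classified by FPT; for
those we fit a correlated-velocity model (CVM: Ornstein-Uhlenbeck
velocity) in a sliding window and impute labels by Ward clustering of
(log eta, log tau) — eta the root-mean-squared speed, tau the velocity
autocorrelation timescale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar

from .trajectory_io import DailyPath, Trajectory

CLUSTER = "CLUSTER"
ARS = "ARS"
TRAVEL = "TRAVEL"

BASIS_FPT = "FPT"
BASIS_CVM = "CVM_CLUSTER"

#: FPT radii (m) and window (s): < 15 m in 12 min = cluster, 15-30 m = ARS
RADIUS_CLUSTER_M = 15.0
RADIUS_ARS_M = 30.0
WINDOW_S = 720.0

#: sliding CVM window: 31 four-minute fixes (~2 h), shrinking at edges
CVM_WINDOW_N = 31
CVM_MIN_N = 8


def _coords(track) -> tuple[np.ndarray, np.ndarray]:
    """(xy, seconds) from a Trajectory/DailyPath, an (xy, times) pair, or a
    bare coordinate array (then unit-spaced times)."""
    if isinstance(track, (Trajectory, DailyPath)):
        return track.xy(), track.times_s()
    if isinstance(track, tuple) and len(track) == 2:
        return (np.asarray(track[0], dtype=float),
                np.asarray(track[1], dtype=float))
    xy = np.asarray(track, dtype=float)
    return xy, np.arange(len(xy), dtype=float)


# ---------------------------------------------------------------------------
# first passage time

@dataclass
class FptRecord:
    """First passage times (s) at the two diagnostic radii for one fix."""

    fpt15: float
    fpt30: float
    censored15: bool
    censored30: bool


def first_passage_time(track, radius: float, index: int,
                       times_s: np.ndarray | None = None
                       ) -> tuple[float, bool]:
    """Time for the track to first leave a circle centred on fix ``index``.

    Scans backward and forward from the fix; each one-sided passage time is
    linearly interpolated between the last inside and first outside fix,
    and the two sides are summed.  If the track starts or ends inside the
    circle the value is censored (a lower bound) on that side.
    """
    xy, t = _coords(track)
    if times_s is not None:
        t = np.asarray(times_s, dtype=float)
    d = np.hypot(xy[:, 0] - xy[index, 0], xy[:, 1] - xy[index, 1])
    return _fpt_from_distances(d, t, index, radius)


def _fpt_from_distances(d: np.ndarray, t: np.ndarray, index: int,
                        radius: float) -> tuple[float, bool]:
    n = len(d)
    censored = False
    # forward
    out = np.flatnonzero(d[index + 1:] > radius)
    if len(out):
        j = index + 1 + out[0]
        frac = (radius - d[j - 1]) / (d[j] - d[j - 1])
        forward = (t[j - 1] - t[index]) + frac * (t[j] - t[j - 1])
    else:
        forward = t[n - 1] - t[index]
        censored = True
    # backward
    out = np.flatnonzero(d[:index][::-1] > radius)
    if len(out):
        j = index - 1 - out[0]
        frac = (radius - d[j + 1]) / (d[j] - d[j + 1])
        backward = (t[index] - t[j + 1]) + frac * (t[j + 1] - t[j])
    else:
        backward = t[index] - t[0]
        censored = True
    return float(forward + backward), censored


def fpt_records(track) -> list[FptRecord]:
    """FPT at 15 m and 30 m for every fix of the track."""
    xy, t = _coords(track)
    records = []
    for i in range(len(xy)):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        f15, c15 = _fpt_from_distances(d, t, i, RADIUS_CLUSTER_M)
        f30, c30 = _fpt_from_distances(d, t, i, RADIUS_ARS_M)
        records.append(FptRecord(f15, f30, c15, c30))
    return records


def classify_fpt(track, window_s: float = WINDOW_S
                 ) -> tuple[np.ndarray, list[FptRecord]]:
    """Label each fix CLUSTER / ARS / TRAVEL from its FPT, where decidable.

    CLUSTER iff the 15-m circle is occupied for at least the window
    (censored occupancy of at least the window still qualifies); else ARS
    by the same rule at 30 m; else TRAVEL when the 30-m exit is observed
    inside the window.  Fixes whose window is truncated by the path edge
    before a decisive exit stay None for CVM imputation.

    Returns (labels object array with None where undecidable, records).
    """
    records = fpt_records(track)
    labels = np.full(len(records), None, dtype=object)
    for i, r in enumerate(records):
        if r.fpt15 >= window_s:
            labels[i] = CLUSTER
        elif r.censored15 and r.fpt15 < window_s:
            labels[i] = None       # truncated before decision
        elif r.fpt30 >= window_s:
            labels[i] = ARS
        elif r.censored30 and r.fpt30 < window_s:
            labels[i] = None
        else:
            labels[i] = TRAVEL
    return labels, records


# ---------------------------------------------------------------------------
# correlated velocity model (OU velocity), Kalman-filter likelihood

@dataclass
class CvmParams:
    """Correlated-velocity-model parameters for one window of fixes."""

    eta: float        # rms speed, m/s
    tau: float        # velocity autocorrelation timescale, s
    window_n: int
    loglik: float = np.nan
    converged: bool = True


def _iou_blocks(dt: np.ndarray, tau: float):
    """Per-step transition and unit-variance process noise of the
    integrated OU velocity model (per coordinate, sigma_v^2 factored out)."""
    x = dt / tau
    phi = np.exp(-x)
    a12 = tau * (-np.expm1(-x))                 # position gain from velocity
    q22 = -np.expm1(-2.0 * x)                   # 1 - phi^2
    q12 = tau * np.expm1(-x) ** 2               # tau (1-phi)^2
    g = np.where(
        x < 1e-2,
        (2.0 / 3.0) * x**3 - 0.5 * x**4 + (7.0 / 30.0) * x**5,
        2.0 * x - 3.0 + 4.0 * np.exp(-x) - np.exp(-2.0 * x),
    )
    q11 = tau * tau * g
    return phi, a12, q11, q12, q22


def _cvm_profile(log_tau: float, xy: np.ndarray, dt: np.ndarray):
    """Profile negative log-likelihood over tau; sigma_v^2 concentrated out.

    Runs a 2-state (position, velocity) Kalman filter per coordinate with
    unit velocity variance; the innovation scale then estimates sigma_v^2
    analytically.
    """
    tau = np.exp(log_tau)
    phi, a12, q11, q12, q22 = _iou_blocks(dt, tau)
    n = len(xy)
    # state mean per coordinate; exact first observation
    mx = np.array([xy[0, 0], 0.0])
    my = np.array([xy[0, 1], 0.0])
    # covariance shared by both coordinates (same dynamics)
    P = np.array([[0.0, 0.0], [0.0, 1.0]])
    sum_logs = 0.0
    ssq = 0.0
    m_innov = 0
    for k in range(n - 1):
        F = np.array([[1.0, a12[k]], [0.0, phi[k]]])
        Q = np.array([[q11[k], q12[k]], [q12[k], q22[k]]])
        mx = F @ mx
        my = F @ my
        P = F @ P @ F.T + Q
        S = P[0, 0] + 1e-12
        ex = xy[k + 1, 0] - mx[0]
        ey = xy[k + 1, 1] - my[0]
        K = P[:, 0] / S
        mx = mx + K * ex
        my = my + K * ey
        P = P - np.outer(K, P[0, :])
        sum_logs += 2.0 * np.log(S)
        ssq += (ex * ex + ey * ey) / S
        m_innov += 2
    sigma2 = max(ssq / m_innov, 1e-30)
    nll = 0.5 * (m_innov * (np.log(sigma2) + 1.0
                            + np.log(2.0 * np.pi)) + sum_logs)
    return nll, sigma2


def fit_cvm(window, times_s: np.ndarray | None = None) -> CvmParams:
    """Maximum-likelihood CVM fit to a window of fixes.

    Positions are modelled as integrated Ornstein-Uhlenbeck velocity with
    rms speed eta and autocorrelation timescale tau; the exact Gaussian
    likelihood is evaluated by Kalman filtering, the velocity variance is
    concentrated out analytically, and tau is profiled by bounded scalar
    optimisation on log tau.
    """
    xy, t = _coords(window)
    if times_s is not None:
        t = np.asarray(times_s, dtype=float)
    n = len(xy)
    if n < CVM_MIN_N:
        return CvmParams(np.nan, np.nan, n, converged=False)
    dt = np.diff(t)
    if np.any(dt <= 0):
        return CvmParams(np.nan, np.nan, n, converged=False)
    med_dt = float(np.median(dt))
    lo, hi = np.log(med_dt / 20.0), np.log(med_dt * 2000.0)
    try:
        res = minimize_scalar(
            lambda lt: _cvm_profile(lt, xy, dt)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4})
        nll, sigma2 = _cvm_profile(res.x, xy, dt)
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        return CvmParams(np.nan, np.nan, n, converged=False)
    tau = float(np.exp(res.x))
    eta = float(np.sqrt(2.0 * sigma2))
    return CvmParams(eta, tau, n, loglik=-float(nll), converged=True)


def cvm_sliding(track, indices: np.ndarray | None = None,
                window_n: int = CVM_WINDOW_N) -> dict[int, CvmParams]:
    """Fit the CVM in centred sliding windows around the given fix indices.

    Windows shrink at path edges down to :data:`CVM_MIN_N` fixes.
    """
    xy, t = _coords(track)
    n = len(xy)
    if indices is None:
        indices = np.arange(n)
    half = window_n // 2
    out: dict[int, CvmParams] = {}
    for i in np.asarray(indices, dtype=int):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = fit_cvm(xy[lo:hi], times_s=t[lo:hi])
    return out


# ---------------------------------------------------------------------------
# imputation of edge labels

_RANKED = (CLUSTER, ARS, TRAVEL)


def _standardize(z: np.ndarray) -> np.ndarray:
    mu = z.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return (z - mu) / sd


def impute_edge_labels(
    unlabeled: dict[int, CvmParams],
    labeled: dict[int, tuple[CvmParams, str]] | None = None,
) -> dict[int, str]:
    """Assign behaviour labels to FPT-undecidable fixes from (eta, tau).

    Ward-linkage agglomerative clustering on standardized (log eta,
    log tau) of the unlabeled records, cut at three clusters, mapped to
    labels by ascending mean eta: slowest cluster -> CLUSTER, middle ->
    ARS, fastest -> TRAVEL.  With fewer than three usable records, falls
    back to the nearest labelled neighbour in (log eta, log tau) space.
    """
    valid = {i: p for i, p in unlabeled.items()
             if p.converged and np.isfinite(p.eta) and np.isfinite(p.tau)}
    if not valid:
        return {}
    idx = np.array(sorted(valid))
    z = np.array([[np.log(max(valid[i].eta, 1e-12)),
                   np.log(max(valid[i].tau, 1e-12))] for i in idx])

    if len(idx) < 3:
        if labeled:
            ref = [(np.log(max(p.eta, 1e-12)), np.log(max(p.tau, 1e-12)), lab)
                   for p, lab in labeled.values()
                   if p.converged and np.isfinite(p.eta)]
            if ref:
                refz = np.array([[r[0], r[1]] for r in ref])
                labs = [r[2] for r in ref]
                out = {}
                for row, i in zip(z, idx):
                    j = int(np.argmin(np.sum((refz - row) ** 2, axis=1)))
                    out[int(i)] = labs[j]
                return out
        warnings.warn("too few CVM records to cluster; labelling by speed rank")
        order = np.argsort([valid[i].eta for i in idx])
        return {int(idx[j]): _RANKED[min(r, 2)]
                for r, j in enumerate(order)}

    zs = _standardize(z)
    if np.allclose(zs, zs[0]):
        warnings.warn("identical CVM records; single degenerate cluster")
        return {int(i): CLUSTER for i in idx}
    link = linkage(zs, method="ward")
    assign = fcluster(link, t=3, criterion="maxclust")
    clusters = np.unique(assign)
    mean_eta = {c: float(np.mean([valid[i].eta
                                  for i, a in zip(idx, assign) if a == c]))
                for c in clusters}
    ranked = sorted(clusters, key=lambda c: mean_eta[c])
    if len(ranked) < 3:
        warnings.warn(f"Ward cut produced {len(ranked)} clusters, not 3")
    label_of = {c: _RANKED[min(r, 2)] for r, c in enumerate(ranked)}
    return {int(i): label_of[a] for i, a in zip(idx, assign)}


# ---------------------------------------------------------------------------
# per-path orchestration

def segment_path(path, window_s: float = WINDOW_S,
                 n_reference: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Full per-fix labelling of one daily path.

    FPT decides where it can; remaining (edge) fixes get CVM fits and Ward
    imputation.  Returns (labels, basis) object arrays, one entry per fix;
    after imputation every fix carries exactly one label.
    """
    labels, _ = classify_fpt(path, window_s=window_s)
    basis = np.where(labels == None, None, BASIS_FPT).astype(object)  # noqa: E711
    missing = np.flatnonzero(labels == None)  # noqa: E711
    if len(missing) == 0:
        return labels, basis

    params = cvm_sliding(path, indices=missing)
    n_valid = sum(p.converged for p in params.values())
    labeled_ref = None
    if n_valid < 3:
        done = np.flatnonzero(labels != None)  # noqa: E711
        if len(done):
            pick = done[np.linspace(0, len(done) - 1,
                                    min(n_reference, len(done))).astype(int)]
            ref_params = cvm_sliding(path, indices=pick)
            labeled_ref = {int(i): (ref_params[i], labels[i]) for i in pick
                           if ref_params[i].converged}
    imputed = impute_edge_labels(params, labeled=labeled_ref)
    for i, lab in imputed.items():
        labels[i] = lab
        basis[i] = BASIS_CVM
    # anything still unlabelled (non-converged CVM): copy nearest labelled fix
    for i in np.flatnonzero(labels == None):  # noqa: E711
        done = np.flatnonzero(labels != None)  # noqa: E711
        if len(done) == 0:
            break
        j = done[np.argmin(np.abs(done - i))]
        labels[i] = labels[j]
        basis[i] = BASIS_CVM
    return labels, basis
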