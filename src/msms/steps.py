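"""Step-scale geometry and distribution fitting.

A step is the displacement between two consecutive analysis fixes (the
4-min last-of-burst series, observed plus interpolated).  Step lengths are
summarised by a maximum-likelihood Gamma fit (shape k, scale theta, metres)
and turn angles — the wrapped change in heading over three consecutive
fixes — by a von Mises fit (mean direction mu, concentration kappa).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import DegenerateDataError, InsufficientDataError, SchemaError
from .trajectory_io import DailyPath, Trajectory

#: kappa is capped here for (near-)degenerate angle samples
KAPPA_MAX = 500.0


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return -np.remainder(-np.asarray(a) + np.pi, 2.0 * np.pi) + np.pi


@dataclass
class StepSeries:
    """Step lengths, headings and turn angles of one fix series.

    ``dropped_turns`` counts turn angles discarded because an adjacent step
    had zero length (heading undefined at a stationary fix).
    """

    step_lengths: np.ndarray      # metres, n-1 values
    headings: np.ndarray          # radians in (-pi, pi], NaN where undefined
    turn_angles: np.ndarray       # radians in (-pi, pi]
    dt: np.ndarray                # seconds per step
    dropped_turns: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.step_lengths)


def compute_steps(track: Trajectory | DailyPath | np.ndarray,
                  times_s: np.ndarray | None = None) -> StepSeries:
    """Step lengths, headings, and wrapped turn angles of a fix series.

    Accepts a Trajectory, a DailyPath, or an (n, 2) coordinate array with
    optional times.  Zero-length steps have undefined headings; the turn
    angles adjacent to them are dropped (counted, not imputed).
    """
    if isinstance(track, (Trajectory, DailyPath)):
        xy = track.xy()
        times_s = track.times_s()
    else:
        xy = np.asarray(track, dtype=float)
        if times_s is None:
            times_s = np.arange(len(xy), dtype=float)
    if xy.size and not np.all(np.isfinite(xy)):
        raise SchemaError("non-finite coordinates in step computation")
    if len(xy) < 2:
        empty = np.empty(0)
        return StepSeries(empty, empty, empty, empty)

    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    dt = np.diff(np.asarray(times_s, dtype=float))
    headings = np.where(lengths > 0, np.arctan2(d[:, 1], d[:, 0]), np.nan)
    headings = wrap_angle(headings)

    if len(lengths) < 2:
        return StepSeries(lengths, headings, np.empty(0), dt)
    raw = wrap_angle(headings[1:] - headings[:-1])
    defined = np.isfinite(headings[1:]) & np.isfinite(headings[:-1])
    turns = raw[defined]
    return StepSeries(lengths, headings, turns, dt,
                      dropped_turns=int((~defined).sum()))


# ---------------------------------------------------------------------------
# Gamma fit

@dataclass
class GammaFit:
    """MLE of a Gamma distribution for step lengths (metres)."""

    shape_k: float
    scale_theta: float
    loglik: float
    n: int
    n_zero_excluded: int = 0

    @property
    def mean(self) -> float:
        return self.shape_k * self.scale_theta


def fit_gamma(lengths: np.ndarray, min_n: int = 10) -> GammaFit:
    """Maximum-likelihood Gamma(k, theta) fit to positive step lengths.

    Zeros are excluded (their count is reported): a Gamma density has no
    atom at zero, and stationary 4-min intervals carry no length signal.
    Solves the profile score  log(k) - psi(k) = log(mean) - mean(log)
    by derivative-based root finding, so k*theta equals the sample mean
    exactly at the optimum.
    """
    x = np.asarray(lengths, dtype=float)
    x = x[np.isfinite(x)]
    n_zero = int((x <= 0).sum())
    x = x[x > 0]
    if len(x) < min_n:
        raise InsufficientDataError(
            f"need >= {min_n} positive step lengths, got {len(x)}")
    if np.allclose(x, x[0]):
        raise DegenerateDataError("all step lengths identical")

    s = np.log(np.mean(x)) - np.mean(np.log(x))  # > 0 by Jensen
    # Minka's initialisation, then Newton on f(k) = log k - psi(k) - s
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * max(1.0, k):
            k = k_new
            break
        k = k_new
    theta = float(np.mean(x) / k)
    ll = float(np.sum(stats.gamma.logpdf(x, a=k, scale=theta)))
    return GammaFit(float(k), theta, ll, len(x), n_zero)


# ---------------------------------------------------------------------------
# von Mises fit

@dataclass
class VonMisesFit:
    """MLE of a von Mises distribution for turn angles (radians)."""

    mu: float
    kappa: float
    loglik: float
    n: int
    rbar: float = 0.0


def _a1(kappa: float) -> float:
    """A1(kappa) = I1(kappa) / I0(kappa), the mean resultant of vM(kappa)."""
    return special.i1e(kappa) / special.i0e(kappa)


def fit_vonmises(angles: np.ndarray, min_n: int = 10,
                 kappa_max: float = KAPPA_MAX) -> VonMisesFit:
    """Maximum-likelihood von Mises(mu, kappa) fit to angles (radians).

    mu-hat is the circular mean; kappa-hat inverts A1(kappa) = Rbar (the
    mean resultant length) via the Best-Fisher starting value plus Newton
    refinement, capped at ``kappa_max`` for near point-mass samples.
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < min_n:
        raise InsufficientDataError(
            f"need >= {min_n} angles, got {len(a)}")
    c = np.mean(np.cos(a))
    s = np.mean(np.sin(a))
    rbar = float(np.hypot(c, s))
    mu = float(wrap_angle(np.arctan2(s, c)))

    if rbar < 1e-12:
        kappa = 0.0
    elif rbar >= _a1(kappa_max):
        kappa = kappa_max
    else:
        # Best & Fisher (1981) approximation
        if rbar < 0.53:
            kappa = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
        elif rbar < 0.85:
            kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
        else:
            kappa = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
        for _ in range(50):
            ak = _a1(kappa)
            # d A1/d kappa = 1 - A1^2 - A1/kappa
            deriv = 1.0 - ak * ak - ak / kappa
            if deriv <= 0:
                break
            step = (ak - rbar) / deriv
            kappa = min(max(kappa - step, 1e-12), kappa_max)
            if abs(step) < 1e-12 * max(1.0, kappa):
                break
    ll = float(np.sum(stats.vonmises.logpdf(a, kappa, loc=mu))) \
        if kappa > 0 else float(-len(a) * np.log(2 * np.pi))
    return VonMisesFit(mu, float(kappa), ll, len(a), rbar)


# ---------------------------------------------------------------------------
# per-individual pooled fits

def fit_individual_steps(traj: Trajectory) -> dict:
    """Pool all steps of one individual and fit both distributions.

    Returns a flat record (id, species, n, k, theta, mu, kappa) suitable
    for the step-scale metric table.
    """
    series = compute_steps(traj)
    gam = fit_gamma(series.step_lengths)
    vm = fit_vonmises(series.turn_angles)
    return {
        "individual_id": traj.individual_id,
        "species": traj.species,
        "n_steps": series.n_steps,
        "gamma_k": gam.shape_k,
        "gamma_theta": gam.scale_theta,
        "vm_mu": vm.mu,
        "vm_kappa": vm.kappa,
    }
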