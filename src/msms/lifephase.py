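"""Life-history-phase metrics: weeks-to-months summaries of one range.

Five range-residency statistics — turn-angle correlation, residence time,
time-to-return, volume of intersection of monthly utilization
distributions, and maximum net squared displacement — plus a Gaussian-KDE
utilization distribution whose 95% isopleth serves as the home range.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .exceptions import DegenerateDataError, InsufficientDataError
from .steps import compute_steps, wrap_angle
from .trajectory_io import Trajectory

#: default excursion cut-off for residence time / time-to-return
CUTOFF_H = 12.0

#: calendar months need this many fixes to enter the monthly-UD overlap
MIN_MONTH_FIXES = 200


# ---------------------------------------------------------------------------
# turn angle correlation

def turn_angle_correlation(track) -> tuple[float, float]:
    """Sum of squared wrapped differences between successive turn angles.

    Returns ``(raw_sum, per_pair_mean)`` in radians^2.  The raw sum grows
    with track length, so cross-individual comparisons use the mean.
    """
    turns = compute_steps(track).turn_angles
    if len(turns) < 2:
        return np.nan, np.nan
    d = wrap_angle(np.diff(turns))
    raw = float(np.sum(d * d))
    return raw, raw / len(d)


# ---------------------------------------------------------------------------
# residence time and time-to-return

def _inside_intervals(t: np.ndarray, d: np.ndarray, radius: float
                      ) -> list[tuple[float, float]]:
    """Time intervals during which the track is within ``radius``.

    Crossing times are linearly interpolated on the distance profile
    between bracketing fixes.
    """
    inside = d <= radius
    if not inside.any():
        return []
    flips = np.flatnonzero(np.diff(inside.view(np.int8)))  # index before flip
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (radius - d[flips]) / (d[flips + 1] - d[flips])
    cross = t[flips] + frac * (t[flips + 1] - t[flips])
    starts = []
    ends = []
    if inside[0]:
        starts.append(t[0])
    for k, f in enumerate(flips):
        if inside[f]:          # inside -> outside: interval ends
            ends.append(cross[k])
        else:                  # outside -> inside: interval starts
            starts.append(cross[k])
    if inside[-1]:
        ends.append(t[-1])
    return list(zip(starts, ends))


def residence_time(track, radius: float, cutoff_h: float = CUTOFF_H,
                   stride: int = 1) -> tuple[np.ndarray, float]:
    """Hours spent inside a circle around each fix, bridging short exits.

    Excursions shorter than the cut-off do not terminate the accumulation;
    the first excursion longer than the cut-off (in either time direction)
    does.  Returns (per-fix hours, mean hours).  ``stride`` evaluates only
    every stride-th fix (the mean is over evaluated fixes); the metric is a
    per-fix average, so thinning the centres leaves it unbiased while
    keeping long tracks tractable.
    """
    xy, t = _track_arrays(track)
    cutoff_s = cutoff_h * 3600.0
    n = len(xy)
    out = np.full(n, np.nan)
    for i in range(0, n, max(1, stride)):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        iv = _inside_intervals(t, d, radius)
        j = _containing_interval(iv, t[i])
        total = iv[j][1] - iv[j][0]
        k = j
        while k + 1 < len(iv) and iv[k + 1][0] - iv[k][1] <= cutoff_s:
            total += iv[k + 1][1] - iv[k + 1][0]
            k += 1
        k = j
        while k - 1 >= 0 and iv[k][0] - iv[k - 1][1] <= cutoff_s:
            total += iv[k - 1][1] - iv[k - 1][0]
            k -= 1
        out[i] = total / 3600.0
    return out, float(np.nanmean(out))


def _containing_interval(iv: list[tuple[float, float]], ti: float) -> int:
    for j, (a, b) in enumerate(iv):
        if a - 1e-9 <= ti <= b + 1e-9:
            return j
    # fall back to the nearest interval (numerical edge)
    return int(np.argmin([min(abs(a - ti), abs(b - ti)) for a, b in iv]))


def time_to_return(track, radius: float, cutoff_h: float = CUTOFF_H,
                   stride: int = 1) -> tuple[np.ndarray, float, int]:
    """Duration of the first long excursion before returning to each fix.

    For each fix, the first excursion outside its circle lasting longer
    than the cut-off and ending in an observed re-entry contributes its
    full duration (hours).  Fixes whose track ends mid-excursion are
    censored (NaN).  Returns (per-fix hours, mean over uncensored,
    censored count).  ``stride`` thins the evaluated centres as in
    :func:`residence_time`.
    """
    xy, t = _track_arrays(track)
    cutoff_s = cutoff_h * 3600.0
    n = len(xy)
    out = np.full(n, np.nan)
    censored = 0
    for i in range(0, n, max(1, stride)):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        iv = _inside_intervals(t, d, radius)
        j = _containing_interval(iv, t[i])
        val = np.nan
        found = False
        for k in range(j, len(iv) - 1):
            gap = iv[k + 1][0] - iv[k][1]
            if gap > cutoff_s:
                val = gap / 3600.0
                found = True
                break
        if not found:
            if iv[-1][1] < t[-1] - 1e-9 and (t[-1] - iv[-1][1]) > cutoff_s:
                censored += 1   # left for > cutoff, never returned
        out[i] = val
    mean = float(np.nanmean(out)) if np.isfinite(out).any() else np.nan
    return out, mean, censored


def _track_arrays(track) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, Trajectory):
        return track.xy(), track.times_s()
    xy = np.asarray(track[0] if isinstance(track, tuple) else track, float)
    if isinstance(track, tuple):
        return xy, np.asarray(track[1], float)
    return xy, np.arange(len(xy), dtype=float)


# ---------------------------------------------------------------------------
# utilization distribution (plain Gaussian KDE)

@dataclass
class UtilizationDistribution:
    """Gridded kernel utilization density; integrates to one.

    ``density[iy, ix]`` on cell centres ``x0 + (ix+0.5)*cell``,
    ``y0 + (iy+0.5)*cell``.
    """

    density: np.ndarray
    x0: float
    y0: float
    cell: float
    bandwidth: float
    n: int = 0

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.density.shape[1]) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.density.shape[0]) + 0.5) * self.cell

    def isopleth_area(self, p: float = 0.95) -> float:
        """Area (hectares) of the smallest region holding probability p."""
        mass = np.sort(self.density.ravel())[::-1] * self.cell**2
        k = int(np.searchsorted(np.cumsum(mass), p)) + 1
        return k * self.cell**2 / 1e4


def kde_ud(fixes: np.ndarray, bandwidth: float | None = None,
           min_n: int = 30) -> UtilizationDistribution:
    """Gaussian-kernel utilization distribution of a point cloud.

    AUTO bandwidth is the reference rule h = sigma * n^(-1/6) with sigma
    the mean of the coordinate standard deviations.  The grid cell is
    h/4 and the extent is padded by three bandwidths, so edge truncation
    is negligible; the density is renormalised to integrate to one.
    Implemented as a fine histogram smoothed with a Gaussian filter.
    """
    xy = np.asarray(fixes, dtype=float)
    if xy.ndim != 2 or len(xy) < min_n:
        raise InsufficientDataError(f"KDE needs >= {min_n} fixes")
    sx, sy = np.std(xy[:, 0]), np.std(xy[:, 1])
    if sx == 0 and sy == 0:
        raise DegenerateDataError("all fixes identical; KDE undefined")
    if bandwidth is None:
        bandwidth = 0.5 * (sx + sy) * len(xy) ** (-1.0 / 6.0)
    cell = bandwidth / 4.0
    pad = 3.0 * bandwidth
    x0 = xy[:, 0].min() - pad
    y0 = xy[:, 1].min() - pad
    nx = int(np.ceil((xy[:, 0].max() + pad - x0) / cell)) + 1
    ny = int(np.ceil((xy[:, 1].max() + pad - y0) / cell)) + 1
    hist, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0], bins=[ny, nx],
        range=[[y0, y0 + ny * cell], [x0, x0 + nx * cell]])
    dens = gaussian_filter(hist, sigma=bandwidth / cell, mode="constant")
    total = dens.sum() * cell**2
    if total <= 0:
        raise DegenerateDataError("empty utilization density")
    return UtilizationDistribution(dens / total, x0, y0, cell,
                                   float(bandwidth), n=len(xy))


def volume_of_intersection(ud1: UtilizationDistribution,
                           ud2: UtilizationDistribution) -> float:
    """Overlap of two utilization distributions: integral of min(UD1, UD2).

    1 for identical distributions, 0 for disjoint supports.  The minimum
    of the two densities vanishes outside the overlap of their extents, so
    only the intersection box is gridded (finest cell of the two UDs);
    each UD is bilinearly resampled there, zero outside its own grid.
    """
    cell = min(ud1.cell, ud2.cell)
    x_min = max(ud1.x0, ud2.x0)
    y_min = max(ud1.y0, ud2.y0)
    x_max = min(ud1.x0 + ud1.density.shape[1] * ud1.cell,
                ud2.x0 + ud2.density.shape[1] * ud2.cell)
    y_max = min(ud1.y0 + ud1.density.shape[0] * ud1.cell,
                ud2.y0 + ud2.density.shape[0] * ud2.cell)
    if x_max <= x_min or y_max <= y_min:
        return 0.0
    xs = np.arange(x_min + cell / 2, x_max, cell)
    ys = np.arange(y_min + cell / 2, y_max, cell)
    gx, gy = np.meshgrid(xs, ys)

    def _resample(ud: UtilizationDistribution) -> np.ndarray:
        interp = RegularGridInterpolator(
            (ud.y_centers, ud.x_centers), ud.density,
            bounds_error=False, fill_value=0.0)
        return interp(np.column_stack([gy.ravel(),
                                       gx.ravel()])).reshape(gy.shape)

    z1 = _resample(ud1)
    z2 = _resample(ud2)
    return float(np.minimum(z1, z2).sum() * cell**2)


# ---------------------------------------------------------------------------
# displacement

def max_net_squared_displacement(track) -> float:
    """Maximum squared displacement (m^2) from the first relocation."""
    xy, _ = _track_arrays(track)
    if len(xy) < 2:
        return 0.0
    d2 = (xy[:, 0] - xy[0, 0]) ** 2 + (xy[:, 1] - xy[0, 1]) ** 2
    return float(d2.max())


def scale_mnsd_by_species(mnsd: dict[str, float],
                          species: dict[str, str]) -> dict[str, float]:
    """Divide each individual's MNSD by the smallest MNSD of its species.

    The individual holding the species minimum scales to exactly 1.
    """
    mins: dict[str, float] = {}
    for ind, v in mnsd.items():
        sp = species[ind]
        if np.isfinite(v) and v > 0:
            mins[sp] = min(mins.get(sp, np.inf), v)
    out = {}
    for ind, v in mnsd.items():
        m = mins.get(species[ind], np.nan)
        out[ind] = v / m if np.isfinite(m) and m > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# monthly-UD stability and per-individual orchestration

def monthly_vi(traj: Trajectory, bandwidth: float | None = None,
               min_month_fixes: int = MIN_MONTH_FIXES,
               consecutive_only: bool = True) -> float:
    """Mean overlap of monthly utilization distributions (range stability).

    Calendar months with at least ``min_month_fixes`` fixes get a UD; the
    metric is the mean volume of intersection over consecutive qualifying
    month pairs (all pairs with ``consecutive_only=False``).  NaN when
    fewer than two months qualify.
    """
    f = traj.fixes
    if len(f) == 0:
        return np.nan
    period = f["timestamp"].dt.to_period("M")
    uds = []
    keys = []
    for m, g in f.groupby(period):
        if len(g) >= min_month_fixes:
            try:
                uds.append(kde_ud(g[["x", "y"]].to_numpy(float),
                                  bandwidth=bandwidth))
                keys.append(m)
            except (InsufficientDataError, DegenerateDataError):
                continue
    if len(uds) < 2:
        return np.nan
    vis = []
    for a in range(len(uds) - 1):
        rng = range(a + 1, a + 2) if consecutive_only else range(a + 1, len(uds))
        for b in rng:
            if consecutive_only and (keys[b] - keys[a]).n != 1:
                continue
            vis.append(volume_of_intersection(uds[a], uds[b]))
    return float(np.mean(vis)) if vis else np.nan


@dataclass
class LifePhaseMetrics:
    """The five life-history-phase statistics plus home range size."""

    individual_id: str
    species: str
    tac: float                    # raw sum, radians^2
    tac_mean: float               # per-pair mean, radians^2
    residence_time_h: float
    time_to_return_h: float
    vi: float
    mnsd_m2: float
    mnsd_scaled: float = field(default=np.nan)
    home_range_ha: float = field(default=np.nan)


def life_phase_metrics(traj: Trajectory,
                       radius: float | None = None,
                       cutoff_h: float = CUTOFF_H,
                       max_centers: int = 2000) -> LifePhaseMetrics:
    """All life-history-phase statistics for one individual's track.

    The residence/return radius defaults to the individual's mean observed
    step length.  ``mnsd_scaled`` is left NaN here; it needs the species
    cohort (:func:`scale_mnsd_by_species`).  Tracks longer than
    ``max_centers`` fixes evaluate residence/return on an evenly thinned
    set of centres (both metrics are per-fix means, so thinning only
    trades Monte-Carlo precision for time).
    """
    series = compute_steps(traj)
    if radius is None:
        pos = series.step_lengths[series.step_lengths > 0]
        radius = float(np.mean(pos)) if len(pos) else 1.0
    raw_tac, mean_tac = turn_angle_correlation(traj)
    stride = max(1, int(np.ceil(traj.n_fixes / max_centers)))
    _, res_mean = residence_time(traj, radius, cutoff_h, stride=stride)
    _, ttr_mean, _ = time_to_return(traj, radius, cutoff_h, stride=stride)
    vi = monthly_vi(traj)
    mnsd = max_net_squared_displacement(traj)
    try:
        hr = kde_ud(traj.xy()).isopleth_area(0.95)
    except (InsufficientDataError, DegenerateDataError):
        hr = np.nan
    return LifePhaseMetrics(
        individual_id=traj.individual_id,
        species=traj.species,
        tac=raw_tac,
        tac_mean=mean_tac,
        residence_time_h=res_mean,
        time_to_return_h=ttr_mean,
        vi=vi,
        mnsd_m2=mnsd,
        home_range_ha=hr,
    )
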