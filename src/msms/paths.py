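"""Daily-path metrics: distance, straightness, sinuosity, behaviour budget.

Five metrics summarise one activity period: total distance moved,
straightness (net/gross displacement ratio), corrected sinuosity on a
rediscretized path, and the proportions of fixes labelled cluster and
area-restricted search (the travel proportion completes the budget).
A path enters cross-individual summaries only when it is complete (hourly
or better coverage) and has at least 100 locations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError
from .segmentation import ARS, CLUSTER, TRAVEL
from .steps import compute_steps
from .trajectory_io import DailyPath

#: minimum locations for a daily path to enter comparative summaries
MIN_PATH_FIXES = 100


@dataclass
class PathMetrics:
    """The five path-scale metrics for one individual-day."""

    individual_id: str
    period_date: object
    distance: float               # metres
    straightness: float           # (0, 1]
    sinuosity: float              # m^(-1/2)
    prop_cluster: float
    prop_ars: float
    prop_travel: float
    n_fixes: int
    complete: bool
    eligible: bool


def daily_distance(path: DailyPath | np.ndarray) -> float:
    """Total distance moved: sum of straight-line step lengths (metres)."""
    series = compute_steps(path)
    return float(np.sum(series.step_lengths))


def straightness_index(path: DailyPath | np.ndarray) -> float:
    """Net displacement over gross path length, in (0, 1].

    1 for dead-straight travel, 0 for a closed loop.  Undefined (raises)
    when the path has zero total length.
    """
    xy = path.xy() if isinstance(path, DailyPath) else np.asarray(path, float)
    if len(xy) < 2:
        raise UndefinedMetricError("straightness needs >= 2 fixes")
    total = daily_distance(xy)
    if total <= 0:
        raise UndefinedMetricError("straightness undefined on zero-length path")
    net = float(np.hypot(*(xy[-1] - xy[0])))
    return net / total


def rediscretize(path: DailyPath | np.ndarray, step: float) -> np.ndarray:
    """Resample a path to points spaced exactly ``step`` metres apart.

    Walks the piecewise-linear path by arc length starting at the first
    fix; the trailing remainder shorter than ``step`` is discarded.
    """
    if step <= 0:
        raise UndefinedMetricError("rediscretization step must be > 0")
    xy = path.xy() if isinstance(path, DailyPath) else np.asarray(path, float)
    if len(xy) < 2:
        raise UndefinedMetricError("cannot rediscretize < 2 fixes")
    seg = np.diff(xy, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total < step:
        raise UndefinedMetricError(
            f"path length {total:.3f} m shorter than step {step} m")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.arange(0.0, total + 1e-9, step)
    # locate each target arc length on the cumulative profile
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1,
                  0, len(seglen) - 1)
    frac = np.where(seglen[idx] > 0,
                    (targets - cum[idx]) / np.where(seglen[idx] > 0,
                                                    seglen[idx], 1.0),
                    0.0)
    return xy[idx] + frac[:, None] * seg[idx]


def sinuosity_index(path: DailyPath | np.ndarray, step: float) -> float:
    """Corrected sinuosity S = 2 / sqrt(p * (1 + c) / (1 - c)).

    ``p`` is the rediscretization step (metres) and ``c`` the mean cosine
    of the rediscretized turn angles.  Near-straight paths (c -> 1) give
    S -> 0; uncorrelated turning (c = 0) gives S = 2/sqrt(p).  Units are
    m^(-1/2).
    """
    pts = rediscretize(path, step)
    if len(pts) < 3:
        raise UndefinedMetricError(
            "sinuosity needs >= 3 rediscretized points")
    turns = compute_steps(pts).turn_angles
    if len(turns) == 0:
        raise UndefinedMetricError("no defined turn angles after resampling")
    c = float(np.mean(np.cos(turns)))
    c = min(c, 1.0 - 1e-12)
    return float(2.0 / np.sqrt(step * (1.0 + c) / (1.0 - c)))


def species_mean_step(step_lengths_by_individual: dict[str, np.ndarray]) -> float:
    """Pooled mean step length across all study animals of a species.

    Used as the rediscretization step so that sinuosity is computed at a
    common spatial grain within a species.
    """
    pooled = np.concatenate([np.asarray(v, float)
                             for v in step_lengths_by_individual.values()])
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        raise UndefinedMetricError("no steps to average")
    return float(np.mean(pooled))


def path_metrics(
    path: DailyPath,
    labels: np.ndarray,
    species_step: float,
    min_fixes: int = MIN_PATH_FIXES,
) -> PathMetrics:
    """Bundle the five path metrics for one daily path.

    ``labels`` holds one behaviour label (CLUSTER/ARS/TRAVEL) per fix.
    Metrics that are undefined for the path (zero length, too short to
    rediscretize) are reported as NaN; eligibility requires completeness
    and at least ``min_fixes`` locations.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != path.n_fixes:
        raise UndefinedMetricError(
            f"labels ({len(labels)}) do not cover path fixes ({path.n_fixes})")
    dist = daily_distance(path) if path.n_fixes >= 2 else 0.0
    try:
        straight = straightness_index(path)
    except UndefinedMetricError:
        straight = np.nan
    try:
        sinu = sinuosity_index(path, species_step)
    except UndefinedMetricError:
        sinu = np.nan
    n_lab = int(np.sum(labels != None))  # noqa: E711  — object array
    if n_lab > 0:
        p_cl = float(np.sum(labels == CLUSTER)) / n_lab
        p_ars = float(np.sum(labels == ARS)) / n_lab
        p_tr = float(np.sum(labels == TRAVEL)) / n_lab
    else:
        p_cl = p_ars = p_tr = np.nan
    eligible = bool(path.complete and path.n_fixes >= min_fixes)
    return PathMetrics(
        individual_id=path.individual_id,
        period_date=path.period_date,
        distance=dist,
        straightness=straight,
        sinuosity=sinu,
        prop_cluster=p_cl,
        prop_ars=p_ars,
        prop_travel=p_tr,
        n_fixes=path.n_fixes,
        complete=path.complete,
        eligible=eligible,
    )
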