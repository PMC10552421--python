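"""Shared fixtures: small synthetic tracks and studies, all seeded."""
from __future__ import annotations

from datetime import time, timedelta

import numpy as np
import pandas as pd
import pytest

from msms.trajectory_io import Trajectory


def make_trajectory(xy, start="2016-01-10 12:00:00", interval_s=240.0,
                    individual_id="ind1", species="coati",
                    altitude=None, burst_id=None,
                    activity_window=(time(6, 0), time(18, 0))):
    """Trajectory from an (n, 2) array with regular UTC timestamps."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    t0 = pd.Timestamp(start)
    fixes = pd.DataFrame({
        "timestamp": [t0 + timedelta(seconds=interval_s * i)
                      for i in range(n)],
        "x": xy[:, 0],
        "y": xy[:, 1],
    })
    if altitude is not None:
        fixes["altitude_hae"] = altitude
    if burst_id is not None:
        fixes["burst_id"] = burst_id
    return Trajectory(individual_id=individual_id, species=species,
                      fixes=fixes, nominal_interval=interval_s,
                      activity_window=activity_window)


@pytest.fixture
def rng():
    return np.random.default_rng(20160110)


@pytest.fixture(scope="session")
def separated_study():
    """Noiseless separated-regime track with ground truth (session cache)."""
    from msms.simulate import separated_regimes_config, simulate_individual

    cfg = separated_regimes_config(days=3, seed=11)
    return simulate_individual(cfg, individual_id="sep", species="simsp")
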