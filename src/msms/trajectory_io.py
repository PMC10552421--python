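"""Reading tracking tables and assembling trajectories and daily paths.

A trajectory is the time-ordered GPS record of one individual, held as a
pandas DataFrame in a planar metric frame (UTM metres).  Lon/lat input is
projected once at ingestion.  Daily paths slice a trajectory into activity
periods (the behavioural "day": a calendar day for diurnal species, a night
keyed to its starting date for nocturnal species).

Timestamps are stored tz-naive and interpreted as UTC; activity windows are
evaluated in a configurable local timezone (default UTC-5, the study-site
offset).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, time, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._utm import geographic_to_utm
from .exceptions import SchemaError

# ---------------------------------------------------------------------------
# constants and schema

#: seconds between nominal GPS bursts
DEFAULT_INTERVAL_S = 240.0

#: local-time activity windows per species group; nocturnal windows span
#: midnight and are keyed to the date the window starts
ACTIVITY_WINDOWS: dict[str, tuple[time, time]] = {
    "kinkajou": (time(23, 0), time(6, 30)),
    "coati": (time(6, 0), time(18, 30)),
    "capuchin": (time(6, 0), time(18, 0)),
    "spider_monkey": (time(6, 0), time(18, 0)),
}

#: default local-time offset from UTC for window evaluation (study site)
DEFAULT_TZ_OFFSET_H = -5.0

SOURCE_OBSERVED = "observed"
SOURCE_INTERPOLATED = "interpolated"

FLAG_ALTITUDE = "ALTITUDE"
FLAG_BOUNDARY = "BOUNDARY"
FLAG_SPEED = "SPEED"
FLAG_DUPLICATE = "DUPLICATE"
ALL_FLAGS = (FLAG_ALTITUDE, FLAG_BOUNDARY, FLAG_SPEED, FLAG_DUPLICATE)

#: canonical fix-table columns
FIX_COLUMNS = ("timestamp", "x", "y", "altitude_hae", "burst_id", "source",
               "outlier_flags")

#: default Movebank-export column mapping
DEFAULT_COLUMNS: dict[str, str] = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "altitude_hae": "height-above-ellipsoid",
    "species": "species",
    "burst_id": "burst_id",
}


def _empty_fixes() -> pd.DataFrame:
    return pd.DataFrame({
        "timestamp": pd.Series(dtype="datetime64[ns]"),
        "x": pd.Series(dtype=float),
        "y": pd.Series(dtype=float),
        "altitude_hae": pd.Series(dtype=float),
        "burst_id": pd.Series(dtype=object),
        "source": pd.Series(dtype=object),
        "outlier_flags": pd.Series(dtype=object),
    })


def _normalize_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Fill optional columns, sort by time, reset the index."""
    fixes = fixes.copy()
    for col in ("altitude_hae",):
        if col not in fixes:
            fixes[col] = np.nan
    if "burst_id" not in fixes:
        fixes["burst_id"] = None
    if "source" not in fixes:
        fixes["source"] = SOURCE_OBSERVED
    if "outlier_flags" not in fixes:
        fixes["outlier_flags"] = [set() for _ in range(len(fixes))]
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    fixes = fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return fixes[list(FIX_COLUMNS)]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Trajectory:
    """Time-ordered relocations of one individual in planar metres.

    ``fixes`` columns: timestamp (UTC), x, y, altitude_hae, burst_id,
    source ('observed'/'interpolated'), outlier_flags (set of flag strings).
    Rows flagged as outliers or duplicates are retained with their flags;
    :meth:`clean` projects them away for analysis.
    """

    individual_id: str
    species: str
    fixes: pd.DataFrame
    nominal_interval: float = DEFAULT_INTERVAL_S
    activity_window: tuple[time, time] | None = None
    crs: str = ""
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H

    def __post_init__(self) -> None:
        self.fixes = _normalize_fixes(self.fixes)
        if not np.all(np.isfinite(self.fixes[["x", "y"]].to_numpy())):
            raise SchemaError(
                f"{self.individual_id}: non-finite coordinates in fix table")
        clean = self.fixes[[len(f) == 0 for f in self.fixes["outlier_flags"]]]
        if clean["timestamp"].duplicated().any():
            raise SchemaError(
                f"{self.individual_id}: duplicate timestamps among unflagged fixes")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def with_fixes(self, fixes: pd.DataFrame) -> "Trajectory":
        return replace(self, fixes=fixes)

    def clean(self) -> "Trajectory":
        """Trajectory restricted to unflagged fixes (observed + interpolated)."""
        keep = [len(f) == 0 for f in self.fixes["outlier_flags"]]
        return self.with_fixes(self.fixes[keep].reset_index(drop=True))

    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def times_s(self) -> np.ndarray:
        """Seconds since the first fix."""
        t = self.fixes["timestamp"].to_numpy()
        if len(t) == 0:
            return np.empty(0)
        return (t - t[0]) / np.timedelta64(1, "s")


@dataclass
class DailyPath:
    """All fixes of one individual inside one activity period.

    ``complete`` is True when no inter-fix gap exceeds one hour, the
    eligibility rule for daily distance summaries.
    """

    individual_id: str
    period_date: date
    fixes: pd.DataFrame
    complete: bool = field(default=False)

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def times_s(self) -> np.ndarray:
        t = self.fixes["timestamp"].to_numpy()
        if len(t) == 0:
            return np.empty(0)
        return (t - t[0]) / np.timedelta64(1, "s")


# ---------------------------------------------------------------------------
# ingestion

def read_tracking_csv(
    path: str | Path,
    columns: dict[str, str] | None = None,
    crs: str = "utm-auto",
    nominal_interval: float = DEFAULT_INTERVAL_S,
    activity_windows: dict[str, tuple[time, time]] | None = None,
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H,
) -> list[Trajectory]:
    """Read a Movebank-style tracking CSV into one Trajectory per individual.

    ``columns`` maps canonical names (individual_id, timestamp, lon, lat —
    or x, y for already-planar input — plus optional altitude_hae, species,
    burst_id) to the file's column headers; unspecified entries fall back to
    Movebank export defaults.  Lon/lat input is projected to the UTM zone of
    the data centroid (or a fixed zone via ``crs='utm-<zone>'``).

    Duplicate timestamps within an individual are flagged DUPLICATE, first
    occurrence kept unflagged.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    df = pd.read_csv(path)
    planar = "x" in colmap and "y" in colmap and \
        colmap["x"] in df.columns and colmap["y"] in df.columns

    required = ["individual_id", "timestamp"]
    required += ["x", "y"] if planar else ["lon", "lat"]
    for key in required:
        col = colmap.get(key)
        if col is None or col not in df.columns:
            raise SchemaError(f"required column missing: {key!r} "
                              f"(expected header {col!r})")

    ts = pd.to_datetime(df[colmap["timestamp"]], errors="coerce", utc=True)
    bad = ts.isna() & df[colmap["timestamp"]].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(
            f"unparseable timestamp at line {line}: "
            f"{df.loc[bad.idxmax(), colmap['timestamp']]!r}")
    ts = ts.dt.tz_localize(None)

    if planar:
        x = df[colmap["x"]].to_numpy(dtype=float)
        y = df[colmap["y"]].to_numpy(dtype=float)
        crs_out = crs if crs != "utm-auto" else "planar"
    else:
        lon = df[colmap["lon"]].to_numpy(dtype=float)
        lat = df[colmap["lat"]].to_numpy(dtype=float)
        zone = None
        if crs.startswith("utm-") and crs != "utm-auto":
            zone = int(crs.split("-")[1])
        x, y, zone = geographic_to_utm(lon, lat, zone=zone)
        crs_out = f"utm-{zone}"

    table = pd.DataFrame({
        "individual_id": df[colmap["individual_id"]].astype(str),
        "timestamp": ts,
        "x": x,
        "y": y,
    })
    alt_col = colmap.get("altitude_hae")
    table["altitude_hae"] = (
        df[alt_col].to_numpy(dtype=float) if alt_col in df.columns else np.nan)
    sp_col = colmap.get("species")
    table["species"] = (
        df[sp_col].astype(str) if sp_col in df.columns else "")
    b_col = colmap.get("burst_id")
    table["burst_id"] = df[b_col] if b_col in df.columns else None
    if "source" in df.columns:
        table["source"] = df["source"]
    if "outlier_flags" in df.columns:
        table["outlier_flags"] = [
            set(s.split("|")) if isinstance(s, str) and s else set()
            for s in df["outlier_flags"]]

    windows = activity_windows if activity_windows is not None else ACTIVITY_WINDOWS
    out: list[Trajectory] = []
    for ind, g in table.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        if "outlier_flags" not in g:
            g["outlier_flags"] = [set() for _ in range(len(g))]
        dup = g["timestamp"].duplicated(keep="first")
        for i in np.flatnonzero(dup.to_numpy()):
            g.at[i, "outlier_flags"] = set(g.at[i, "outlier_flags"]) | {FLAG_DUPLICATE}
        species = str(g["species"].iloc[0]) if len(g) else ""
        out.append(Trajectory(
            individual_id=str(ind),
            species=species,
            fixes=g,
            nominal_interval=nominal_interval,
            activity_window=windows.get(species),
            crs=crs_out,
            tz_offset_h=tz_offset_h,
        ))
    return out


def write_tracking_csv(trajectories: Iterable[Trajectory],
                       path: str | Path) -> None:
    """Write trajectories to a cleaned-track CSV (planar x/y dialect).

    Round-trips through :func:`read_tracking_csv` with an x/y column
    mapping: timestamps to the second, coordinates at full float precision.
    """
    rows = []
    for traj in trajectories:
        f = traj.fixes.copy()
        f.insert(0, "individual_id", traj.individual_id)
        f.insert(1, "species", traj.species)
        f["outlier_flags"] = ["|".join(sorted(s)) for s in f["outlier_flags"]]
        rows.append(f)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["individual_id", "species", *FIX_COLUMNS])
    out.to_csv(path, index=False, float_format="%.9f")


PLANAR_COLUMNS = {"individual_id": "individual_id", "timestamp": "timestamp",
                  "x": "x", "y": "y", "altitude_hae": "altitude_hae",
                  "species": "species", "burst_id": "burst_id"}


# ---------------------------------------------------------------------------
# burst selection and daily paths

def select_burst_last_fix(traj: Trajectory) -> Trajectory:
    """Keep only the last (latest-timestamp) fix of each GPS burst.

    The final fix of a 1 Hz burst has the best horizontal accuracy, so
    analyses run on the per-burst last-fix series.  Fixes without a burst id
    pass through unchanged; idempotent.
    """
    f = traj.fixes
    has_burst = f["burst_id"].notna()
    if not has_burst.any():
        return traj
    keep = np.ones(len(f), dtype=bool)
    grp = f.loc[has_burst].groupby("burst_id", sort=False)["timestamp"].idxmax()
    keep[has_burst.to_numpy()] = False
    keep[grp.to_numpy()] = True
    return traj.with_fixes(f[keep].reset_index(drop=True))


def _local_times(fixes: pd.DataFrame, tz_offset_h: float) -> pd.Series:
    return fixes["timestamp"] + timedelta(hours=tz_offset_h)


def assemble_daily_paths(
    traj: Trajectory,
    max_gap_s: float = 3600.0,
) -> list[DailyPath]:
    """Split a (cleaned) trajectory into activity-period daily paths.

    Each in-window fix belongs to exactly one path.  A window spanning local
    midnight (nocturnal species) keys the whole night to the date the window
    starts.  ``complete`` is True when no inter-fix gap exceeds ``max_gap_s``
    (default one hour): days with sparser coverage are excluded from daily
    distance summaries.
    """
    if traj.activity_window is None:
        raise SchemaError(
            f"{traj.individual_id}: no activity window configured "
            f"(species {traj.species!r})")
    start, end = traj.activity_window
    f = traj.fixes
    if len(f) == 0:
        return []
    local = _local_times(f, traj.tz_offset_h)
    tod = local.dt.time
    spans_midnight = start > end
    if spans_midnight:
        in_win = (tod >= start) | (tod <= end)
        key = local.dt.date.where(tod >= start,
                                  (local - timedelta(days=1)).dt.date)
    else:
        in_win = (tod >= start) & (tod <= end)
        key = local.dt.date

    out: list[DailyPath] = []
    sub = f[in_win.to_numpy()]
    for d, g in sub.groupby(key[in_win.to_numpy()], sort=True):
        g = g.reset_index(drop=True)
        gaps = g["timestamp"].diff().dt.total_seconds().iloc[1:]
        complete = bool((gaps <= max_gap_s).all()) if len(gaps) else True
        out.append(DailyPath(traj.individual_id, d, g, complete=complete))
    return out
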