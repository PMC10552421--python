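"""End-to-end pipeline: preprocess -> steps -> segment -> paths ->
lifephase -> syndromes, driven by a single config, with a run manifest.

Every stage writes a CSV into the output directory; the manifest records
versions, seeds, thresholds and per-stage row counts, including the
conservation check fixes_in = fixes_retained + fixes_flagged.  A rerun
with the same config and inputs is bit-identical.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, InsufficientDataError, DegenerateDataError
from .lifephase import life_phase_metrics, scale_mnsd_by_species
from .paths import path_metrics, species_mean_step
from .preprocess import ErrorModel, preprocess_trajectory
from .segmentation import segment_path
from .steps import compute_steps, fit_individual_steps
from .syndromes import individual_means, partition_all, pca_syndromes
from .trajectory_io import (
    Trajectory,
    assemble_daily_paths,
    read_tracking_csv,
    write_tracking_csv,
)

PATH_METRIC_COLS = ["distance", "straightness", "sinuosity",
                    "prop_cluster", "prop_ars"]
STEP_METRIC_COLS = ["gamma_k", "gamma_theta", "vm_mu", "vm_kappa"]
LIFE_METRIC_COLS = ["tac_mean", "residence_time_h", "time_to_return_h",
                    "vi", "mnsd_scaled"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every study constant surfaced here."""

    input_csv: str = ""
    out_dir: str = "msms_out"
    boundary: str | None = None          # GeoJSON or WKT file
    altitude_low: float | str = "auto"
    altitude_high: float | str = "auto"
    vmax: float = 3.0                    # m/s spike threshold
    error_mean_m: float = 5.46
    error_dispersion: float = 2.4
    stationarity_radius_m: float = 30.0
    fpt_radii_m: tuple[float, float] = (15.0, 30.0)
    fpt_window_s: float = 720.0
    residence_cutoff_h: float = 12.0
    min_path_fixes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.fpt_window_s <= 0 or \
                self.residence_cutoff_h <= 0 or self.min_path_fixes <= 0:
            raise ConfigurationError("all thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_boundary(path: str | Path):
    """Read a boundary polygon from a GeoJSON or WKT file."""
    from shapely import wkt as shapely_wkt
    from shapely.geometry import shape

    text = Path(path).read_text().strip()
    if text.startswith("{"):
        geo = json.loads(text)
        if geo.get("type") == "FeatureCollection":
            geo = geo["features"][0]["geometry"]
        elif geo.get("type") == "Feature":
            geo = geo["geometry"]
        return shape(geo)
    return shapely_wkt.loads(text)


def run_pipeline(config: RunConfig,
                 trajectories: list[Trajectory] | None = None) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    ``trajectories`` may be passed directly (e.g. from the simulator) to
    skip CSV ingestion.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()},
                      "stages": {}}

    # -- preprocess ---------------------------------------------------------
    if trajectories is None:
        trajectories = read_tracking_csv(config.input_csv)
    boundary = load_boundary(config.boundary) if config.boundary else None
    error_model = ErrorModel(config.error_mean_m, config.error_dispersion)
    rng = np.random.default_rng(config.seed)
    clean: list[Trajectory] = []
    n_in = n_flagged = n_retained = 0
    for traj in trajectories:
        c, reports = preprocess_trajectory(
            traj, boundary=boundary,
            altitude_low=config.altitude_low,
            altitude_high=config.altitude_high,
            vmax=config.vmax, error_model=error_model, rng=rng,
            stationarity_radius=config.stationarity_radius_m)
        from .trajectory_io import select_burst_last_fix
        burst = select_burst_last_fix(traj)
        flagged = sum(len(f) > 0 for f in burst.fixes["outlier_flags"])
        n_in += burst.n_fixes
        n_flagged += flagged
        n_retained += burst.n_fixes - flagged
        clean.append(c)
    assert n_in == n_retained + n_flagged
    write_tracking_csv(clean, out / "clean.csv")
    manifest["stages"]["preprocess"] = {
        "fixes_in": n_in, "fixes_flagged": n_flagged,
        "fixes_retained": n_retained,
        "individuals": len(clean)}

    # -- steps --------------------------------------------------------------
    step_rows = []
    step_series = {}
    for traj in clean:
        step_series[traj.individual_id] = compute_steps(traj)
        try:
            step_rows.append(fit_individual_steps(traj))
        except (InsufficientDataError, DegenerateDataError):
            continue
    stepfits = pd.DataFrame(step_rows)
    stepfits.to_csv(out / "stepfits.csv", index=False)
    manifest["stages"]["steps"] = {"individuals_fit": len(stepfits)}

    # -- species mean steps (for sinuosity rediscretization) ----------------
    sp_steps: dict[str, float] = {}
    for sp in sorted({t.species for t in clean}):
        pooled = {t.individual_id: step_series[t.individual_id].step_lengths
                  for t in clean if t.species == sp}
        sp_steps[sp] = species_mean_step(pooled)
    manifest["stages"]["species_mean_step_m"] = sp_steps

    # -- segmentation + daily path metrics ----------------------------------
    label_rows = []
    metric_rows = []
    for traj in clean:
        for path in assemble_daily_paths(traj):
            if path.n_fixes < 2:
                continue
            labels, basis = segment_path(path,
                                         window_s=config.fpt_window_s)
            for ts, lab, b in zip(path.fixes["timestamp"], labels, basis):
                label_rows.append({
                    "individual_id": traj.individual_id,
                    "timestamp": ts, "label": lab, "basis": b})
            pm = path_metrics(path, labels, sp_steps[traj.species],
                              min_fixes=config.min_path_fixes)
            metric_rows.append({
                "individual_id": traj.individual_id,
                "species": traj.species,
                "period_date": pm.period_date,
                "distance": pm.distance,
                "straightness": pm.straightness,
                "sinuosity": pm.sinuosity,
                "prop_cluster": pm.prop_cluster,
                "prop_ars": pm.prop_ars,
                "prop_travel": pm.prop_travel,
                "n_fixes": pm.n_fixes,
                "complete": pm.complete,
                "eligible": pm.eligible})
    pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
    daily = pd.DataFrame(metric_rows)
    daily.to_csv(out / "daily_metrics.csv", index=False)
    eligible = daily[daily["eligible"]].reset_index(drop=True) \
        if len(daily) else daily
    manifest["stages"]["paths"] = {
        "paths_total": len(daily), "paths_eligible": len(eligible)}

    # -- lifephase ----------------------------------------------------------
    life_rows = []
    for traj in clean:
        m = life_phase_metrics(traj, cutoff_h=config.residence_cutoff_h)
        life_rows.append({
            "individual_id": m.individual_id, "species": m.species,
            "tac": m.tac, "tac_mean": m.tac_mean,
            "residence_time_h": m.residence_time_h,
            "time_to_return_h": m.time_to_return_h,
            "vi": m.vi, "mnsd_m2": m.mnsd_m2,
            "home_range_ha": m.home_range_ha})
    life = pd.DataFrame(life_rows)
    if len(life):
        scaled = scale_mnsd_by_species(
            dict(zip(life["individual_id"], life["mnsd_m2"])),
            dict(zip(life["individual_id"], life["species"])))
        life["mnsd_scaled"] = life["individual_id"].map(scaled)
    life.to_csv(out / "lifephase.csv", index=False)
    manifest["stages"]["lifephase"] = {"individuals": len(life)}

    # -- syndromes ----------------------------------------------------------
    syn_dir = out / "syndromes"
    syn_dir.mkdir(exist_ok=True)
    summary: dict = {}

    def _analyse(name: str, table: pd.DataFrame, metrics: list[str]) -> None:
        metrics = [m for m in metrics if table[m].notna().any()]
        if len(metrics) < 2:
            summary[name] = "insufficient data"
            return
        table = table.dropna(subset=metrics)
        if len(table) < 3 or table["species"].nunique() < 2:
            summary[name] = "insufficient data"
            return
        vp = partition_all(table, metrics)
        vp.to_csv(syn_dir / f"variance_{name}.csv", index=False)
        space = pca_syndromes(table, metrics=metrics)
        pd.DataFrame(space.loadings, index=space.metrics).to_csv(
            syn_dir / f"loadings_{name}.csv")
        pd.DataFrame(space.scores, index=table.loc[space.index,
                                                   "individual_id"]).to_csv(
            syn_dir / f"scores_{name}.csv")
        summary[name] = {
            "retained_components": space.retained,
            "pct_variance_retained": space.cum_pct_retained,
            "pct_species_mean": float(vp["pct_species"].mean())}

    if len(stepfits):
        _analyse("step", stepfits, STEP_METRIC_COLS)
    if len(eligible):
        _analyse("path_daily", eligible, PATH_METRIC_COLS)
        _analyse("path_individual",
                 individual_means(eligible, PATH_METRIC_COLS),
                 PATH_METRIC_COLS)
    if len(life):
        _analyse("lifephase", life, LIFE_METRIC_COLS)
    with open(syn_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest["stages"]["syndromes"] = summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
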