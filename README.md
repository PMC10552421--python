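# msms — multi-scale movement syndromes

`msms` is a Python toolkit for movement ecologists who want to describe and
compare animal movement across its natural hierarchy of scales: fine-scale
**steps** accumulate into **daily paths**, which over weeks to months form a
**life-history phase** (e.g. a home range).  Starting from burst-mode GPS
collar tables (Movebank-style CSV), it cleans and reconstructs tracks,
computes scale-specific metrics, segments behaviour into *cluster* /
*area-restricted search (ARS)* / *travel*, and compares individuals and
species through variance partitioning and PCA "syndrome spaces".  A
multi-state movement simulator reproduces the whole observation process, so
every stage is testable without field data.

## The model in brief

**Steps.**  The analysis series is the last fix of each 1 Hz GPS burst, one
fix every 4 min.  Step lengths ℓ are fit by maximum likelihood to a Gamma
distribution with shape *k* and scale *θ* (metres); turn angles φ to a von
Mises distribution with mean direction *μ* and concentration *κ*.

**Daily paths.**  Each activity period (a day for diurnal species, a night
keyed to its start date for nocturnal ones) is summarised by five metrics:
total distance (Σ ℓᵢ), straightness (net / gross displacement, in (0, 1]),
corrected sinuosity S = 2·[p(1+c)/(1−c)]^(−1/2) on a path rediscretized at
the species mean step *p* (c = mean cosine of turn angles), and the
proportions of fixes in cluster and ARS behaviour.  Behaviour is labelled
from first passage time (FPT): a fix whose 15 m circle holds the track for
≥ 12 min is a cluster, one whose 30 m circle does is ARS, the rest are
travel.  Fixes near path edges, where FPT is censored, are imputed by Ward
clustering of correlated-velocity-model parameters (η = rms speed, τ =
velocity autocorrelation time) fitted by an exact Kalman-filter likelihood.

**Life-history phase.**  Five range-residency statistics: turn-angle
correlation, residence time and time-to-return (radius = mean step length,
12 h cut-off), volume of intersection of monthly 95 % kernel utilization
distributions, and maximum net squared displacement scaled by the species
minimum — plus the 95 % KDE isopleth as home-range area.

**Comparison.**  Per scale, a nested ANOVA partitions each metric's
variance into species and individual-within-species components, and a
correlation-matrix PCA (components retained at eigenvalue > 1) spans the
syndrome space in which individuals cluster.

## Worked example

Simulate a two-species study and push it through the full pipeline:

```python
import msms

study = msms.simulate_study(species=["kinkajou", "coati"],
                            n_per_species=4, days=10, seed=2)
cfg = msms.RunConfig(out_dir="demo_out", seed=2)
manifest = msms.run_pipeline(cfg, trajectories=study.trajectories)
print(manifest["stages"]["syndromes"]["path_individual"])
```

which prints (seed 2):

```
{'retained_components': 1, 'pct_variance_retained': 84.5128717490032,
 'pct_species_mean': 82.94079679558106}
```

i.e. a single principal component (eigenvalue > 1) carries ~85 % of the
variance in the per-individual daily-path metrics, and on average ~83 % of
each metric's variance sits at the species level — the nocturnal, sinuous,
cluster-heavy kinkajou regime separates cleanly from the search-heavy
coati regime.  Per-stage CSVs (`clean.csv`, `stepfits.csv`, `labels.csv`,
`daily_metrics.csv`, `lifephase.csv`, `syndromes/`) and a JSON manifest
land in `demo_out/`.

The same pipeline runs from the shell:

```bash
msms simulate --preset four-frugivores --days 14 --seed 42 --out sim/
msms run --config study.yaml
```

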