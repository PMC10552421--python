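# Methods

This note documents the models, estimators, defaults and design choices in
`msms`, and what its synthetic-data tests do and do not demonstrate.

## Data model and ingestion

Tracking tables arrive in Movebank-export dialect (configurable column
mapping).  All geometry is Euclidean in a planar metric frame: lon/lat
input is projected once at ingestion to the UTM zone of the data centroid.
The forward projection is the Karney/Krüger transverse-Mercator series,
6th order in the third flattening (sub-millimetre inside a zone); it is
implemented in-package and cross-checked in the test suite against an
independent Snyder-series formulation at < 1 cm.

Timestamps are stored as UTC; activity windows are evaluated on a local
clock at a configurable offset (default UTC−5, the study-site longitude).
Windows per species: kinkajou 23:00–06:30 (nocturnal, spanning midnight),
coati 06:00–18:30, capuchin and spider monkey 06:00–18:00.  A window that
spans midnight keys the whole night to the date it *starts*, so one
activity period is always one behavioural "day".  Duplicate timestamps are
flagged and the first occurrence kept — the choice is arbitrary but
deterministic.

Only the last fix of each 1 Hz burst enters analysis (it carries the best
horizontal accuracy in burst-mode collars); selection is idempotent and
fixes without a burst id pass through.

## Outlier screening

Screening is deterministic and ordered: duplicates → burst selection →
altitude → boundary → speed.  Flags never move a coordinate; removal is a
separate projection of unflagged fixes.

* **Altitude**: height-above-ellipsoid ≤ low or ≥ high.  `auto` derives
  the cut-offs per individual as Q1 − 2·IQR and Q3 + 2·IQR
  (linear-interpolation quartiles); for the study system these rules give
  21 m and 244 m.  With constant altitudes the interval degenerates to a
  point and everything is flagged — surfaced as a documented degenerate
  case rather than special-cased away.
* **Boundary**: strictly outside the study-area polygon (GeoJSON/WKT;
  shapely `covers`, so edges count as inside).
* **Speed**: a fix is a spike when *both* its incoming and outgoing
  straight-line speeds exceed `vmax` (default 3 m/s); a genuine fast
  transit yields a run of fast steps and is kept.  Additionally, fixes
  further from the individual's median location than 10× the 95th
  percentile of those distances are flagged.  This replaces interactive
  error screening with reproducible rules; both thresholds are exposed.

## Gap interpolation (ACC-informed collars)

Collars that suppress fixes while accelerometry reads "inactive" leave
gaps at stationary positions.  Gaps whose bounding fixes lie within a
stationarity radius (default 30 m, the cluster/ARS spatial grain) are
filled on the nominal 4-min grid, restricted to the activity window: each
missing slot gets an `INTERPOLATED` fix at the last observed position
displaced by an integer-metre radius drawn from a negative binomial (mean
5.46 m, dispersion/size 2.4 — the stationary-collar GPS error calibration)
at a uniform angle.  Gaps with endpoints further apart are left unfilled:
the animal moved, so the outage was not an inactivity dropout.  The
"dispersion parameter" is interpreted as the NB size (shape) parameter,
the only reading that names a single distribution with that mean; the
anchor is the last fix before the gap (the gap midpoint would be an
equally defensible, unimplemented alternative).  Interpolation only adds
fixes and is reproducible under a seed.

## Step-scale estimators

Step lengths: Gamma MLE via Newton's method on the profile score
log k − ψ(k) = log(mean) − mean(log), Minka initialisation, parameter
tolerance 1e-10; k·θ equals the sample mean exactly at the optimum.  Zeros
are excluded with a reported count (no atom at zero; stationary intervals
carry no length information).  Turn angles: von Mises MLE with μ̂ the
circular mean and κ̂ solving A₁(κ) = R̄ (Best–Fisher start, Newton
refinement), capped at κ = 500 to keep near-degenerate samples finite.
Zero-length steps have undefined headings; adjacent turn angles are
dropped (counted), never imputed.  Per-individual fits pool all steps over
the whole tracking period.

## Daily-path metrics

Distance is the sum of step lengths over a *complete* activity period (no
inter-fix gap above 1 h); straightness is net over gross displacement.
Sinuosity uses the corrected estimator S = 2·[p(1+c)/(1−c)]^(−1/2) with
*p* the rediscretization step and *c* the mean turn-angle cosine computed
on the rediscretized path (the convention of the trajectory packages this
estimator comes from); *p* defaults to the pooled mean step length of the
species in the current dataset, cached and reported.  Rediscretization
walks the piecewise-linear path by arc length from the first fix and
discards the trailing remainder.  *c* is clamped below 1 − 1e-12 so
dead-straight paths return S → 0 instead of dividing by zero.

Paths enter comparative summaries only when complete and holding ≥ 100
locations; the straightness metric is log-transformed where the syndrome
module standardises it (a per-metric transform flag, applied by default to
straightness only).

## Behavioural segmentation

First passage time at a fix is the summed backward and forward time the
track spends inside a circle centred there, with crossing times linearly
interpolated on the distance profile; it is censored (a lower bound) when
the track starts or ends inside the circle.  Labels for a 12-min (720 s)
window: FPT(15 m) ≥ 720 s → cluster; else FPT(30 m) ≥ 720 s → ARS; else
travel when the 30 m exit is observed.  A censored FPT that already
exceeds the window still decides (the bound suffices); a censored FPT
below it leaves the fix unlabelled.  "Moved less than 15 m in 12 min" is
thus operationalised as circle occupancy, which also guarantees that any
fix whose full 12-min neighbourhood fits in a 7.5 m ball is a cluster.

Unlabelled (edge) fixes get a correlated-velocity-model fit in a centred
sliding window of 31 fixes (~2 h; edge windows shrink, minimum 8 — the
window size is this package's choice, as is the centred alignment).  The
CVM is the integrated Ornstein–Uhlenbeck velocity process; its exact
Gaussian likelihood is evaluated by a 2-state Kalman filter per
coordinate, the velocity variance concentrated out analytically, and τ
profiled by bounded scalar optimisation on log τ (x- and y-components
share the parameters; process-noise terms use `expm1`/series forms to stay
stable for τ ≫ Δt).  η = √2·σ̂_v is the rms 2-D speed.  Imputation is
Ward-linkage clustering of the unlabelled records on standardized
(log η, log τ) — the two parameters differ by orders of magnitude, hence
the log/z-scoring — cut at three clusters and mapped to labels by
ascending mean η (slowest → cluster, fastest → travel).  With fewer than
three usable records the fall-back is the nearest labelled neighbour in
the same feature space.

## Life-history-phase metrics

* **Turn-angle correlation**: Σ wrap(φᵢ₊₁ − φᵢ)², reported both as the raw
  sum and as a per-pair mean; the comparative tables use the mean because
  the raw sum grows with track length.  Angular (wrapped) differences are
  used; a linear-difference reading of "distance between angles" was
  considered and rejected as dimensionally inconsistent.
* **Residence time** / **time-to-return**: event-scan over
  inside-the-circle intervals (radius = the individual's mean step length,
  cut-off 12 h), crossings linearly interpolated.  Excursions under the
  cut-off are bridged into the residence total; time-to-return is the
  duration of the first excursion exceeding the cut-off that ends in an
  observed re-entry, censored otherwise.  Both are per-fix means; tracks
  longer than 2,000 fixes are thinned to ≤ 2,000 evenly spaced centres,
  which trades Monte-Carlo precision for time without bias.
* **Utilization distribution**: plain Gaussian KDE (fine histogram +
  Gaussian filter), reference-rule bandwidth h = σ̄·n^(−1/6) with σ̄ the
  mean coordinate SD, cell h/4, extent padded 3h, renormalised to
  integrate to one.  Home range = 95 % isopleth area.  This deliberately
  replaces autocorrelation-corrected (AKDE-style) estimation, which is out
  of scope; KDE on autocorrelated fixes underestimates long-run ranges,
  so absolute areas should be read as occupancy of the tracking period.
* **Volume of intersection**: ∫ min(UD₁, UD₂) between calendar months with
  ≥ 200 fixes, resampled to a common grid over the intersection of their
  extents (the integrand vanishes elsewhere); the per-individual value is
  the mean over *consecutive* qualifying month pairs (stability reading;
  an all-pairs flag exists).
* **MNSD**: maximum squared displacement from the first relocation,
  scaled per species by the cohort minimum (the minimum individual maps
  to exactly 1).

## Comparison across individuals and species

The nested ANOVA decomposes each metric's total sum of squares into
species, individual-within-species, and residual; percentages are SS
fractions, and F tests the species mean square against the
individual-within-species mean square (individuals are the replicates).
No multiple-testing correction is applied.  PCA is on the correlation
matrix of the (optionally log-transformed) z-scored metrics; components
with eigenvalue > 1 are retained (Kaiser), the full spectrum is always
reported, and signs are fixed by making each component's largest-|loading|
metric positive.  Sample units per scale: per-individual distribution
parameters (step), per-day and per-individual-average tables (path),
per-individual (life-history).  Ward clustering of retained scores with a
silhouette readout stands in for identifying syndrome clusters by eye.

## Simulator

The generator is a discrete-time, three-state (cluster / ARS / travel)
Markov-switching correlated random walk on the 4-min tick: per state a
Gamma step length and a von Mises turn; home-range attraction blends the
heading unit vector with the unit vector toward a centre (weight *w*), a
biased CRW rather than an OU pull — simpler, and sufficient to induce
range residency.  The observation layer adds the collar process: bursts of
six 1 Hz fixes per tick, independent negative-binomial GPS error per fix,
species activity windows, and ACC-informed dropout of cluster-state bursts.
State dwell times come from the transition diagonal.

Species presets emulate the four-frugivore study system.  Their step
scales were calibrated once, at design time, so that the *emitted* (noisy,
last-of-burst) mean daily distances meet the study targets — kinkajou
3.3 km, coati 3.8 km, capuchin 3.7 km, spider monkey 3.1 km — because GPS
error inflates observed step sums by a state-dependent amount that is easier
to measure than to derive; attraction weights were likewise calibrated to
the reported home-range scale (kinkajou ≈ 30 ha, coati ≈ 150 ha, capuchin
≈ 120 ha).  Dropout 0.35 for the ACC-informed kinkajou and coati collars.
A separate `separated_regimes_config` provides long-dwell, well-separated
states (cluster nets ≪ 15 m per 12 min, ARS 15–30 m, travel ≫ 30 m) for
label-recovery validation.

What the simulator does *not* emulate: vertical (canopy) movement, social
interaction, serially correlated GPS error, habitat structure, or
continuous-time state switching.  Passing tests therefore demonstrate
correctness of the estimators under the stated observation model, not
robustness to every artefact of real field data.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulated studies of 2–4
species × 3–4 individuals × 10–14 days (≈ 25,000 emitted fixes pipeline-
wide), chosen as the smallest sizes at which the statistical checks are
stable; distribution-recovery checks use 10,000 draws, the KDE contour
calibration 50,000.  A 14-day spider-monkey track cannot cover that
species' full multi-hundred-hectare range, so its simulated home range
reads low relative to the preset's real-world counterpart — an expected
consequence of the short window, not a calibration target.  Key numeric
defaults: Gamma/von Mises parameter tolerances 1e-10/1e-12, κ cap 500,
CVM τ search within [Δt/20, 2000·Δt], sinuosity cosine clamp 1 − 1e-12,
UD normalisation tolerance 1e-6.

## Known limitations

* KDE (not autocorrelation-corrected) home ranges; absolute areas biased
  low for strongly autocorrelated tracks.
* FPT labels depend on the 15/30 m and 12-min constants; they are exposed
  in `RunConfig` but the defaults encode a feeding-bout definition
  specific to large-crowned fruiting trees.
* The ANOVA is a fixed-effects SS decomposition, not a REML variance-
  component model; percentages are descriptive.
* The manual-screening surrogate (spike + median-distance rules) will not
  reproduce the judgement calls of an interactive workflow on edge cases.
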