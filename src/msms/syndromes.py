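"""Cross-individual and cross-species comparison of movement metrics.

Two complementary views per movement scale: (1) a nested analysis of
variance that splits each metric's variation into a species component and
an individual-within-species component, and (2) a correlation-matrix PCA
of the standardized metrics whose retained components (eigenvalue > 1,
Kaiser rule) span the "syndrome space" in which individuals may cluster.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f as f_dist
from sklearn.metrics import silhouette_score

from .exceptions import ConfigurationError, DegenerateDataError

#: metrics log-transformed before standardization by default
DEFAULT_LOG_METRICS = ("straightness",)


@dataclass
class VariancePartition:
    """Nested sums-of-squares decomposition for one metric."""

    metric: str
    pct_species: float
    pct_individual: float
    F: float
    df1: int
    df2: int
    p: float


def variance_partition(table: pd.DataFrame, metric: str,
                       species_col: str = "species",
                       individual_col: str = "individual_id"
                       ) -> VariancePartition:
    """Percent of a metric's variation attributable to species vs individual.

    Nested decomposition: total SS = SS(species) + SS(individual within
    species) + SS(residual); the percentages are SS fractions of the
    total.  F tests the species effect against the individual-within-
    species mean square (the correct error stratum when individuals are
    the replicates).
    """
    sub = table[[species_col, individual_col, metric]].dropna()
    y = sub[metric].to_numpy(dtype=float)
    if len(y) == 0:
        raise DegenerateDataError(f"no data for metric {metric!r}")
    species = sub[species_col].to_numpy()
    if len(np.unique(species)) < 2:
        raise DegenerateDataError("species effect needs >= 2 species")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        raise DegenerateDataError(f"metric {metric!r} has zero variance")

    ss_sp = 0.0
    ss_ind = 0.0
    n_ind = 0
    for sp in np.unique(species):
        ys = y[species == sp]
        inds = sub.loc[sub[species_col] == sp, individual_col].to_numpy()
        ss_sp += len(ys) * (ys.mean() - grand) ** 2
        for ind in np.unique(inds):
            yi = ys[inds == ind]
            ss_ind += len(yi) * (yi.mean() - ys.mean()) ** 2
            n_ind += 1
    n_sp = len(np.unique(species))
    df1 = n_sp - 1
    df2 = n_ind - n_sp
    if df2 <= 0:
        raise DegenerateDataError("need replicate individuals within species")
    ms_sp = ss_sp / df1
    ms_ind = ss_ind / df2
    F = ms_sp / ms_ind if ms_ind > 0 else np.inf
    p = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return VariancePartition(
        metric=metric,
        pct_species=100.0 * ss_sp / ss_total,
        pct_individual=100.0 * ss_ind / ss_total,
        F=float(F), df1=df1, df2=df2, p=p)


# ---------------------------------------------------------------------------
# PCA syndrome space

@dataclass
class SyndromeSpace:
    """Correlation-matrix PCA of one scale's metric table."""

    metrics: list[str]
    loadings: np.ndarray          # metrics x components
    scores: np.ndarray            # units x components
    eigenvalues: np.ndarray
    retained: int
    pct_variance: np.ndarray      # per component, %
    index: pd.Index = field(default_factory=lambda: pd.Index([]))
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, :self.retained]

    @property
    def cum_pct_retained(self) -> float:
        return float(self.pct_variance[:self.retained].sum())


def pca_syndromes(table: pd.DataFrame,
                  metrics: list[str] | None = None,
                  log_metrics: tuple[str, ...] = DEFAULT_LOG_METRICS
                  ) -> SyndromeSpace:
    """Standardized (correlation-matrix) PCA over a metric table.

    Rows with any missing metric are dropped; configured metrics (by
    default straightness) are log-transformed before z-scoring; constant
    columns are dropped with a record.  Components with eigenvalue > 1
    are retained (Kaiser).  Sign convention: in each component the metric
    with the largest |loading| loads positive.
    """
    if metrics is None:
        metrics = [c for c in table.columns
                   if table[c].dtype.kind in "fc"]
    sub = table[metrics].copy()
    for m in log_metrics:
        if m in sub.columns:
            vals = sub[m].to_numpy(dtype=float)
            if np.nanmin(vals) <= 0:
                vals = vals - np.nanmin(vals) + 1e-12
            sub[m] = np.log(vals)
    sub = sub.dropna()
    if len(sub) < 3:
        raise DegenerateDataError("PCA needs >= 3 complete rows")
    dropped = [m for m in sub.columns if np.std(sub[m].to_numpy(float)) == 0]
    if dropped:
        import warnings
        warnings.warn(f"dropping constant metric column(s): {dropped}")
        sub = sub.drop(columns=dropped)
    kept = list(sub.columns)
    if len(kept) < 2:
        raise DegenerateDataError("PCA needs >= 2 non-constant metrics")

    X = sub.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        lead = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Z @ evecs
    retained = max(int(np.sum(evals > 1.0)), 1)
    pct = 100.0 * evals / evals.sum()
    return SyndromeSpace(
        metrics=kept,
        loadings=evecs,
        scores=scores,
        eigenvalues=evals,
        retained=retained,
        pct_variance=pct,
        index=sub.index,
        dropped_constant=dropped)


def cluster_individuals(space: SyndromeSpace, k: int
                        ) -> tuple[np.ndarray, float]:
    """Ward clustering of units on the retained component scores.

    Returns (cluster assignments 1..k, silhouette score).  The paper-style
    use is k=3 on per-individual averages to recover the syndromes that a
    reader would otherwise draw by eye on the PCA plot.
    """
    X = space.retained_scores
    n = len(X)
    if not (2 <= k <= n - 1):
        raise ConfigurationError(f"k must be in [2, {n - 1}], got {k}")
    link = linkage(X, method="ward")
    assign = fcluster(link, t=k, criterion="maxclust")
    sil = float(silhouette_score(X, assign)) if len(np.unique(assign)) > 1 \
        else np.nan
    return assign, sil


# ---------------------------------------------------------------------------
# table assembly helpers

def partition_all(table: pd.DataFrame, metrics: list[str],
                  **kwargs) -> pd.DataFrame:
    """Variance partition for each metric, as one tidy DataFrame."""
    rows = []
    for m in metrics:
        vp = variance_partition(table, m, **kwargs)
        rows.append({"metric": m, "pct_species": vp.pct_species,
                     "pct_individual": vp.pct_individual, "F": vp.F,
                     "df1": vp.df1, "df2": vp.df2, "p": vp.p})
    return pd.DataFrame(rows)


def individual_means(daily_table: pd.DataFrame, metrics: list[str],
                     species_col: str = "species",
                     individual_col: str = "individual_id") -> pd.DataFrame:
    """Average per-day metrics into one row per individual."""
    g = daily_table.groupby([individual_col, species_col])[metrics].mean()
    return g.reset_index()
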