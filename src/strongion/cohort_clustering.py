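"""Exploratory clustering of a cohort into physiological states.

Pipeline: pick a segmentation base (a short, physiologically prioritized
variable list pruned so that no retained pair has |Pearson rho| >= 0.75 and
at most one variable per ten observations survives), z-score it, compute
Euclidean distances, agglomerate with Ward's minimum-variance method
(Ward.D2 dialect: Euclidean input distances with the Lance-Williams Ward
update), and choose the number of clusters by maximal mean silhouette width
over a candidate range. Per-cluster median/quartile profiles and
centered/scaled medians are emitted for heatmap-style inspection.

The cluster-number choice mechanizes only the internal-validity criterion;
judging interpretability of competing partitions remains a human step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SEGMENTATION_VARIABLES", "SegmentationConfig", "ClusteringResult",
    "select_segmentation_base", "standardize", "ward_cluster", "choose_k",
    "cluster_profiles", "run_clustering",
]

#: Default segmentation base, in physiological priority order: the dependent
#: acid-base outcome (temperature-corrected pH), the independent strong-ion
#: determinants, dilution markers, energy-balance/unmeasured-ion markers, and
#: the urinary excretion variables.
DEFAULT_SEGMENTATION_VARIABLES = [
    "pH_BT", "Atot_alb", "SID_m5", "AGR", "Hct",
    "cBHB", "cNEFA", "SIG_prt", "cNa_u", "cCl_u", "BAR",
]


@dataclass(frozen=True)
class SegmentationConfig:
    candidate_variables: Sequence[str] = tuple(DEFAULT_SEGMENTATION_VARIABLES)
    max_vars_per_obs: float = 0.1          # at most one variable per 10 observations
    correlation_threshold: float = 0.75    # retained pairs must have |rho| below this
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.candidate_variables:
            raise ValueError("candidate_variables must be non-empty")
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ValueError("correlation_threshold must be in (0, 1]")


def select_segmentation_base(data: pd.DataFrame,
                             config: SegmentationConfig = SegmentationConfig()) -> list[str]:
    """Prune the candidate list to an uncorrelated segmentation base.

    Candidates are visited in priority order; a candidate is kept only while
    its absolute Pearson correlation with every already-kept variable stays
    below the threshold and the size cap floor(n_obs * max_vars_per_obs) is
    not exhausted. Later-listed (lower-priority) variables lose.
    """
    missing = [v for v in config.candidate_variables if v not in data.columns]
    if missing:
        raise ValueError(f"candidate variables not in data: {missing}")
    sub = data[list(config.candidate_variables)]
    for v in config.candidate_variables:
        if not pd.api.types.is_numeric_dtype(sub[v]):
            raise ValueError(f"candidate variable {v!r} is not numeric")
        frac = sub[v].isna().mean()
        if frac >= config.max_missing_fraction:
            raise ValueError(f"candidate variable {v!r} has {frac:.0%} missing values")
    cap = max(1, int(np.floor(len(sub) * config.max_vars_per_obs)))
    corr = sub.corr(method="pearson").abs()
    kept: list[str] = []
    for v in config.candidate_variables:
        if len(kept) == cap:
            logger.info("segmentation cap of %d variables reached", cap)
            break
        if all(corr.loc[v, k] < config.correlation_threshold for k in kept):
            kept.append(v)
        else:
            clash = [k for k in kept if corr.loc[v, k] >= config.correlation_threshold]
            logger.info("dropping %r (|rho| >= %.2f with %s)",
                        v, config.correlation_threshold, clash)
    return kept


def standardize(data: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each column (sample standard deviation, n-1 divisor)."""
    sd = data.std(ddof=ddof)
    flat = sd[(sd == 0) | sd.isna()].index.tolist()
    if flat:
        raise ValueError(f"zero-variance column(s) cannot be standardized: {flat}")
    return (data - data.mean()) / sd


def ward_cluster(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage (Ward.D2) on Euclidean distances.

    Returns the (n-1, 4) merge table: children, merge height, cluster size.
    Heights are non-decreasing (ultrametric property of Ward's criterion).
    """
    x = np.asarray(z, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    if np.isnan(x).any():
        raise ValueError("missing values in clustering input; drop or impute rows first")
    return linkage(x, method="ward", metric="euclidean")


def choose_k(linkage_matrix: np.ndarray, z: pd.DataFrame | np.ndarray,
             k_range: Sequence[int]) -> tuple[int, pd.DataFrame, dict[int, np.ndarray]]:
    """Pick the cluster number maximizing mean silhouette width.

    Returns ``(chosen_k, silhouette_table, labels_by_k)`` where the table has
    one row per candidate k with its mean silhouette width. Ties break toward
    smaller k. Silhouettes are computed on the same standardized Euclidean
    space the tree was grown in.
    """
    k_range = sorted(set(int(k) for k in k_range))
    x = np.asarray(z, dtype=float)
    n = x.shape[0]
    if not k_range:
        raise ValueError("k_range is empty")
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rows, labels_by_k, widths = [], {}, {}
    for k in k_range:
        lab = fcluster(linkage_matrix, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:  # degenerate cut (duplicate points)
            mean_w, w = float("nan"), np.full(n, np.nan)
        else:
            w = silhouette_samples(x, lab, metric="euclidean")
            mean_w = float(w.mean())
        widths[k] = w
        rows.append({"k": k, "mean_silhouette": mean_w,
                     "n_clusters_realized": int(len(np.unique(lab)))})
    table = pd.DataFrame(rows).set_index("k")
    valid = table["mean_silhouette"].dropna()
    if valid.empty:
        raise ValueError("no candidate k produced a valid silhouette")
    chosen = int(valid.idxmax())  # idxmax returns the first (smallest) maximizer
    return chosen, table, labels_by_k


def cluster_profiles(data: pd.DataFrame, labels: Sequence[int]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster median/Q1/Q3 profiles and centered/scaled medians.

    ``profiles`` is indexed by (cluster, variable) with columns median/q1/q3.
    ``scaled_medians`` has one row per cluster and one column per variable:
    (cluster median - overall median) / overall IQR; variables with zero
    overall IQR get NaN (degenerate scale flag) rather than raising.
    """
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels must partition the rows of data")
    num = data.select_dtypes(include=[np.number])
    recs = []
    for cl in np.unique(labels):
        sub = num[labels == cl]
        if sub.empty:
            raise ValueError(f"cluster {cl} is empty")
        q = sub.quantile([0.25, 0.5, 0.75])
        for v in num.columns:
            recs.append({"cluster": cl, "variable": v, "median": q.loc[0.5, v],
                         "q1": q.loc[0.25, v], "q3": q.loc[0.75, v]})
    profiles = pd.DataFrame(recs).set_index(["cluster", "variable"])
    overall_med = num.median()
    iqr = num.quantile(0.75) - num.quantile(0.25)
    scale = iqr.replace(0.0, np.nan)
    med = profiles["median"].unstack("variable")[num.columns]
    scaled = (med - overall_med) / scale
    return profiles, scaled


@dataclass
class ClusteringResult:
    """Full output of the clustering pipeline."""

    variables: list[str]
    linkage: np.ndarray
    chosen_k: int
    labels: np.ndarray
    labels_by_k: dict[int, np.ndarray]
    silhouette_table: pd.DataFrame
    silhouette_widths: np.ndarray
    profiles: pd.DataFrame
    scaled_medians: pd.DataFrame
    dropped_rows: int = 0
    row_index: pd.Index = field(default_factory=lambda: pd.Index([]))

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def run_clustering(data: pd.DataFrame,
                   config: SegmentationConfig = SegmentationConfig(),
                   k_range: Sequence[int] = range(2, 13)) -> ClusteringResult:
    """Select, standardize, agglomerate, validate and profile in one call.

    Rows with missing values in the selected segmentation variables are
    dropped (with a logged count) before standardization; profiles are
    computed over all numeric columns of the retained rows.
    """
    variables = select_segmentation_base(data, config)
    sub = data.dropna(subset=variables)
    dropped = len(data) - len(sub)
    if dropped:
        logger.info("dropped %d row(s) with missing segmentation values", dropped)
    z = standardize(sub[variables])
    lm = ward_cluster(z)
    chosen, table, labels_by_k = choose_k(lm, z, k_range)
    labels = labels_by_k[chosen]
    widths = silhouette_samples(np.asarray(z, dtype=float), labels, metric="euclidean")
    profiles, scaled = cluster_profiles(sub, labels)
    return ClusteringResult(
        variables=variables, linkage=lm, chosen_k=chosen, labels=labels,
        labels_by_k=labels_by_k, silhouette_table=table,
        silhouette_widths=widths, profiles=profiles, scaled_medians=scaled,
        dropped_rows=dropped, row_index=sub.index)
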