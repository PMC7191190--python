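"""Consensus clustering of tumors over immune CpGs, methylation centroids,
and nearest-centroid classification by Kendall rank correlation.

Consensus clustering follows the Monti resampling scheme: repeatedly
subsample the cohort, cluster each subsample hierarchically (Ward
linkage on Euclidean distance) at the requested k, and record how often
each co-sampled pair of tumors lands in the same cluster.  Final labels
come from average-linkage hierarchical clustering of 1 − consensus.
Clusters are renumbered 1..k by ascending mean β over the clustering
CpGs, so cluster 1 is always the least-methylated (immune-rich) group.

Centroids are per-cluster median β vectors over the immune CpGs that
differ across clusters (Kruskal-Wallis, BH-FDR below 1e-4).  A new
sample is assigned to the centroid with the highest Kendall τ-b,
provided that correlation reaches 0.3; otherwise it is unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau, kruskal
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConsensusSettings",
    "ConsensusResult",
    "CentroidSet",
    "ClusterAssignment",
    "consensus_cluster",
    "build_centroids",
    "classify_by_centroid",
    "classify_cohort",
]


@dataclass
class ConsensusSettings:
    subsample_fraction: float = 0.8
    n_iterations: int = 1000
    linkage_method: str = "ward"
    seed: int = 0


@dataclass
class ConsensusResult:
    labels: pd.Series  # sample -> 1..k
    consensus_matrix: pd.DataFrame
    k: int
    settings: ConsensusSettings


@dataclass
class CentroidSet:
    medians: pd.DataFrame  # centroid CpGs x clusters
    kw_table: pd.DataFrame  # per-CpG KW p and FDR over the immune CpG set
    kw_fdr_threshold: float = 1e-4
    classify_threshold: float = 0.3

    @property
    def centroid_cpgs(self) -> pd.Index:
        return self.medians.index


@dataclass
class ClusterAssignment:
    sample: str
    tau_per_cluster: pd.Series
    assigned: int | str  # cluster index, or "unclassified"
    reason: str | None = None


def _prepare_matrix(beta: pd.DataFrame) -> np.ndarray:
    """Samples x CpGs array; per-CpG median imputation for stray missing."""
    if beta.isna().all(axis=1).any():
        bad = beta.index[beta.isna().all(axis=1)].tolist()
        raise ValueError(f"all-missing CpGs: {bad[:5]}")
    x = beta.to_numpy(dtype=float).T
    if np.isnan(x).any():
        med = np.nanmedian(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = med[idx[1]]
    return x


def consensus_cluster(
    beta: pd.DataFrame, k: int, settings: ConsensusSettings | None = None
) -> ConsensusResult:
    """Monti-style consensus clustering of samples (columns of ``beta``)."""
    settings = settings or ConsensusSettings()
    n = beta.shape[1]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} samples for k={k}, have {n}")
    x = _prepare_matrix(beta)
    rng = np.random.default_rng([settings.seed, 4])
    m = max(k + 1, int(round(settings.subsample_fraction * n)))

    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(settings.n_iterations):
        idx = rng.choice(n, size=m, replace=False)
        z = linkage(x[idx], method=settings.linkage_method)
        lab = fcluster(z, t=k, criterion="maxclust")
        same = lab[:, None] == lab[None, :]
        together[np.ix_(idx, idx)] += same
        sampled[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1.0), 0.0)
    np.fill_diagonal(consensus, 1.0)

    z = linkage(squareform(1.0 - consensus, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber so cluster 1 has the lowest mean methylation
    order = np.argsort(
        [x[raw == c].mean() for c in range(1, k + 1)]
    )
    remap = {int(c + 1): int(rank + 1) for rank, c in enumerate(order)}
    labels = pd.Series(
        [remap[int(c)] for c in raw], index=beta.columns, name="cluster"
    )
    cm = pd.DataFrame(consensus, index=beta.columns, columns=beta.columns)
    return ConsensusResult(labels=labels, consensus_matrix=cm, k=k, settings=settings)


def build_centroids(
    beta: pd.DataFrame,
    labels: pd.Series,
    immune_cpgs,
    kw_fdr_threshold: float = 1e-4,
    classify_threshold: float = 0.3,
) -> CentroidSet:
    """Per-cluster median β over immune CpGs that separate the clusters.

    Each CpG in ``immune_cpgs`` is screened with a Kruskal-Wallis test
    across cluster labels; BH-FDR is computed over the whole set and
    CpGs below the threshold are retained.
    """
    labels = labels.loc[beta.columns]
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need at least 2 clusters with >= 3 samples each")
    cpgs = pd.Index(immune_cpgs).intersection(beta.index)
    if cpgs.empty:
        raise ValueError("none of the immune CpGs are present in the matrix")

    clusters = sorted(counts.index)
    group_cols = {c: beta.columns[(labels == c).to_numpy()] for c in clusters}
    pvals = []
    for cpg in cpgs:
        samples = [beta.loc[cpg, group_cols[c]].dropna().to_numpy() for c in clusters]
        if any(len(s) == 0 for s in samples) or np.ptp(np.concatenate(samples)) == 0:
            pvals.append(1.0)  # constant CpG carries no rank information
            continue
        try:
            pvals.append(float(kruskal(*samples).pvalue))
        except ValueError:  # all values identical -> no evidence
            pvals.append(1.0)
    kw = pd.DataFrame({"p": pvals}, index=cpgs)
    kw["fdr"] = multipletests(kw["p"], method="fdr_bh")[1]
    retained = kw.index[kw["fdr"] < kw_fdr_threshold]
    if retained.empty:
        raise ValueError(
            "no CpG passes the Kruskal-Wallis FDR gate "
            f"(min FDR {kw['fdr'].min():.3g} vs threshold {kw_fdr_threshold:g})"
        )
    medians = pd.DataFrame(
        {c: beta.loc[retained, group_cols[c]].median(axis=1) for c in clusters}
    )
    medians.columns.name = "cluster"
    return CentroidSet(
        medians=medians,
        kw_table=kw,
        kw_fdr_threshold=kw_fdr_threshold,
        classify_threshold=classify_threshold,
    )


def classify_by_centroid(
    sample_beta: pd.Series,
    centroids: CentroidSet,
    min_cpgs: int = 10,
) -> ClusterAssignment:
    """Assign one sample to the centroid with the highest Kendall τ-b.

    Pairwise-complete over centroid CpGs; requires ``min_cpgs``
    informative CpGs.  Assignment needs max τ ≥ the classification
    threshold (0.3), otherwise "unclassified".  Exact τ ties go to the
    lowest cluster index with a warning.
    """
    name = str(sample_beta.name) if sample_beta.name is not None else "sample"
    common = centroids.medians.index.intersection(sample_beta.index)
    taus = pd.Series(np.nan, index=centroids.medians.columns, name="tau")
    if common.empty:
        return ClusterAssignment(name, taus, "unclassified", reason="no_overlap")
    v = sample_beta.loc[common].to_numpy(dtype=float)
    for c in centroids.medians.columns:
        w = centroids.medians.loc[common, c].to_numpy(dtype=float)
        ok = ~(np.isnan(v) | np.isnan(w))
        if ok.sum() < min_cpgs:
            continue
        taus[c] = kendalltau(v[ok], w[ok]).statistic
    if taus.isna().all():
        return ClusterAssignment(name, taus, "unclassified", reason="too_few_cpgs")
    best = taus.max()
    if not best >= centroids.classify_threshold:
        return ClusterAssignment(name, taus, "unclassified", reason="low_correlation")
    winners = taus.index[taus == best]
    if len(winners) > 1:
        warnings.warn(
            f"τ tie for sample {name}; assigning lowest cluster index", stacklevel=2
        )
    return ClusterAssignment(name, taus, int(min(winners)))


def classify_cohort(
    beta: pd.DataFrame, centroids: CentroidSet, min_cpgs: int = 10
) -> pd.DataFrame:
    """Classify every column of ``beta``; one row per sample with τ columns."""
    rows = []
    for sample in beta.columns:
        a = classify_by_centroid(beta[sample], centroids, min_cpgs=min_cpgs)
        row = {f"tau_{c}": a.tau_per_cluster[c] for c in a.tau_per_cluster.index}
        row["assigned"] = a.assigned
        row["reason"] = a.reason or ""
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(beta.columns, name="sample_id"))
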