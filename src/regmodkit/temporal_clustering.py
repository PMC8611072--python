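"""K-means clustering of temporal profiles and cluster-cluster enrichment.

Regulated features are summarized as z-scored per-day mean profiles and
partitioned by Euclidean k-means (default k=5, best of 50 restarts).
Cluster labels are renumbered so that cluster mean-profile peak days are
non-decreasing — cluster 1 peaks earliest — with ties broken by the
temporal center of mass, making the labels sequential and reproducible.

The gene-cluster x DHS-cluster enrichment matrix counts, for each gene
cluster Gi, the regulated DHSs of each temporal class Ej whose midpoint
lies within a window (default +/-50 kb) of any Gi gene's TSS, compares the
count to the expectation under the marginal class shares, and reports the
log2 observed/expected ratio (pseudocount 0.5) with a chi-square test on
the corresponding 2x2 table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from .io_formats import GenomicInterval

__all__ = [
    "ClusteringResult",
    "EnrichmentMatrix",
    "zscore_profiles",
    "kmeans_profiles",
    "cluster_enrichment_matrix",
]


@dataclass
class ClusteringResult:
    assignments: pd.Series  # feature_id -> cluster label (1..k)
    zprofiles: pd.DataFrame  # feature x day z-scored profiles
    centers: np.ndarray  # k x n_days cluster mean z-profiles (renumbered)
    inertia: float
    restart_inertias: np.ndarray


@dataclass
class EnrichmentMatrix:
    observed: pd.DataFrame  # gene_cluster x dhs_cluster
    expected: pd.DataFrame
    log2_ratio: pd.DataFrame
    chi2_p: pd.DataFrame
    low_expected: pd.DataFrame  # cells with expected < 5


def zscore_profiles(day_means: pd.DataFrame) -> pd.DataFrame:
    """z-score per-day mean profiles per feature (population SD).

    Constant profiles cannot be z-scored and are dropped with a warning;
    regulated-feature filters upstream normally remove them already.
    """
    values = day_means.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant profile(s) before z-scoring")
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    return pd.DataFrame(z, index=day_means.index[keep], columns=day_means.columns)


def _order_labels(centers: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Permutation of cluster indices by (peak day, center of mass)."""
    peak = days[np.argmax(centers, axis=1)]
    w = centers - centers.min(axis=1, keepdims=True)
    wsum = w.sum(axis=1)
    com = np.where(wsum > 0, (w * days).sum(axis=1) / np.where(wsum > 0, wsum, 1.0), 0.0)
    return np.lexsort((np.arange(len(peak)), com, peak))


def kmeans_profiles(
    zprofiles: pd.DataFrame, k: int = 5, n_restarts: int = 50, seed: int = 0
) -> ClusteringResult:
    """Euclidean k-means over z-profiles, best of ``n_restarts`` by inertia.

    Labels are 1..k ordered by cluster peak time (cluster 1 earliest).
    Deterministic for a given seed.
    """
    X = zprofiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite z-profiles")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of features ({X.shape[0]})")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best = None
    inertias = np.empty(n_restarts)
    for r in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(seeds[r] % (2**31)),
                    algorithm="lloyd").fit(X)
        inertias[r] = km.inertia_
        if best is None or km.inertia_ < best.inertia_:
            best = km
    days = np.asarray(zprofiles.columns, dtype=float)
    order = _order_labels(best.cluster_centers_, days)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[best.labels_]
    centers = best.cluster_centers_[order]
    return ClusteringResult(
        assignments=pd.Series(labels, index=zprofiles.index, name="cluster"),
        zprofiles=zprofiles,
        centers=centers,
        inertia=float(best.inertia_),
        restart_inertias=inertias,
    )


def cluster_enrichment_matrix(
    gene_clusters: pd.Series,
    dhs_clusters: pd.Series,
    annotation: pd.DataFrame,
    intervals: list[GenomicInterval],
    window: int = 50_000,
) -> EnrichmentMatrix:
    """Enrichment of DHS temporal classes near each gene cluster's TSSs.

    observed(Gi, Ej) counts regulated DHSs of class Ej with midpoint within
    +/-``window`` of any Gi gene TSS; expected(Gi, Ej) distributes Gi's
    in-window total across classes by their overall shares.
    """
    ann = annotation.set_index("gene_id")
    mid = {iv.id: (iv.chrom, iv.midpoint) for iv in intervals}
    missing = [d for d in dhs_clusters.index if d not in mid]
    if missing:
        raise ValueError(f"DHS ids without intervals: {missing[:10]}")
    gene_labels = sorted(gene_clusters.unique())
    dhs_labels = sorted(dhs_clusters.unique())
    n_dhs = len(dhs_clusters)
    share = {e: (dhs_clusters == e).sum() / n_dhs for e in dhs_labels}

    # per gene cluster: sorted TSS positions per chromosome
    tss_by_cluster: dict = {}
    for g in gene_labels:
        genes = gene_clusters.index[gene_clusters == g]
        sub = ann.loc[ann.index.intersection(genes)]
        tss_by_cluster[g] = {
            chrom: np.sort(grp["tss"].to_numpy()) for chrom, grp in sub.groupby("chrom")
        }

    dhs_ids = dhs_clusters.index.to_numpy()
    dhs_class = dhs_clusters.to_numpy()
    in_window = {}
    for g in gene_labels:
        flags = np.zeros(n_dhs, dtype=bool)
        tss_map = tss_by_cluster[g]
        for i, d in enumerate(dhs_ids):
            chrom, m = mid[d]
            tss = tss_map.get(chrom)
            if tss is None or len(tss) == 0:
                continue
            lo = np.searchsorted(tss, m - window, side="left")
            hi = np.searchsorted(tss, m + window, side="right")
            flags[i] = hi > lo
        in_window[g] = flags

    obs = pd.DataFrame(0.0, index=gene_labels, columns=dhs_labels)
    exp = pd.DataFrame(np.nan, index=gene_labels, columns=dhs_labels)
    l2r = pd.DataFrame(np.nan, index=gene_labels, columns=dhs_labels)
    chi2p = pd.DataFrame(np.nan, index=gene_labels, columns=dhs_labels)
    lowexp = pd.DataFrame(False, index=gene_labels, columns=dhs_labels)
    for g in gene_labels:
        flags = in_window[g]
        total_in = int(flags.sum())
        if total_in == 0:
            warnings.warn(f"gene cluster {g}: no in-window DHSs; row set to NA")
            obs.loc[g] = np.nan
            continue
        for e in dhs_labels:
            is_e = dhs_class == e
            o = int((flags & is_e).sum())
            x = total_in * share[e]
            obs.loc[g, e] = o
            exp.loc[g, e] = x
            l2r.loc[g, e] = np.log2((o + 0.5) / (x + 0.5))
            table = np.array(
                [
                    [o, total_in - o],
                    [int(is_e.sum()) - o, n_dhs - total_in - int(is_e.sum()) + o],
                ]
            )
            if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                chi2p.loc[g, e] = chi2_contingency(table, correction=False)[1]
            lowexp.loc[g, e] = x < 5
    return EnrichmentMatrix(obs, exp, l2r, chi2p, lowexp)
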