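"""Hypergeometric motif enrichment per temporal DHS cluster.

A TF motif is "present" in a DHS when it has at least one hit.  For each
(TF, cluster) pair the over-representation p-value is the upper tail
P[X >= k] of Hypergeometric(N=universe size, K=DHSs with the motif,
n=cluster size); the under-representation p-value is the lower tail
P[X <= k].  Over-representation p-values are Benjamini-Hochberg adjusted
across all (TF, cluster) pairs.

The universe defaults to the clustered (changing) DHSs; all detected DHSs
can be used instead.  An optional motif -> group map collapses individual
motifs into archetype groups before testing (presence = any member motif).
"""
from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import MotifHitTable

__all__ = ["motif_cluster_enrichment"]


def motif_cluster_enrichment(
    hits: MotifHitTable,
    clusters: pd.Series,
    universe: str = "changing",
    all_dhs_ids: list[str] | None = None,
    motif_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Test over/under-representation of each TF motif in each cluster.

    Parameters
    ----------
    hits
        Aggregated motif hit table.
    clusters
        Series mapping clustered DHS ids to cluster labels.
    universe
        "changing" (the clustered set, default) or "all" (requires
        ``all_dhs_ids``).
    motif_groups
        Optional map tf_name -> group name; rows are then per group.
    """
    if len(clusters) == 0:
        raise ValueError("empty universe: no clustered DHSs")
    if universe == "changing":
        universe_ids = list(clusters.index)
    elif universe == "all":
        if not all_dhs_ids:
            raise ValueError("universe='all' requires all_dhs_ids")
        universe_ids = list(all_dhs_ids)
        missing = set(clusters.index) - set(universe_ids)
        if missing:
            raise ValueError(f"cluster ids outside universe: {sorted(missing)[:10]}")
    else:
        raise ValueError(f"unknown universe {universe!r}")

    table = hits.table
    if motif_groups is not None:
        table = table.assign(tf_name=table["tf_name"].map(lambda t: motif_groups.get(t, t)))
        table = table.groupby(["dhs_id", "tf_name"], as_index=False)["hit_count"].sum()
    universe_set = set(universe_ids)
    present = table[(table["hit_count"] >= 1) & table["dhs_id"].isin(universe_set)]
    by_tf = {t: set(grp["dhs_id"]) for t, grp in present.groupby("tf_name")}

    N = len(universe_ids)
    rows = []
    cluster_members = {c: set(clusters.index[clusters == c]) for c in sorted(clusters.unique())}
    for tf in sorted(by_tf):
        with_motif = by_tf[tf]
        K = len(with_motif)
        for c, members in cluster_members.items():
            n = len(members)
            k = len(with_motif & members)
            p_over = float(hypergeom.sf(k - 1, N, K, n))
            p_under = float(hypergeom.cdf(k, N, K, n))
            rows.append(
                {
                    "tf_name": tf,
                    "cluster_label": c,
                    "n_universe": N,
                    "n_cluster": n,
                    "n_with_motif_universe": K,
                    "n_with_motif_cluster": k,
                    "p_over": p_over,
                    "p_under": p_under,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_over"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out
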