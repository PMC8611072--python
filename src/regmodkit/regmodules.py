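"""Resolving TFs into sequential regulatory modules.

Highly connected TFs (positively associated with at least
``min_positive_dhs`` DHSs) are clustered by the cosine distance between
their coefficient vectors over all modeled DHSs (zeros included), using
agglomerative hierarchical clustering cut into k clusters.  Modules are
numbered by the mean peak day of the DHS profiles positively associated
with their member TFs, so module 1 acts earliest.  A module is the TF
cluster together with the union of its members' positively associated
DHSs; DHS sets of different modules may overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .tfmodel import TFCoefficientMatrix

__all__ = [
    "RegulatoryModule",
    "select_connected_tfs",
    "cluster_tfs_cosine",
    "module_dhs_fraction",
]


@dataclass
class RegulatoryModule:
    module_id: int
    tf_members: list[str]
    dhs_members: set[str]
    mean_peak_day: float


def select_connected_tfs(
    coefs: TFCoefficientMatrix, min_positive_dhs: int = 200, strict: bool = False
) -> list[str]:
    """TFs positively associated with at least (or more than, if strict)
    ``min_positive_dhs`` DHSs."""
    c = coefs.coefficients
    pos = c[c["coefficient"] > 0].groupby("tf_name").size()
    if strict:
        keep = pos[pos > min_positive_dhs]
    else:
        keep = pos[pos >= min_positive_dhs]
    return sorted(keep.index)


def cluster_tfs_cosine(
    coefs: TFCoefficientMatrix,
    tf_list: list[str],
    k: int = 5,
    linkage: str = "average",
    dhs_day_means: pd.DataFrame | None = None,
) -> tuple[pd.Series, list[RegulatoryModule]]:
    """Hierarchically cluster TF coefficient vectors by cosine distance.

    Returns (tf -> module Series, RegulatoryModule list).  When
    ``dhs_day_means`` is given, modules are renumbered by the mean peak day
    of member TFs' positively associated DHS profiles (module 1 earliest);
    otherwise dendrogram order is kept.
    """
    if k > len(tf_list):
        raise ValueError(f"k={k} exceeds number of TFs ({len(tf_list)})")
    wide = coefs.to_wide(tf_names=None)
    missing = [t for t in tf_list if t not in wide.columns]
    if missing:
        raise ValueError(f"TFs without coefficients: {missing}")
    vectors = wide[tf_list].T  # TF x DHS, zeros included
    norms = np.linalg.norm(vectors.to_numpy(), axis=1)
    keep = norms > 0
    if not keep.all():
        warnings.warn(
            f"excluding all-zero coefficient vector(s): "
            f"{[t for t, k_ in zip(tf_list, keep) if not k_]}"
        )
    vectors = vectors.loc[np.asarray(tf_list)[keep]]
    if k > len(vectors):
        raise ValueError("k exceeds number of TFs with nonzero vectors")
    dist = pdist(vectors.to_numpy(), metric="cosine")
    Z = scipy_linkage(dist, method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")

    # positively associated DHSs per TF
    c = coefs.coefficients
    pos = c[c["coefficient"] > 0]
    pos_by_tf = {t: set(grp["dhs_id"]) for t, grp in pos.groupby("tf_name")}

    peak_day_of_dhs: dict[str, float] = {}
    if dhs_day_means is not None:
        days = np.asarray(dhs_day_means.columns, dtype=float)
        arg = np.argmax(dhs_day_means.to_numpy(), axis=1)
        peak_day_of_dhs = dict(zip(dhs_day_means.index, days[arg]))

    tf_names = list(vectors.index)
    module_peak = {}
    for m in np.unique(raw):
        members = [t for t, lab in zip(tf_names, raw) if lab == m]
        peaks = [
            peak_day_of_dhs[d]
            for t in members
            for d in pos_by_tf.get(t, ())
            if d in peak_day_of_dhs
        ]
        module_peak[m] = float(np.mean(peaks)) if peaks else float("inf")
    order = sorted(np.unique(raw), key=lambda m: (module_peak[m], m))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([relabel[m] for m in raw], index=tf_names, name="module")

    modules = []
    for new_id in range(1, k + 1):
        members = sorted(labels.index[labels == new_id])
        dhs_union: set[str] = set()
        for t in members:
            dhs_union |= pos_by_tf.get(t, set())
        old = order[new_id - 1]
        modules.append(
            RegulatoryModule(
                module_id=new_id,
                tf_members=members,
                dhs_members=dhs_union,
                mean_peak_day=module_peak[old],
            )
        )
    return labels, modules


def module_dhs_fraction(
    coefs: TFCoefficientMatrix, tf_list: list[str], dhs_clusters: pd.Series
) -> pd.DataFrame:
    """fraction(tf, cluster) = positive-coefficient DHSs of that cluster / cluster size."""
    c = coefs.coefficients
    pos = c[c["coefficient"] > 0]
    pos_by_tf = {t: set(grp["dhs_id"]) for t, grp in pos.groupby("tf_name")}
    out = {}
    clusters = sorted(dhs_clusters.unique())
    for cl in clusters:
        members = set(dhs_clusters.index[dhs_clusters == cl])
        if not members:
            out[cl] = [np.nan] * len(tf_list)
            continue
        out[cl] = [len(pos_by_tf.get(t, set()) & members) / len(members) for t in tf_list]
    return pd.DataFrame(out, index=tf_list)
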