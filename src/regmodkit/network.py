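"""Stage-specific TF -> gene regulatory networks.

For each TF in a stage-specific list, target DHSs are those with a
strictly positive elastic-net coefficient; each such DHS contributes its
positively correlated target genes (links computed with r >= 0.7).  A
(TF, gene) edge aggregates every connecting DHS path, its raw weight being
the sum over paths of coefficient(tf, dhs) * r(dhs, gene).  Edge weights
are then standardized to mean 0 / SD 1 within the network (a single-edge
network gets std_weight 0 by convention).
"""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .tfmodel import TFCoefficientMatrix

__all__ = ["build_network", "node_centrality", "top_targets", "standardize_weights"]


def build_network(
    stage_tfs: list[str],
    coefs: TFCoefficientMatrix,
    links_positive: pd.DataFrame,
    aggregate: str = "sum",
) -> nx.DiGraph:
    """Build a weighted TF -> gene network for one developmental stage.

    ``links_positive`` must come from the positive-correlation link variant
    (columns dhs_id, gene_id, r).  ``aggregate`` is "sum" (default) or
    "max" for multi-DHS (tf, gene) paths.
    """
    if aggregate not in {"sum", "max"}:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    c = coefs.coefficients
    known_tfs = set(c["tf_name"])
    unknown = [t for t in stage_tfs if t not in known_tfs]
    if unknown:
        raise ValueError(f"unknown TF name(s): {unknown}")
    pos = c[(c["coefficient"] > 0) & c["tf_name"].isin(stage_tfs)]
    links_by_dhs = {d: grp for d, grp in links_positive.groupby("dhs_id")}

    g = nx.DiGraph()
    for t in stage_tfs:
        g.add_node(t, kind="TF")
    edges: dict[tuple[str, str], dict] = {}
    for row in pos.itertuples(index=False):
        grp = links_by_dhs.get(row.dhs_id)
        if grp is None:
            continue
        for link in grp.itertuples(index=False):
            key = (row.tf_name, link.gene_id)
            w = float(row.coefficient) * float(link.r)
            e = edges.setdefault(key, {"raw_weight": None, "via_dhs": set()})
            if e["raw_weight"] is None:
                e["raw_weight"] = w
            elif aggregate == "sum":
                e["raw_weight"] += w
            else:
                e["raw_weight"] = max(e["raw_weight"], w)
            e["via_dhs"].add(row.dhs_id)
    for (tf, gene), e in sorted(edges.items()):
        if not g.has_node(gene):
            g.add_node(gene, kind="gene")
        g.add_edge(tf, gene, raw_weight=e["raw_weight"], via_dhs=e["via_dhs"])
    standardize_weights(g)
    return g


def standardize_weights(g: nx.DiGraph) -> None:
    """(Re)compute std_weight = (w - mean) / sd over all edges (population SD);
    networks with < 2 edges, or zero weight spread, get std_weight 0."""
    weights = np.array([d["raw_weight"] for _, _, d in g.edges(data=True)])
    if len(weights) < 2 or weights.std() == 0:
        for _, _, d in g.edges(data=True):
            d["std_weight"] = 0.0
        return
    mean, sd = weights.mean(), weights.std()
    for _, _, d in g.edges(data=True):
        d["std_weight"] = (d["raw_weight"] - mean) / sd


def node_centrality(g: nx.DiGraph, method: str = "degree") -> pd.Series:
    """Per-node centrality: degree (normalized by n-1, default), betweenness,
    or eigenvector (computed per weakly connected component)."""
    if g.number_of_nodes() == 0:
        return pd.Series(dtype=float, name=method)
    if method == "degree":
        cent = nx.degree_centrality(g)
    elif method == "betweenness":
        # on the undirected view, so a TF->gene->TF chain scores the gene
        cent = nx.betweenness_centrality(g.to_undirected())
    elif method == "eigenvector":
        und = g.to_undirected()
        comps = list(nx.connected_components(und))
        if len(comps) > 1:
            warnings.warn(
                f"eigenvector centrality computed per component ({len(comps)} components)"
            )
        cent = {}
        for comp in comps:
            sub = und.subgraph(comp)
            if sub.number_of_nodes() == 1:
                cent[next(iter(comp))] = 0.0
                continue
            cent.update(nx.eigenvector_centrality(sub, max_iter=1000))
    else:
        raise ValueError(f"unknown centrality method {method!r}")
    return pd.Series(cent, name=method).sort_index()


def top_targets(g: nx.DiGraph, n: int = 50) -> nx.DiGraph:
    """Keep, per TF, the n edges with largest |std_weight| (ties resolved
    toward the lexicographically smaller gene id); weights are then
    re-standardized on the filtered edge set."""
    keep = []
    for tf, d in g.nodes(data=True):
        if d.get("kind") != "TF":
            continue
        out = sorted(
            g.out_edges(tf, data=True),
            key=lambda e: (-abs(e[2]["std_weight"]), e[1]),
        )
        keep.extend((u, v) for u, v, _ in out[:n])
    keep_set = set(keep)
    h = nx.DiGraph()
    for node, d in g.nodes(data=True):
        if d.get("kind") == "TF":
            h.add_node(node, **d)
    for u, v, d in g.edges(data=True):
        if (u, v) in keep_set:
            if not h.has_node(v):
                h.add_node(v, **g.nodes[v])
            h.add_edge(u, v, raw_weight=d["raw_weight"], via_dhs=d["via_dhs"])
    standardize_weights(h)
    return h
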