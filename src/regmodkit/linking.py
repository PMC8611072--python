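"""Correlation-based linking of regulated DHSs to regulated genes.

Candidate pairs are a regulated gene and a regulated DHS on the same
chromosome with the DHS midpoint within a window of the gene's TSS
(default +/-1 Mb).  A pair becomes a link when the Pearson correlation of
their per-day mean profiles passes the threshold: |r| > min_abs_r for
discovery links, or r >= min_abs_r when only positive links are wanted
(the network-building variant).  Distances are reported signed and
strand-aware (upstream of the TSS is negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval

__all__ = ["LinkResult", "link_dhs_to_genes", "link_stats"]

LINK_COLUMNS = ["dhs_id", "gene_id", "r", "distance"]


@dataclass
class LinkResult:
    links: pd.DataFrame  # columns dhs_id, gene_id, r, distance
    n_zero_variance: int
    n_candidates: pd.Series  # gene_id -> candidate DHS count


def link_dhs_to_genes(
    gene_profiles: pd.DataFrame,
    dhs_profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    intervals: list[GenomicInterval],
    window: int = 1_000_000,
    min_abs_r: float = 0.7,
    require_positive: bool = False,
) -> LinkResult:
    """Link DHSs to genes by temporal correlation within a genomic window.

    ``gene_profiles`` and ``dhs_profiles`` are per-day mean profiles
    (features x days) on the same day grid; only features present in the
    profile tables are considered (pass regulated features only).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if list(gene_profiles.columns) != list(dhs_profiles.columns):
        raise ValueError("gene and DHS profiles are on different day grids")
    ann = annotation.set_index("gene_id")
    genes = [g for g in gene_profiles.index if g in ann.index]

    iv_by_id = {iv.id: iv for iv in intervals}
    dhs_ids = [d for d in dhs_profiles.index if d in iv_by_id]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv_by_id[d].chrom for d in dhs_ids}:
        ids = np.array([d for d in dhs_ids if iv_by_id[d].chrom == chrom])
        mids = np.array([iv_by_id[d].midpoint for d in ids])
        order = np.argsort(mids, kind="stable")
        by_chrom[chrom] = (mids[order], ids[order])

    # standardized profiles for O(1) correlation per pair
    def standardize(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        v = df.to_numpy(dtype=float)
        vc = v - v.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(vc, axis=1)
        ok = norm > 0
        vc[ok] /= norm[ok, None]
        return vc, ok

    gmat, g_ok = standardize(gene_profiles)
    dmat, d_ok = standardize(dhs_profiles)
    g_row = {g: i for i, g in enumerate(gene_profiles.index)}
    d_row = {d: i for i, d in enumerate(dhs_profiles.index)}

    n_zero_var = int((~g_ok).sum() + (~d_ok).sum())
    rows = []
    n_candidates = {}
    for g in genes:
        chrom, tss, strand = ann.loc[g, ["chrom", "tss", "strand"]]
        entry = by_chrom.get(chrom)
        if entry is None:
            n_candidates[g] = 0
            continue
        mids, ids = entry
        lo = np.searchsorted(mids, tss - window, side="left")
        hi = np.searchsorted(mids, tss + window, side="right")
        n_candidates[g] = int(hi - lo)
        gi = g_row[g]
        if not g_ok[gi]:
            continue
        for m, d in zip(mids[lo:hi], ids[lo:hi]):
            di = d_row[d]
            if not d_ok[di]:
                continue
            r = float(gmat[gi] @ dmat[di])
            keep = (r >= min_abs_r) if require_positive else (abs(r) > min_abs_r)
            if keep:
                dist = int(m - tss) if strand == "+" else int(tss - m)
                rows.append((d, g, r, dist))
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return LinkResult(
        links=links,
        n_zero_variance=n_zero_var,
        n_candidates=pd.Series(n_candidates, name="n_candidates", dtype=int),
    )


def link_stats(
    result: LinkResult,
    gene_set: list[str],
    dhs_set: list[str],
    window: int = 1_000_000,
    bin_width: int = 10_000,
) -> dict:
    """Summary statistics of a link set (per-gene/per-DHS connectivity and
    the |distance| histogram in ``bin_width`` bins)."""
    links = result.links
    per_gene = links.groupby("gene_id").size().reindex(gene_set, fill_value=0)
    per_dhs = links.groupby("dhs_id").size().reindex(dhs_set, fill_value=0)
    counts = per_gene.to_numpy(dtype=float)
    edges = np.arange(0, window + bin_width, bin_width)
    if len(links):
        hist, _ = np.histogram(links["distance"].abs(), bins=edges)
    else:
        hist = np.zeros(len(edges) - 1, dtype=int)
    return {
        "n_links": int(len(links)),
        "frac_genes_linked": float((per_gene > 0).mean()) if len(gene_set) else 0.0,
        "frac_dhs_linked": float((per_dhs > 0).mean()) if len(dhs_set) else 0.0,
        "mean_links_per_gene": float(counts.mean()) if len(gene_set) else 0.0,
        "sd_links_per_gene": float(counts.std(ddof=1)) if len(gene_set) > 1 else 0.0,
        "mean_candidates_per_gene": float(
            result.n_candidates.reindex(gene_set, fill_value=0).mean()
        )
        if len(gene_set)
        else 0.0,
        "distance_histogram": pd.Series(hist, index=edges[:-1], name="count"),
    }
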