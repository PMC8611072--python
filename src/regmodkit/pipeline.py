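"""End-to-end orchestration of the regulatory-module pipeline.

Stages run in dependency order: normalization and developmental calls,
temporal clustering and the cluster-cluster enrichment matrix, DHS-gene
linking, motif enrichment, elastic-net TF modeling, regulatory-module
resolution, and the stage-specific TF network.  Inputs are either files
(matrices + sample sheets, hotspot BED, TSS BED, motif table) or a
synthetic-data configuration; with synthetic input the planted truth is
scored automatically.  A JSON manifest records version, seed, parameters
and per-file checksums, with no timestamps, so identical configurations
produce byte-identical artifact directories.

All thresholds default to the published analysis values (adjusted p <
1e-5, fold change >= 2, density >= 30 counts, FPKM >= 2, k = 5, +/-1 Mb
and +/-50 kb windows, |r| > 0.7, >= 200 positively associated DHSs).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import devreg, io_formats, linking, motif_enrichment, network, regmodules
from . import synthetic_data, temporal_clustering, tfmodel

logger = logging.getLogger("regmodkit")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    # input files (ignored when `simulation` is set)
    dhs_matrix: str | None = None
    dhs_samples: str | None = None
    gene_matrix: str | None = None
    gene_samples: str | None = None
    hotspots_bed: str | None = None
    tss_bed: str | None = None
    motif_hits: str | None = None
    simulation: synthetic_data.SimulationConfig | None = None
    # developmental calls
    fit_mode: str = "robust"
    p_adj_max: float = 1e-5
    min_log2_range: float = 1.0
    min_max_density: float = 30.0
    min_max_fpkm: float = 2.0
    # clustering
    k_clusters: int = 5
    kmeans_restarts: int = 50
    enrichment_window: int = 50_000
    # linking
    link_window: int = 1_000_000
    min_abs_r: float = 0.7
    # motif enrichment
    motif_universe: str = "changing"
    # TF model
    enet: tfmodel.ElasticNetConfig = field(default_factory=tfmodel.ElasticNetConfig)
    require_regulated_tf: bool = True
    # modules
    min_positive_dhs: int = 200
    min_positive_dhs_strict: bool = False
    module_k: int = 5
    module_linkage: str = "average"
    # network
    stage_tfs: list[str] | None = None
    network_top_n: int = 50
    centrality: str = "degree"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = synthetic_data.SimulationConfig(**raw["simulation"])
        if "enet" in raw and raw["enet"] is not None:
            enet = raw["enet"]
            for key in ("alpha_grid", "lambda_grid"):
                if key in enet:
                    enet[key] = np.asarray(enet[key], dtype=float)
            raw["enet"] = tfmodel.ElasticNetConfig(**enet)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.enet is not None:
            d["enet"]["alpha_grid"] = list(map(float, self.enet.alpha_grid))
            d["enet"]["lambda_grid"] = list(map(float, self.enet.lambda_grid))
        return d


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        ds = synthetic_data.generate_dataset(config.simulation)
        return ds.dhs_matrix, ds.gene_matrix, ds.motif_hits, ds.intervals, ds.annotation, ds.truth, {}
    needed = {
        "dhs_matrix": config.dhs_matrix,
        "dhs_samples": config.dhs_samples,
        "gene_matrix": config.gene_matrix,
        "gene_samples": config.gene_samples,
        "hotspots_bed": config.hotspots_bed,
        "tss_bed": config.tss_bed,
        "motif_hits": config.motif_hits,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError(f"missing inputs (and no simulation config): {missing}")
    checksums = {k: io_formats.sha256_file(v) for k, v in needed.items()}
    dhs_tcm = io_formats.read_matrix_with_samples(config.dhs_matrix, config.dhs_samples)
    gene_tcm = io_formats.read_matrix_with_samples(config.gene_matrix, config.gene_samples)
    intervals = io_formats.read_hotspots_bed(config.hotspots_bed)
    annotation = io_formats.read_tss_bed(config.tss_bed)
    hits = io_formats.read_fimo_hits(config.motif_hits, intervals)
    return dhs_tcm, gene_tcm, hits, intervals, annotation, None, checksums


from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    """Abort with the stage name and cause on any stage error."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Any stage error aborts the run with the stage name and the cause."""
    tracker = {"stage": "inputs"}
    try:
        return _run_all_impl(config, out_dir, tracker)
    except Exception as exc:
        raise RuntimeError(f"stage {tracker['stage']!r} failed: {exc}") from exc


def _run_all_impl(config: PipelineConfig, out_dir: str | Path, tracker: dict) -> dict:
    out_dir = Path(out_dir)
    results: dict = {}
    stages: dict[str, list[str]] = {}

    dhs_tcm, gene_tcm, hits, intervals, annotation, truth, checksums = _load_inputs(config)
    stages["inputs"] = ["config"]
    logger.info("inputs: %d DHSs, %d genes, %d samples",
                len(dhs_tcm.feature_ids), len(gene_tcm.feature_ids),
                dhs_tcm.values.shape[1])

    tracker["stage"] = "devreg"
    # ---- stage: developmental calls -----------------------------------
    dhs_norm = io_formats.TimeCourseMatrix(
        devreg.quantile_normalize(dhs_tcm.values), dhs_tcm.samples
    )
    gene_norm = io_formats.TimeCourseMatrix(
        devreg.quantile_normalize(gene_tcm.values), gene_tcm.samples
    )
    fits_dhs = devreg.call_regulated(
        devreg.fit_matrix(dhs_norm, mode=config.fit_mode), "dhs",
        p_adj_max=config.p_adj_max, min_log2_range=config.min_log2_range,
        min_max_density=config.min_max_density,
    )
    fits_gene = devreg.call_regulated(
        devreg.fit_matrix(gene_norm, mode=config.fit_mode), "gene",
        p_adj_max=config.p_adj_max, min_log2_range=config.min_log2_range,
        min_max_fpkm=config.min_max_fpkm,
    )
    reg_dhs = fits_dhs.loc[fits_dhs["regulated"], "feature_id"].tolist()
    reg_gene = fits_gene.loc[fits_gene["regulated"], "feature_id"].tolist()
    results["fits_dhs"] = fits_dhs
    results["fits_gene"] = fits_gene
    stages["devreg"] = ["fits_dhs.tsv", "fits_gene.tsv"]
    logger.info("devreg: %d/%d regulated DHSs, %d/%d regulated genes",
                len(reg_dhs), len(fits_dhs), len(reg_gene), len(fits_gene))

    dhs_day_means = dhs_norm.day_means()
    gene_day_means = gene_norm.day_means()

    tracker["stage"] = "clustering"
    # ---- stage: temporal clustering -----------------------------------
    dhs_clusters = gene_clusters = None
    empty_clusters = pd.DataFrame(columns=["feature_id", "cluster"])
    if len(reg_dhs) >= config.k_clusters:
        z = temporal_clustering.zscore_profiles(dhs_day_means.loc[reg_dhs])
        dhs_clusters = temporal_clustering.kmeans_profiles(
            z, k=config.k_clusters, n_restarts=config.kmeans_restarts,
            seed=config.seed,
        ).assignments
        results["clusters_dhs"] = dhs_clusters.rename_axis("feature_id").reset_index()
    else:
        logger.info("clustering: too few regulated DHSs (%d); skipped", len(reg_dhs))
        results["clusters_dhs"] = empty_clusters
    if len(reg_gene) >= config.k_clusters:
        zg = temporal_clustering.zscore_profiles(gene_day_means.loc[reg_gene])
        gene_clusters = temporal_clustering.kmeans_profiles(
            zg, k=config.k_clusters, n_restarts=config.kmeans_restarts,
            seed=config.seed + 1,
        ).assignments
        results["clusters_gene"] = gene_clusters.rename_axis("feature_id").reset_index()
    else:
        results["clusters_gene"] = empty_clusters
    if dhs_clusters is not None and gene_clusters is not None:
        em = temporal_clustering.cluster_enrichment_matrix(
            gene_clusters, dhs_clusters, annotation, intervals,
            window=config.enrichment_window,
        )
        rows = []
        for g in em.observed.index:
            for e in em.observed.columns:
                rows.append({
                    "gene_cluster": g, "dhs_cluster": e,
                    "observed": em.observed.loc[g, e],
                    "expected": em.expected.loc[g, e],
                    "log2_ratio": em.log2_ratio.loc[g, e],
                    "chi2_p": em.chi2_p.loc[g, e],
                })
        results["cluster_enrichment"] = pd.DataFrame(rows)
    else:
        results["cluster_enrichment"] = pd.DataFrame(
            columns=["gene_cluster", "dhs_cluster", "observed", "expected",
                     "log2_ratio", "chi2_p"]
        )
    stages["clustering"] = ["clusters_dhs.tsv", "clusters_gene.tsv",
                            "cluster_enrichment.tsv"]

    tracker["stage"] = "linking"
    # ---- stage: linking -------------------------------------------------
    link_res = linking.link_dhs_to_genes(
        gene_day_means.loc[reg_gene], dhs_day_means.loc[reg_dhs],
        annotation, intervals, window=config.link_window,
        min_abs_r=config.min_abs_r, require_positive=False,
    )
    link_pos = linking.link_dhs_to_genes(
        gene_day_means.loc[reg_gene], dhs_day_means.loc[reg_dhs],
        annotation, intervals, window=config.link_window,
        min_abs_r=config.min_abs_r, require_positive=True,
    )
    stats = linking.link_stats(link_res, reg_gene, reg_dhs, window=config.link_window)
    results["links"] = link_res.links
    results["links_positive"] = link_pos.links
    results["link_stats"] = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v) for k, v in stats.items()
    }
    stages["linking"] = ["links.tsv", "links_positive.tsv", "link_stats.json"]
    logger.info("linking: %d links (|r|>%.2f) among %d genes x %d DHSs",
                len(link_res.links), config.min_abs_r, len(reg_gene), len(reg_dhs))

    tracker["stage"] = "motif_enrichment"
    # ---- stage: motif enrichment ---------------------------------------
    if dhs_clusters is not None and len(hits.table):
        results["motif_enrichment"] = motif_enrichment.motif_cluster_enrichment(
            hits, dhs_clusters, universe=config.motif_universe,
            all_dhs_ids=[iv.id for iv in intervals],
        )
    else:
        results["motif_enrichment"] = pd.DataFrame(
            columns=["tf_name", "cluster_label", "n_universe", "n_cluster",
                     "n_with_motif_universe", "n_with_motif_cluster",
                     "p_over", "p_under", "p_adj"]
        )
    stages["motif_enrichment"] = ["motif_enrichment.tsv"]

    tracker["stage"] = "tfmodel"
    # ---- stage: TF model ------------------------------------------------
    tf_names = [t for t in hits.tf_names() if t in gene_day_means.index]
    tf_expression = gene_day_means.loc[tf_names]
    regulated_tfs = set(reg_gene) & set(tf_names)
    coefs = None
    if dhs_clusters is not None and tf_names:
        cluster_designs = {}
        for cl in sorted(dhs_clusters.unique()):
            ids = sorted(dhs_clusters.index[dhs_clusters == cl])
            cluster_designs[cl] = tfmodel.build_designs_for_cluster(
                ids, hits, tf_expression, dhs_day_means,
                min_max_fpkm=config.min_max_fpkm,
                require_regulated_tf=config.require_regulated_tf,
                regulated_tfs=regulated_tfs,
            )
        coefs = tfmodel.fit_cluster_models(cluster_designs, config.enet)
        results["coefficients"] = coefs.coefficients
        results["cluster_params"] = coefs.cluster_params
        summary = tfmodel.model_summary(coefs, list(dhs_clusters.index))
        nb_report = {
            "frac_modeled": summary["frac_modeled"],
            "mean_positive_tfs_per_dhs": summary["mean_positive_tfs_per_dhs"],
        }
        try:
            counts_wide = hits.to_wide(list(dhs_clusters.index), tf_names)
            nb_counts, nb_coefs, ratio = tfmodel.naive_bayes_cluster_benchmark(
                counts_wide, coefs.to_wide(dhs_ids=list(dhs_clusters.index)),
                dhs_clusters, seed=config.seed,
            )
            nb_report.update(
                accuracy_counts=nb_counts.mean_accuracy,
                accuracy_coefficients=nb_coefs.mean_accuracy,
                accuracy_ratio=ratio,
            )
        except ValueError as exc:
            logger.info("naive Bayes benchmark skipped: %s", exc)
            nb_report["skipped"] = str(exc)
        results["nb_report"] = nb_report
    else:
        results["coefficients"] = pd.DataFrame(columns=["dhs_id", "tf_name", "coefficient"])
        results["cluster_params"] = pd.DataFrame(columns=["cluster", "alpha", "lam"])
        results["nb_report"] = {"skipped": "no clustered DHSs or no TFs"}
    stages["tfmodel"] = ["coefficients.tsv", "cluster_params.tsv", "nb_report.json"]

    tracker["stage"] = "modules"
    # ---- stage: modules -------------------------------------------------
    module_labels = None
    if coefs is not None and len(coefs.coefficients):
        connected = regmodules.select_connected_tfs(
            coefs, min_positive_dhs=config.min_positive_dhs,
            strict=config.min_positive_dhs_strict,
        )
        if len(connected) >= config.module_k:
            module_labels, modules = regmodules.cluster_tfs_cosine(
                coefs, connected, k=config.module_k, linkage=config.module_linkage,
                dhs_day_means=dhs_day_means.loc[reg_dhs],
            )
            results["modules"] = module_labels.rename_axis("tf_name").reset_index()
            results["module_fractions"] = (
                regmodules.module_dhs_fraction(coefs, connected, dhs_clusters)
                .rename_axis("tf_name").reset_index()
                if dhs_clusters is not None else None
            )
        else:
            logger.info("modules: no TFs pass min_positive_dhs=%d (%d found)",
                        config.min_positive_dhs, len(connected))
            results["modules"] = pd.DataFrame(columns=["tf_name", "module"])
    else:
        logger.info("modules: no TFs pass min_positive_dhs (no coefficients)")
        results["modules"] = pd.DataFrame(columns=["tf_name", "module"])
    stages["modules"] = ["modules.tsv", "module_fractions.tsv"]

    tracker["stage"] = "network"
    # ---- stage: network -------------------------------------------------
    stage_tfs = config.stage_tfs
    if stage_tfs is None:
        stage_tfs = list(module_labels.index) if module_labels is not None else []
    if coefs is not None and stage_tfs:
        net = network.build_network(stage_tfs, coefs, results["links_positive"])
        net = network.top_targets(net, n=config.network_top_n)
        results["network"] = net
        results["centrality"] = (
            network.node_centrality(net, method=config.centrality)
            .rename_axis("node").reset_index()
        )
    else:
        import networkx as nx

        results["network"] = nx.DiGraph()
        results["centrality"] = pd.DataFrame(columns=["node", config.centrality])
    stages["network"] = ["network.edges.tsv", "network.graphml", "centrality.tsv"]

    tracker["stage"] = "recovery"
    # ---- recovery scoring (synthetic runs) -----------------------------
    recovery = None
    if truth is not None:
        scored = {
            "dhs_changing": reg_dhs,
            "gene_changing": reg_gene,
            "links": link_res.links,
        }
        if dhs_clusters is not None:
            scored["dhs_clusters"] = dhs_clusters
        if module_labels is not None:
            scored["tf_modules"] = module_labels
        if coefs is not None:
            scored["tf_effects"] = coefs.coefficients
        recovery = synthetic_data.score_recovery(truth, scored)
        results["recovery"] = recovery
        logger.info("recovery: %s", recovery)

    tracker["stage"] = "write_outputs"
    manifest = io_formats.write_outputs(
        results,
        out_dir,
        parameters=config.to_dict(),
        seed=config.seed,
        input_checksums=checksums,
    )
    manifest["stages"] = stages
    if recovery is not None:
        manifest["recovery"] = recovery
    import json

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True,
                  default=io_formats._json_default)
    return manifest
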