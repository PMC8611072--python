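"""Model each regulated DHS's accessibility from motif-compatible TF
expression by elastic net, with (alpha, lambda) chosen per temporal cluster
by repeated leave-4-days-out validation, then benchmark coefficients vs
raw motif counts with the Poisson/Gaussian naive Bayes classifier."""
import json

import pandas as pd

from common import ENET_CONFIG, RESULTS, SEED, get_dataset, normalized

from regmodkit import score_recovery
from regmodkit.io_formats import write_table
from regmodkit.tfmodel import (
    build_designs_for_cluster,
    fit_cluster_models,
    model_summary,
    naive_bayes_cluster_benchmark,
)


def main():
    ds = get_dataset()
    dhs_norm, gene_norm = normalized(ds)
    dhs_dm, gene_dm = dhs_norm.day_means(), gene_norm.day_means()
    clusters = pd.read_csv(RESULTS / "clusters_dhs.tsv", sep="\t").set_index(
        "feature_id"
    )["cluster"]
    fits_gene = pd.read_csv(RESULTS / "fits_gene.tsv", sep="\t")
    regulated_tfs = set(fits_gene.loc[fits_gene["regulated"], "feature_id"])

    tf_names = [t for t in ds.motif_hits.tf_names() if t in gene_dm.index]
    tf_expr = gene_dm.loc[tf_names]
    designs = {
        cl: build_designs_for_cluster(
            sorted(clusters.index[clusters == cl]), ds.motif_hits, tf_expr,
            dhs_dm, require_regulated_tf=True, regulated_tfs=regulated_tfs,
        )
        for cl in sorted(clusters.unique())
    }
    coefs = fit_cluster_models(designs, ENET_CONFIG)
    write_table(coefs.coefficients, RESULTS / "coefficients.tsv")
    write_table(coefs.cluster_params, RESULTS / "cluster_params.tsv")

    summary = model_summary(coefs, list(clusters.index))
    m = score_recovery(ds.truth, {"tf_effects": coefs.coefficients})
    nb_counts, nb_coefs, ratio = naive_bayes_cluster_benchmark(
        ds.motif_hits.to_wide(list(clusters.index), tf_names),
        coefs.to_wide(dhs_ids=list(clusters.index)), clusters, seed=SEED,
    )
    report = {
        "frac_modeled": summary["frac_modeled"],
        "mean_positive_tfs_per_dhs": summary["mean_positive_tfs_per_dhs"],
        "effect_recovery": m["effect_recovery"],
        "sign_accuracy": m["sign_accuracy"],
        "nb_accuracy_counts": nb_counts.mean_accuracy,
        "nb_accuracy_coefficients": nb_coefs.mean_accuracy,
        "nb_accuracy_ratio": ratio,
    }
    with open(RESULTS / "nb_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"modeled {summary['frac_modeled']:.1%} of clustered DHSs; "
          f"{summary['mean_positive_tfs_per_dhs']:.1f} positive TFs/DHS on average")
    print(f"planted-effect recovery {m['effect_recovery']:.2f}, "
          f"sign accuracy {m['sign_accuracy']:.2f}")
    print(f"naive Bayes cluster prediction: coefficients "
          f"{nb_coefs.mean_accuracy:.1%} vs motif counts "
          f"{nb_counts.mean_accuracy:.1%} ({ratio:.2f}-fold)")


if __name__ == "__main__":
    main()
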