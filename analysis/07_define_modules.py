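"""Resolve highly connected TFs into sequential regulatory modules by
cosine-distance hierarchical clustering of their coefficient vectors."""
import pandas as pd

from common import RESULTS, connectivity_cutoff, get_dataset, normalized

from regmodkit import score_recovery
from regmodkit.io_formats import write_table
from regmodkit.regmodules import (
    cluster_tfs_cosine,
    module_dhs_fraction,
    select_connected_tfs,
)
from regmodkit.tfmodel import TFCoefficientMatrix


def load_coefs():
    return TFCoefficientMatrix(
        coefficients=pd.read_csv(RESULTS / "coefficients.tsv", sep="\t"),
        intercepts=pd.Series(dtype=float),
        train_mse=pd.Series(dtype=float),
        cluster_params=pd.read_csv(RESULTS / "cluster_params.tsv", sep="\t"),
    )


def main():
    ds = get_dataset()
    dhs_norm, _ = normalized(ds)
    coefs = load_coefs()
    clusters = pd.read_csv(RESULTS / "clusters_dhs.tsv", sep="\t").set_index(
        "feature_id"
    )["cluster"]
    cutoff = connectivity_cutoff(len(clusters))
    tfs = select_connected_tfs(coefs, min_positive_dhs=cutoff)
    labels, modules = cluster_tfs_cosine(
        coefs, tfs, k=5, dhs_day_means=dhs_norm.day_means().loc[clusters.index]
    )
    write_table(labels.rename_axis("tf_name").reset_index(), RESULTS / "modules.tsv")
    write_table(
        module_dhs_fraction(coefs, tfs, clusters).rename_axis("tf_name").reset_index(),
        RESULTS / "module_fractions.tsv",
    )
    m = score_recovery(ds.truth, {"tf_modules": labels})
    print(f"{len(tfs)} TFs positively associated with >= {cutoff} DHSs")
    for mod in modules:
        print(f"  module {mod.module_id}: {len(mod.tf_members)} TFs, "
              f"{len(mod.dhs_members)} DHSs, mean peak day {mod.mean_peak_day:.1f}")
    print(f"ARI vs planted modules = {m['module_ari']:.3f}")


if __name__ == "__main__":
    main()
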