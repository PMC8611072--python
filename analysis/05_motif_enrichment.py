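"""Test TF-motif over/under-representation in each temporal DHS cluster
(one-tailed hypergeometric, BH-adjusted; universe = clustered DHSs)."""
import pandas as pd

from common import RESULTS, get_dataset

from regmodkit.io_formats import write_table
from regmodkit.motif_enrichment import motif_cluster_enrichment


def main():
    ds = get_dataset()
    clusters = pd.read_csv(RESULTS / "clusters_dhs.tsv", sep="\t").set_index(
        "feature_id"
    )["cluster"]
    table = motif_cluster_enrichment(ds.motif_hits, clusters)
    write_table(table, RESULTS / "motif_enrichment.tsv")
    hits = table[table["p_adj"] < 0.05]
    top = (
        hits.sort_values("p_adj").groupby("cluster_label").head(2)
        [["cluster_label", "tf_name", "p_adj"]]
    )
    print(f"{len(hits)}/{len(table)} (TF, cluster) pairs enriched at FDR 5%")
    for row in top.itertuples(index=False):
        print(f"  E{row.cluster_label}: {row.tf_name} (p_adj={row.p_adj:.2e})")


if __name__ == "__main__":
    main()
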