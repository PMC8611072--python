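"""Build the stage-specific TF->gene network from elastic-net TF->DHS
assignments and positive DHS->gene links; report node centralities."""
import pandas as pd

from common import RESULTS

from regmodkit.io_formats import write_network, write_table
from regmodkit.network import build_network, node_centrality, top_targets
from regmodkit.tfmodel import TFCoefficientMatrix


def main():
    coefs = TFCoefficientMatrix(
        coefficients=pd.read_csv(RESULTS / "coefficients.tsv", sep="\t"),
        intercepts=pd.Series(dtype=float),
        train_mse=pd.Series(dtype=float),
        cluster_params=pd.DataFrame(),
    )
    links_pos = pd.read_csv(RESULTS / "links_positive.tsv", sep="\t")
    modules = pd.read_csv(RESULTS / "modules.tsv", sep="\t")
    for module_id, grp in modules.groupby("module"):
        stage_tfs = sorted(grp["tf_name"])
        net = top_targets(build_network(stage_tfs, coefs, links_pos), n=50)
        write_network(net, RESULTS / f"network_module{module_id}")
        cent = node_centrality(net, method="degree")
        write_table(
            cent.rename_axis("node").reset_index(),
            RESULTS / f"network_module{module_id}.centrality.tsv",
        )
        genes = [n for n, d in net.nodes(data=True) if d.get("kind") != "TF"]
        hub = cent.idxmax() if len(cent) else "-"
        print(f"module {module_id}: {len(stage_tfs)} TFs -> {len(genes)} target "
              f"genes, {net.number_of_edges()} edges; top hub {hub}")


if __name__ == "__main__":
    main()
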