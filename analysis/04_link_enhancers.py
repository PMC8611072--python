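"""Link regulated DHSs to regulated genes by temporal correlation
(|r| > 0.7 within +/-1 Mb of the TSS) and summarize connectivity."""
import pandas as pd

from common import RESULTS, get_dataset, normalized

from regmodkit import score_recovery
from regmodkit.io_formats import write_table
from regmodkit.linking import link_dhs_to_genes, link_stats


def regulated_ids(kind):
    fits = pd.read_csv(RESULTS / f"fits_{kind}.tsv", sep="\t")
    return fits.loc[fits["regulated"], "feature_id"].tolist()


def main():
    ds = get_dataset()
    dhs_norm, gene_norm = normalized(ds)
    reg_d, reg_g = regulated_ids("dhs"), regulated_ids("gene")
    gene_prof = gene_norm.day_means().loc[reg_g]
    dhs_prof = dhs_norm.day_means().loc[reg_d]

    res = link_dhs_to_genes(gene_prof, dhs_prof, ds.annotation, ds.intervals)
    pos = link_dhs_to_genes(gene_prof, dhs_prof, ds.annotation, ds.intervals,
                            require_positive=True)
    write_table(res.links, RESULTS / "links.tsv")
    write_table(pos.links, RESULTS / "links_positive.tsv")
    stats = link_stats(res, reg_g, reg_d)
    m = score_recovery(ds.truth, {"links": res.links})
    print(f"{stats['n_links']} links; {stats['frac_genes_linked']:.1%} of genes and "
          f"{stats['frac_dhs_linked']:.1%} of DHSs linked; "
          f"{stats['mean_links_per_gene']:.2f} +/- {stats['sd_links_per_gene']:.2f} "
          f"links/gene of {stats['mean_candidates_per_gene']:.1f} candidates")
    print(f"planted-link recovery: precision={m['links']['precision']:.3f}, "
          f"recall={m['links']['recall']:.3f}")


if __name__ == "__main__":
    main()
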