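"""Generate the study dataset and write it in the pipeline's input formats.

Writes the DHS and gene matrices with their sample sheet, hotspot and TSS
BED files and the motif-hit table under results/inputs/, exactly as a real
run would consume them from disk.
"""
from common import RESULTS, get_dataset

from regmodkit.io_formats import write_table


def main():
    ds = get_dataset()
    out = RESULTS / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    write_table(ds.dhs_matrix.values.rename_axis("feature_id"), out / "dhs_matrix.tsv", index=True)
    write_table(ds.gene_matrix.values.rename_axis("feature_id"), out / "gene_matrix.tsv", index=True)
    write_table(ds.dhs_matrix.samples.rename_axis("sample_id"), out / "samples.tsv", index=True)
    with open(out / "hotspots.bed", "w") as fh:
        for iv in ds.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
    with open(out / "tss.bed", "w") as fh:
        for row in ds.annotation.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.tss}\t{row.tss + 1}\t{row.gene_id}\t0\t{row.strand}\n")
    write_table(ds.motif_hits.table, out / "motif_hits.tsv")
    n_changing = int(ds.truth.dhs_changing.sum())
    print(f"dataset: {len(ds.dhs_matrix.feature_ids)} DHSs ({n_changing} changing), "
          f"{len(ds.gene_matrix.feature_ids)} genes incl. {ds.config.n_tf} TFs, "
          f"{ds.dhs_matrix.values.shape[1]} samples -> {out}")


if __name__ == "__main__":
    main()
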