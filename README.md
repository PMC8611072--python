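# regmodkit

Temporal regulatory-module inference from dense differentiation time
courses of chromatin accessibility and gene expression.

## The problem

During directed differentiation (e.g., ex vivo erythropoiesis sampled
daily over ~12 days across donors), thousands of DNase I hypersensitive
sites (DHSs) open and close while transcription factor (TF) expression
sweeps through sequential programs.  `regmodkit` turns paired DHS-density
and gene-FPKM time courses into an explicit regulatory reconstruction:

1. **Developmentally regulated features.**  Each feature's
   quantile-normalized profile is fit with a natural cubic spline of day
   (3 df, robust or exact least squares) and tested against an
   intercept-only null with a likelihood-ratio test,
   `LRT = n log(RSS0/RSS1) ~ chi2(3)`; calls require BH-adjusted p < 1e-5,
   log2 fold range >= 1, and max daily mean >= 30 counts (DHS) or
   >= 2 FPKM (genes).
2. **Temporal classes.**  k-means (k = 5) on z-scored per-day profiles,
   labels ordered by peak time (E1 earliest), plus a gene-cluster x
   DHS-cluster ±50 kb enrichment matrix (log2 observed/expected, chi2).
3. **Enhancer–gene links.**  Pearson correlation of per-day profiles for
   DHSs within ±1 Mb of a regulated gene's TSS, kept at |r| > 0.7.
4. **Motif enrichment.**  One-tailed hypergeometric tests of motif
   presence per temporal cluster, BH-adjusted.
5. **TF-to-chromatin model.**  Each DHS's accessibility y is regressed on
   the expression X of motif-compatible TFs by elastic net,
   `(1/2n)||y − b0 − Xb||² + λ(α||b||₁ + (1−α)/2·||b||₂²)`,
   with (α, λ) selected per cluster by repeated leave-4-days-out
   validation over an α ∈ [0,1] × λ ∈ [1e-5, 1e5] grid; a naive Bayes
   classifier (Poisson on motif counts vs Gaussian on coefficients)
   benchmarks how much cluster information the coefficients add.
6. **Regulatory modules.**  TFs positively associated with many DHSs are
   clustered by cosine distance of their coefficient vectors
   (average linkage, k = 5), yielding sequential modules of TFs with
   their target DHSs.
7. **Stage-specific networks.**  TF→gene edges via positive-coefficient
   DHSs and positive links, weighted by the standardized product of
   coefficient and correlation, with node centralities and a top-50
   targets display filter.

A first-class synthetic-data generator plants all of this structure
(module activity curves, TF effects, enhancer links, decoy motifs and
decoy geometry) with a truth ledger, so the entire chain is verifiable
without external data.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

The numbered scripts under `analysis/` run the complete study on a
synthetic time course (13 days x 3 donors; 2,000 DHSs, 30% changing;
300 genes; 40 TFs in 5 modules; seed 42) and write tables under
`results/`:

```bash
cd analysis
python 01_simulate.py
python 02_call_regulated.py
python 03_cluster_profiles.py
python 04_link_enhancers.py
python 05_motif_enrichment.py
python 06_fit_tf_model.py
python 07_define_modules.py
python 08_build_network.py
```

Output of this run:

```
regulated: 600/2000 DHSs (40% activated), 215/340 genes
recovery vs truth: DHS F1=1.000, gene F1=0.938
DHS clusters E1..E5 sizes: {1: 118, 2: 120, 3: 120, 4: 123, 5: 119}; ARI vs planted modules = 1.000
202 links; 69.8% of genes and 33.7% of DHSs linked; 0.94 +/- 0.74 links/gene of 0.9 candidates
planted-link recovery: precision=1.000, recall=1.000
30/200 (TF, cluster) pairs enriched at FDR 5%
modeled 100.0% of clustered DHSs; 5.1 positive TFs/DHS on average
naive Bayes cluster prediction: coefficients 96.3% vs motif counts 40.3% (2.39-fold)
40 TFs positively associated with >= 10 DHSs
  module 1: 8 TFs, 126 DHSs, mean peak day 0.4
  ...
  module 5: 8 TFs, 247 DHSs, mean peak day 11.4
ARI vs planted modules = 1.000
module 1: 8 TFs -> 32 target genes, 141 edges; top hub TF001
```

Reading this: every planted changing DHS is recalled with no false
positives; the five temporal classes and five TF modules are recovered
exactly; each DHS's accessibility is explained by ~5 positively
associated TFs; and elastic-net coefficients predict a DHS's temporal
class far better than its raw motif content — the qualitative signature
of coordinated TF programs driving chromatin dynamics.

The same pipeline runs from files (TSV matrices + sample sheet, BED
hotspots and TSSs, FIMO-style motif hits) through one config:

```bash
regmodkit run --config config.yaml --out artifacts/
```

with subcommands (`regmodkit simulate / devreg / cluster / link /
enrich-motifs / network`) mirroring each stage.

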