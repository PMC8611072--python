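import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regmodkit.io_formats import GenomicInterval
from regmodkit.synthetic_data import module_activity_curves
from regmodkit.temporal_clustering import (
    cluster_enrichment_matrix,
    kmeans_profiles,
    zscore_profiles,
)

DAYS = np.arange(13)


def planted_zprofiles(n_per_class=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    curves = module_activity_curves(DAYS, 5)
    rows, labels = [], []
    for c in range(5):
        for _ in range(n_per_class):
            rows.append(curves[c] + rng.normal(0, noise, len(DAYS)))
            labels.append(c)
    df = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))], columns=DAYS)
    return zscore_profiles(df), np.array(labels)


class TestKmeansProfiles:
    def test_planted_classes_recovered_exactly(self):
        z, labels = planted_zprofiles(noise=0.0)
        res = kmeans_profiles(z, k=5, seed=0)
        assert adjusted_rand_score(labels, res.assignments) == 1.0

    def test_duplicates_get_identical_labels(self):
        z, _ = planted_zprofiles(n_per_class=10, noise=0.05)
        doubled = pd.concat([z, z.set_index(z.index + "_dup")])
        res = kmeans_profiles(doubled, k=5, seed=0)
        for f in z.index:
            assert res.assignments[f] == res.assignments[f + "_dup"]

    def test_deterministic_given_seed(self):
        z, _ = planted_zprofiles(noise=0.2)
        a = kmeans_profiles(z, k=5, seed=3).assignments
        b = kmeans_profiles(z, k=5, seed=3).assignments
        pd.testing.assert_series_equal(a, b)

    def test_labels_ordered_by_peak_time(self):
        z, _ = planted_zprofiles(noise=0.05)
        res = kmeans_profiles(z, k=5, seed=0)
        peaks = DAYS[np.argmax(res.centers, axis=1)]
        assert (np.diff(peaks) >= 0).all()

    def test_best_of_restarts(self):
        z, _ = planted_zprofiles(n_per_class=15, noise=0.3)
        res = kmeans_profiles(z, k=5, n_restarts=20, seed=1)
        assert res.inertia <= res.restart_inertias.min() + 1e-9

    def test_k_exceeding_features_rejected(self):
        z, _ = planted_zprofiles(n_per_class=1, noise=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(z, k=10, seed=0)

    def test_zscore_drops_constant_profiles(self):
        df = pd.DataFrame(
            {"d0": [1.0, 5.0], "d1": [2.0, 5.0], "d2": [3.0, 5.0]},
            index=["varies", "flat"],
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_profiles(df)
        assert list(z.index) == ["varies"]
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)


def _grid(genes, dhss):
    """Build annotation and intervals from (id, pos) tuples on one chromosome."""
    ann = pd.DataFrame(
        [(g, "chr1", pos, "+") for g, pos in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    ivs = [GenomicInterval("chr1", pos - 50, pos + 50, d) for d, pos in dhss]
    return ann, ivs


class TestEnrichmentMatrix:
    def test_constructed_enrichment(self):
        # four DHS classes at four separated loci, each hosting one gene
        # cluster: every class's DHSs sit only near its own genes
        genes = [(f"g{c}", c * 10_000_000) for c in range(1, 5)]
        gene_clusters = pd.Series({f"g{c}": c for c in range(1, 5)})
        dhss = [
            (f"e{c}_{i}", c * 10_000_000 + i * 1000)
            for c in range(1, 5)
            for i in range(20)
        ]
        labels = {f"e{c}_{i}": c for c in range(1, 5) for i in range(20)}
        ann, ivs = _grid(genes, dhss)
        em = cluster_enrichment_matrix(
            gene_clusters, pd.Series(labels), ann, ivs
        )
        for c in range(1, 5):
            assert em.log2_ratio.loc[c, c] > 1.0
        assert em.log2_ratio.loc[1, 2] < 0.0

    def test_pseudocount_arithmetic(self):
        # Gi windows contain 10 of 10 E1 DHSs and 10 of 30 E2 DHSs:
        # total_in = 20, share(E1) = 0.25 -> expected 5, observed 10
        genes = [("g", 1_000_000)]
        gene_clusters = pd.Series({"g": 1})
        dhss = [(f"e1_{i}", 1_000_000 + i * 100) for i in range(10)]
        dhss += [(f"e2in_{i}", 1_010_000 + i * 100) for i in range(10)]
        dhss += [(f"e2out_{i}", 9_000_000 + i * 100) for i in range(20)]
        labels = {f"e1_{i}": 1 for i in range(10)}
        labels.update({f"e2in_{i}": 2 for i in range(10)})
        labels.update({f"e2out_{i}": 2 for i in range(20)})
        ann, ivs = _grid(genes, dhss)
        em = cluster_enrichment_matrix(gene_clusters, pd.Series(labels), ann, ivs)
        assert em.observed.loc[1, 1] == 10
        assert em.expected.loc[1, 1] == pytest.approx(5.0)
        assert em.log2_ratio.loc[1, 1] == pytest.approx(np.log2(10.5 / 5.5))

    def test_label_permutation_permutes_matrix(self):
        rng = np.random.default_rng(0)
        genes = [(f"g{i}", int(p)) for i, p in enumerate(rng.integers(0, 10_000_000, 20))]
        dhss = [(f"d{i}", int(p)) for i, p in enumerate(rng.integers(0, 10_000_000, 100))]
        gene_clusters = pd.Series({g: i % 3 + 1 for i, (g, _) in enumerate(genes)})
        dhs_clusters = pd.Series({d: i % 4 + 1 for i, (d, _) in enumerate(dhss)})
        ann, ivs = _grid(genes, dhss)
        em = cluster_enrichment_matrix(gene_clusters, dhs_clusters, ann, ivs)
        swap = {1: 2, 2: 1, 3: 3}
        em2 = cluster_enrichment_matrix(
            gene_clusters.map(swap), dhs_clusters, ann, ivs
        )
        np.testing.assert_allclose(
            em.observed.loc[1].to_numpy(), em2.observed.loc[2].to_numpy()
        )

    def test_uniform_scatter_is_null(self):
        """Uniformly placed DHS classes show no enrichment in nearly all cells."""
        ok = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            L = 3_000_000
            genes = [(f"g{i}", int(p)) for i, p in enumerate(rng.integers(100, L, 50))]
            dhss = [(f"d{i}", int(p)) for i, p in enumerate(rng.integers(100, L, 3000))]
            gene_clusters = pd.Series({g: i % 5 + 1 for i, (g, _) in enumerate(genes)})
            dhs_clusters = pd.Series(
                {d: int(c) for (d, _), c in zip(dhss, rng.integers(1, 6, len(dhss)))}
            )
            ann, ivs = _grid(genes, dhss)
            em = cluster_enrichment_matrix(gene_clusters, dhs_clusters, ann, ivs)
            for g in em.log2_ratio.index:
                for e in em.log2_ratio.columns:
                    total += 1
                    if abs(em.log2_ratio.loc[g, e]) <= 0.2 and em.chi2_p.loc[g, e] > 0.05:
                        ok += 1
        assert ok / total >= 0.9
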