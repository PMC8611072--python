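import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmodkit import SimulationConfig, generate_dataset, score_recovery
from regmodkit import devreg
from regmodkit.io_formats import TimeCourseMatrix
from regmodkit.synthetic_data import module_activity_curves


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_dhs=100, n_genes=30, seed=1)
        a = generate_dataset(cfg)
        b = generate_dataset(SimulationConfig(n_dhs=100, n_genes=30, seed=1))
        pd.testing.assert_frame_equal(a.dhs_matrix.values, b.dhs_matrix.values)
        pd.testing.assert_frame_equal(a.gene_matrix.values, b.gene_matrix.values)
        pd.testing.assert_frame_equal(a.motif_hits.table, b.motif_hits.table)

    def test_different_seed_differs(self):
        a = generate_dataset(SimulationConfig(n_dhs=50, n_genes=20, seed=1))
        b = generate_dataset(SimulationConfig(n_dhs=50, n_genes=20, seed=2))
        assert not a.dhs_matrix.values.equals(b.dhs_matrix.values)


class TestModuleCurves:
    days = np.arange(13)

    def test_shapes_monotone_or_unimodal(self):
        curves = module_activity_curves(self.days, 5)
        first_diff = np.diff(curves[0])
        last_diff = np.diff(curves[-1])
        assert (first_diff <= 1e-12).all()  # early ramp-down
        assert (last_diff >= -1e-12).all()  # late ramp-up
        for c in curves[1:3]:  # transient bumps: one sign change in slope
            signs = np.sign(np.diff(c))
            signs = signs[signs != 0]
            changes = (np.diff(signs) != 0).sum()
            assert changes == 1

    def test_curves_span_unit_interval(self):
        curves = module_activity_curves(self.days, 5)
        np.testing.assert_allclose(curves.min(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(curves.max(axis=1), 1, atol=1e-12)


class TestNoiselessLimit:
    def test_single_effect_dhs_tracks_tf_curve(self):
        cfg = SimulationConfig(n_dhs=60, n_genes=20, noise_sd=0.0, seed=3)
        ds = generate_dataset(cfg)
        dhs_dm = ds.dhs_matrix.day_means()
        effects = ds.truth.tf_effects.groupby("dhs_id").size()
        singles = effects.index[effects == 1]
        assert len(singles) > 0
        for d in singles:
            tf = ds.truth.tf_effects.set_index("dhs_id").loc[d, "tf_name"]
            r = np.corrcoef(dhs_dm.loc[d], ds.truth.tf_activity.loc[tf])[0, 1]
            # softplus curvature at small effect*expression keeps r just
            # below 1 even without noise
            assert r > 0.995


class TestNullSimulation:
    def test_no_changing_features_yields_no_calls(self):
        """With frac_changing_dhs=0 the developmental fit should flag nothing
        at adjusted p < 1e-5 in nearly all seeds."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_dhs=200, n_genes=30, frac_changing_dhs=0.0, seed=seed
            )
            ds = generate_dataset(cfg)
            qn = devreg.quantile_normalize(ds.dhs_matrix.values)
            tcm = TimeCourseMatrix(qn, ds.dhs_matrix.samples)
            fits = devreg.call_regulated(devreg.fit_matrix(tcm, mode="ols"), "dhs")
            if fits["regulated"].sum() == 0:
                clean += 1
        assert clean >= 0.95 * n_seeds

    def test_flat_dhs_mean_is_day_independent(self):
        """Non-changing DHS per-day means show no day effect (ANOVA)."""
        not_rejected = total = 0
        for seed in range(5):
            ds = generate_dataset(
                SimulationConfig(n_dhs=100, n_genes=20, frac_changing_dhs=0.0, seed=seed)
            )
            days = ds.dhs_matrix.days
            for row in ds.dhs_matrix.values.to_numpy():
                groups = [row[days == d] for d in np.unique(days)]
                total += 1
                if stats.f_oneway(*groups).pvalue > 0.01:
                    not_rejected += 1
        assert not_rejected / total >= 0.95


class TestScoreRecovery:
    def test_perfect_results_score_one(self, small_dataset):
        t = small_dataset.truth
        metrics = score_recovery(
            t,
            {
                "dhs_changing": list(t.dhs_changing.index[t.dhs_changing]),
                "links": t.gene_links.rename(columns={"weight": "r"}),
                "dhs_clusters": t.dhs_module,
                "tf_modules": t.tf_module,
            },
        )
        assert metrics["dhs_changing"]["f1"] == 1.0
        assert metrics["links"]["f1"] == 1.0
        assert metrics["cluster_ari"] == 1.0
        assert metrics["module_ari"] == 1.0

    def test_permuted_module_labels_score_near_zero(self, small_dataset):
        t = small_dataset.truth
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(100):
            perm = pd.Series(
                rng.permutation(t.tf_module.to_numpy()), index=t.tf_module.index
            )
            aris.append(score_recovery(t, {"tf_modules": perm})["module_ari"])
        assert abs(np.mean(aris)) < 0.1

    def test_half_links_dropped(self, small_dataset):
        t = small_dataset.truth
        half = t.gene_links.iloc[: len(t.gene_links) // 2]
        m = score_recovery(t, {"links": half})["links"]
        assert m["precision"] == 1.0
        assert m["recall"] == pytest.approx(len(half) / len(t.gene_links))

    def test_unknown_id_raises(self, small_dataset):
        with pytest.raises(ValueError, match="nosuch"):
            score_recovery(small_dataset.truth, {"dhs_changing": ["nosuch"]})


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_dhs": 0},
            {"frac_changing_dhs": 1.5},
            {"noise_sd": -1.0},
            {"n_modules": 50, "n_tf": 5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(SimulationConfig(**kwargs))

    def test_planted_links_within_window(self, small_dataset):
        ds = small_dataset
        ann = ds.annotation.set_index("gene_id")
        mid = {iv.id: iv.midpoint for iv in ds.intervals}
        for row in ds.truth.gene_links.itertuples(index=False):
            dist = abs(mid[row.dhs_id] - ann.loc[row.gene_id, "tss"])
            assert dist <= ds.config.link_window

    def test_beyond_window_decoys_outside_window(self, small_dataset):
        ds = small_dataset
        ann = ds.annotation.set_index("gene_id")
        mid = {iv.id: iv.midpoint for iv in ds.intervals}
        assert len(ds.truth.beyond_window_decoys) > 0
        for row in ds.truth.beyond_window_decoys.itertuples(index=False):
            dist = abs(mid[row.dhs_id] - ann.loc[row.gene_id, "tss"])
            assert dist > ds.config.link_window
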