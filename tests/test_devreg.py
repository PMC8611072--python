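import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from regmodkit.devreg import (
    call_regulated,
    fit_developmental_model,
    fit_matrix,
    natural_spline_basis,
    quantile_normalize,
)

DAYS = np.repeat(np.arange(13), 3)


from _oracles import ols_lrt_oracle


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_hand_computed_reference(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize(df)
        expected = [5.5, 11.0, 16.5]
        np.testing.assert_allclose(out["a"], expected)
        np.testing.assert_allclose(out["b"], expected)

    def test_tie_rule_averages_reference_slots(self):
        # sorted refs: mean([5,1])=3, mean([5,2])=3.5, mean([8,3])=5.5;
        # ties 5,5 in column a occupy slots 1-2 -> both get (3+3.5)/2
        df = pd.DataFrame({"a": [5.0, 5.0, 8.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [3.25, 3.25, 5.5])
        np.testing.assert_allclose(out["b"], [3.0, 3.5, 5.5])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            quantile_normalize(pd.DataFrame({"a": [-1.0, 2.0], "b": [1.0, 2.0]}))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            (8, 3),
            elements=st.floats(0, 100, allow_nan=False, width=32),
        )
    )
    def test_columns_share_sorted_distribution(self, values):
        """After normalization every column has the same multiset of values
        up to tie-averaging; column means are equal."""
        df = pd.DataFrame(values, columns=["a", "b", "c"])
        out = quantile_normalize(df)
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0], rtol=1e-9, atol=1e-9)


class TestDevelopmentalFit:
    def test_constant_profile_is_null(self):
        fit = fit_developmental_model(np.full(39, 7.0), DAYS)
        assert fit.lrt_stat == 0.0
        assert fit.p_raw == 1.0

    def test_linear_ramp_is_highly_significant(self, rng):
        y = DAYS + rng.normal(0, 0.1, len(DAYS))
        fit = fit_developmental_model(y, DAYS, mode="ols")
        assert fit.p_raw < 1e-10
        # -log10 p within 10% of the normal-equation oracle
        from scipy.stats import chi2

        p_oracle = chi2.sf(ols_lrt_oracle(y - y.mean(), DAYS), 3)
        assert np.isclose(
            -np.log10(fit.p_raw), -np.log10(p_oracle), rtol=0.1
        )

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(20):
            y = rng.normal(size=39) + rng.uniform(-1, 1) * DAYS
            yc = y - y.mean()
            fit = fit_developmental_model(y, DAYS, mode="ols")
            assert np.isclose(fit.lrt_stat, ols_lrt_oracle(yc, DAYS), rtol=1e-8)

    def test_signal_monotonicity(self, rng):
        """Adding a spline-representable signal to a null profile never
        decreases the LRT (the full-model residual is unchanged while the
        null-model residual grows)."""
        signal = natural_spline_basis(DAYS) @ np.array([2.0, -1.0, 1.5])
        for _ in range(100):
            noise = rng.normal(size=39)
            null = fit_developmental_model(noise, DAYS, mode="ols").lrt_stat
            with_sig = fit_developmental_model(noise + signal, DAYS, mode="ols").lrt_stat
            assert with_sig >= null - 1e-9

    def test_too_few_days_error(self):
        with pytest.raises(ValueError, match="4 distinct days"):
            fit_developmental_model(np.arange(9.0), np.repeat([0, 1, 2], 3))

    def test_robust_mode_agrees_on_clean_signal(self, rng):
        y = np.sin(DAYS / 3) * 5 + rng.normal(0, 0.3, len(DAYS))
        ols = fit_developmental_model(y, DAYS, mode="ols")
        rob = fit_developmental_model(y, DAYS, mode="robust")
        assert rob.p_raw < 1e-6
        assert np.isclose(rob.lrt_stat, ols.lrt_stat, rtol=0.5)

    def test_robust_mode_resists_outlier(self, rng):
        y = np.sin(DAYS / 3) * 5 + rng.normal(0, 0.3, len(DAYS))
        y_out = y.copy()
        y_out[5] += 100.0
        clean = fit_developmental_model(y, DAYS, mode="robust")
        dirty = fit_developmental_model(y_out, DAYS, mode="robust")
        # fitted curve barely moves despite the gross outlier
        assert np.max(np.abs(dirty.fitted_daily - clean.fitted_daily)) < 5.0

    def test_fit_matrix_matches_per_feature(self, make_tcm, rng):
        values = rng.normal(10, 2, size=(5, 39)).clip(0)
        tcm = make_tcm(values, DAYS)
        table = fit_matrix(tcm, mode="ols")
        for i, fid in enumerate(tcm.feature_ids):
            single = fit_developmental_model(values[i], DAYS, mode="ols")
            assert np.isclose(table.loc[i, "lrt_stat"], single.lrt_stat, rtol=1e-10)


class TestCallRegulated:
    def _fits(self, p_raw, log2_range, max_daily):
        n = len(p_raw)
        df = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(n)],
                "lrt_stat": 1.0,
                "p_raw": p_raw,
                "p_adj": np.nan,
                "log2_range": log2_range,
                "max_daily_mean": max_daily,
                "regulated": False,
                "direction": "other",
            }
        )
        df["fitted_day_0"] = 0.0
        df["fitted_day_1"] = 1.0
        df["fitted_day_2"] = 2.0
        df["fitted_day_3"] = 3.0
        return df

    def test_bh_hand_computation(self):
        out = call_regulated(self._fits([0.01, 0.02, 0.03], [2] * 3, [50] * 3), "dhs")
        np.testing.assert_allclose(out["p_adj"], [0.03, 0.03, 0.03])

    def test_adjusted_p_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        out = call_regulated(self._fits(p, [2] * 50, [50] * 50), "dhs")
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_dhs_density_boundary(self):
        fits = self._fits([1e-9, 1e-9], [1.3, 1.3], [35.0, 29.0])
        out = call_regulated(fits, "dhs")
        assert out.loc[0, "regulated"]
        assert not out.loc[1, "regulated"]

    def test_gene_fpkm_threshold(self):
        fits = self._fits([1e-9, 1e-9], [1.3, 1.3], [2.5, 1.5])
        out = call_regulated(fits, "gene")
        assert out.loc[0, "regulated"]
        assert not out.loc[1, "regulated"]

    def test_direction_rule(self):
        fits = self._fits([1e-9] * 3, [2] * 3, [50] * 3)
        rising = fits.copy()  # fitted_day_* columns default to 0,1,2,3
        falling = fits.copy()
        for j, c in enumerate(["fitted_day_0", "fitted_day_1", "fitted_day_2", "fitted_day_3"]):
            falling[c] = 3 - j
        out_r = call_regulated(rising, "dhs")
        out_f = call_regulated(falling, "dhs")
        assert (out_r["direction"] == "activated").all()
        assert (out_f["direction"] == "silenced").all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="feature_kind"):
            call_regulated(self._fits([0.5], [0.0], [1.0]), "protein")
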