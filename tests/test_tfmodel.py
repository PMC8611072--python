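import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from regmodkit.io_formats import MotifHitTable
from regmodkit.tfmodel import (
    ElasticNetConfig,
    _cd_kernel_py,
    build_design,
    cv_select_cluster_params,
    elastic_net_objective,
    fit_elastic_net_final,
    kkt_violations,
    model_summary,
    naive_bayes_cluster_benchmark,
    TFCoefficientMatrix,
)


def random_problem(rng, n=13, p=6):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta_true = rng.normal(size=p) * (rng.random(p) < 0.5)
    y = X @ beta_true + rng.normal(0, 0.5, n)
    return X, y - y.mean()


class TestSolver:
    def test_single_predictor_ols_limit(self, rng):
        x = rng.normal(size=13)
        x = (x - x.mean()) / x.std()
        beta, b0 = fit_elastic_net_final(x[:, None], x.copy(), alpha=0.3, lam=1e-8)
        assert beta[0] == pytest.approx(1.0, abs=1e-4)
        assert b0 == pytest.approx(0.0, abs=1e-6)

    def test_lasso_null_threshold(self, rng):
        for alpha in (0.2, 0.6, 1.0):
            X, y = random_problem(rng)
            lam_max = np.max(np.abs(X.T @ y)) / (len(y) * alpha)
            beta, _ = fit_elastic_net_final(X, y, alpha=alpha, lam=lam_max * 1.0001)
            assert np.all(beta == 0.0)
            beta2, _ = fit_elastic_net_final(X, y, alpha=alpha, lam=lam_max * 0.9)
            assert np.any(beta2 != 0.0)

    def test_ridge_matches_closed_form(self, rng):
        for _ in range(10):
            X, y = random_problem(rng)
            lam = 10.0 ** rng.uniform(-3, 1)
            beta, _ = fit_elastic_net_final(X, y, alpha=0.0, lam=lam, tol=1e-12)
            n = len(y)
            Xc = X - X.mean(axis=0)
            closed = np.linalg.solve(
                Xc.T @ Xc + n * lam * np.eye(X.shape[1]), Xc.T @ y
            )
            np.testing.assert_allclose(beta, closed, atol=1e-6)

    def test_kkt_conditions_hold(self, rng):
        for _ in range(20):
            X, y = random_problem(rng)
            alpha = float(rng.uniform(0.05, 1.0))
            lam = 10.0 ** rng.uniform(-3, 0)
            beta, b0 = fit_elastic_net_final(X, y, alpha=alpha, lam=lam)
            assert kkt_violations(X, y, beta, b0, alpha, lam).max() < 1e-5

    def test_objective_decreases_across_sweeps(self, rng):
        X, y = random_problem(rng, p=8)
        alpha, lam = 0.5, 0.05
        n = len(y)
        Xc = X - X.mean(axis=0)
        G, c = Xc.T @ Xc, Xc.T @ y
        beta = np.zeros(X.shape[1])
        objs = [elastic_net_objective(X, y, beta, 0.0, alpha, lam)]
        for _ in range(30):
            beta = _cd_kernel_py(G, c, float(n), lam, alpha, beta, 1, 0.0)
            objs.append(elastic_net_objective(X, y, beta, 0.0, alpha, lam))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_path_sparsity_decreases_on_average(self, rng):
        lams = np.logspace(-3, 1, 15)
        counts = np.zeros((20, len(lams)))
        for i in range(20):
            X, y = random_problem(rng)
            for j, lam in enumerate(lams):
                beta, _ = fit_elastic_net_final(X, y, alpha=1.0, lam=lam)
                counts[i, j] = (beta != 0).sum()
        mean_counts = counts.mean(axis=0)
        assert all(b <= a + 1e-9 for a, b in zip(mean_counts, mean_counts[1:]))

    def test_non_finite_design_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net_final(np.array([[np.inf]]), np.array([1.0]), 0.5, 0.1)


def _expr(rows):
    df = pd.DataFrame(rows).T
    df.columns = range(13)
    return df


class TestBuildDesign:
    hits = MotifHitTable(
        pd.DataFrame(
            {
                "dhs_id": ["d1", "d1", "d1"],
                "tf_name": ["TFa", "TFb", "TFc"],
                "hit_count": [1, 2, 1],
            }
        )
    )

    def test_fpkm_filter_drops_low_expressed_tf(self):
        expr = _expr({
            "TFa": np.linspace(1, 10, 13),
            "TFb": np.linspace(0.1, 1.5, 13),  # max below 2 FPKM
            "TFc": np.linspace(2, 8, 13),
        })
        des = build_design("d1", self.hits, expr, np.linspace(5, 50, 13),
                           require_regulated_tf=False)
        assert des.tf_names == ["TFa", "TFc"]
        np.testing.assert_allclose(des.X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(des.X.std(axis=0), 1, atol=1e-12)

    def test_no_hits_is_unmodelable(self):
        expr = _expr({"TFa": np.linspace(1, 10, 13)})
        des = build_design("d9", self.hits, expr, np.linspace(5, 50, 13),
                           require_regulated_tf=False)
        assert not des.modelable
        assert des.tf_names == []

    def test_constant_tf_dropped_with_warning(self):
        expr = _expr({"TFa": np.full(13, 5.0), "TFc": np.linspace(2, 8, 13)})
        with pytest.warns(UserWarning, match="constant"):
            des = build_design("d1", self.hits, expr, np.linspace(5, 50, 13),
                               require_regulated_tf=False)
        assert des.tf_names == ["TFc"]

    def test_regulated_tf_filter(self):
        expr = _expr({"TFa": np.linspace(1, 10, 13), "TFc": np.linspace(2, 8, 13)})
        des = build_design("d1", self.hits, expr, np.linspace(5, 50, 13),
                           require_regulated_tf=True, regulated_tfs={"TFc"})
        assert des.tf_names == ["TFc"]


class TestClusterCV:
    def _design(self, rng, noise=0.0):
        x = np.linspace(0, 1, 13)
        X = ((x - x.mean()) / x.std())[:, None]
        y = 20 * X[:, 0] + rng.normal(0, noise, 13)
        from regmodkit.tfmodel import Design

        return Design("d1", ["TFa"], X, y - y.mean(), float(y.mean()), True)

    def test_noiseless_recovery_selects_tiny_penalty(self, rng):
        des = self._design(rng)
        cfg = ElasticNetConfig(
            alpha_grid=np.array([0.5]), lambda_grid=np.logspace(-5, 5, 20),
            n_repeats=10, seed=0,
        )
        params = cv_select_cluster_params([des], cfg)
        beta, b0 = fit_elastic_net_final(des.X, des.y, params.alpha, params.lam)
        heldout_mse = np.mean((des.y - b0 - des.X @ beta) ** 2)
        assert heldout_mse < 1e-3 * des.y.var()

    def test_pure_noise_selects_sparsest_model(self, rng):
        from regmodkit.tfmodel import Design

        X = rng.normal(size=(13, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = rng.normal(size=13)
        des = Design("d1", ["a", "b", "c"], X, y - y.mean(), 0.0, True)
        cfg = ElasticNetConfig(
            alpha_grid=np.linspace(0, 1, 5), lambda_grid=np.logspace(-2, 5, 10),
            n_repeats=10, seed=0,
        )
        params = cv_select_cluster_params([des], cfg)
        assert params.lam == pytest.approx(cfg.lambda_grid.max())
        beta, _ = fit_elastic_net_final(des.X, des.y, params.alpha, params.lam)
        assert np.all(beta == 0.0)

    def test_deterministic_given_seed(self, rng):
        des = self._design(rng, noise=2.0)
        cfg = ElasticNetConfig(
            alpha_grid=np.linspace(0, 1, 3), lambda_grid=np.logspace(-3, 2, 8),
            n_repeats=5, seed=42,
        )
        p1 = cv_select_cluster_params([des], cfg)
        p2 = cv_select_cluster_params([des], cfg)
        assert (p1.alpha, p1.lam) == (p2.alpha, p2.lam)

    def test_too_few_training_days_rejected(self, rng):
        des = self._design(rng)
        cfg = ElasticNetConfig(n_heldout_days=9)
        with pytest.raises(ValueError, match="at least 6"):
            cv_select_cluster_params([des], cfg)


class TestModelSummary:
    def _coefs(self, rows):
        return TFCoefficientMatrix(
            coefficients=pd.DataFrame(rows, columns=["dhs_id", "tf_name", "coefficient"]),
            intercepts=pd.Series(dtype=float),
            train_mse=pd.Series(dtype=float),
            cluster_params=pd.DataFrame(),
        )

    def test_positive_count(self):
        coefs = self._coefs(
            [("d1", "a", 0.5), ("d1", "b", 0.2), ("d1", "c", -0.3)]
        )
        s = model_summary(coefs, ["d1"])
        assert s["positive_per_dhs"]["d1"] == 2
        assert s["frac_modeled"] == 1.0

    def test_all_zero_matrix(self):
        s = model_summary(self._coefs([]), ["d1", "d2"])
        assert s["frac_modeled"] == 0.0


class TestNaiveBayes:
    def test_separable_counts_classify_perfectly(self):
        n = 20
        counts = pd.DataFrame(
            {"TFa": [0] * n + [10] * n}, index=[f"d{i}" for i in range(2 * n)]
        )
        coefs = pd.DataFrame(
            {"TFa": [1.0] * (2 * n)}, index=counts.index
        )
        labels = pd.Series([1] * n + [2] * n, index=counts.index)
        nb_counts, _, _ = naive_bayes_cluster_benchmark(counts, coefs, labels, seed=0)
        assert nb_counts.mean_accuracy == 1.0
        assert nb_counts.confusion.to_numpy().sum() == 2 * n

    def test_poisson_posterior_matches_enumeration(self):
        """Resubstitution posterior for a 2-class, 2-TF problem equals the
        explicit Poisson likelihood arithmetic."""
        counts = pd.DataFrame(
            {"TFa": [0, 1, 5, 6], "TFb": [3, 4, 0, 1]},
            index=["d1", "d2", "d3", "d4"],
        )
        coefs = pd.DataFrame(
            {"TFa": [1.0] * 4, "TFb": [1.0] * 4}, index=counts.index
        )
        labels = pd.Series([1, 1, 2, 2], index=counts.index)
        nb_counts, _, _ = naive_bayes_cluster_benchmark(
            counts, coefs, labels, resubstitution=True, seed=0
        )
        # hand arithmetic for d1 = (0, 3): rates class1 = (0.6, 3.6),
        # class2 = (5.6, 0.6); equal priors
        def loglik(x, rates):
            return sum(
                xi * np.log(r) - r - gammaln(xi + 1) for xi, r in zip(x, rates)
            )

        l1 = np.log(0.5) + loglik([0, 3], [0.6, 3.6])
        l2 = np.log(0.5) + loglik([0, 3], [5.6, 0.6])
        assert l1 > l2  # d1 must be classified into class 1
        assert nb_counts.mean_accuracy == 1.0
        from regmodkit.tfmodel import _nb_predict_poisson

        lp = _nb_predict_poisson(
            counts.to_numpy(float), labels.to_numpy(), counts.to_numpy(float)[:1], [1, 2]
        )
        assert lp[0, 0] == pytest.approx(l1, abs=1e-10)
        assert lp[0, 1] == pytest.approx(l2, abs=1e-10)

    def test_small_class_suggests_fewer_folds(self):
        counts = pd.DataFrame({"TFa": [0, 10, 0]}, index=["d1", "d2", "d3"])
        coefs = pd.DataFrame({"TFa": [1.0] * 3}, index=counts.index)
        labels = pd.Series([1, 2, 1], index=counts.index)
        with pytest.raises(ValueError, match="fewer folds"):
            naive_bayes_cluster_benchmark(counts, coefs, labels, cv_folds=5)
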