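"""Elastic-net modeling of DHS accessibility from TF expression.

Each regulated DHS's per-day mean accessibility is modeled as a linear
function of the per-day mean expression of its *candidate* TFs — those
with a motif hit inside the DHS, maximum expression above an FPKM floor
and (optionally) a developmental-regulation call.  The fit minimizes

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

by cyclic coordinate descent on the precomputed Gram matrix, warm-started
along the lambda path (numba-accelerated when available).

Hyperparameters are chosen per temporal DHS cluster rather than per DHS:
for every (alpha, lambda) on the grid and every random held-out day set
(default 4 days, 100 repeats), models are trained on the remaining days
and scored on the held-out days; the cluster objective sums each DHS's
mean held-out MSE plus its standard error, and the minimizing pair —
ties resolved toward larger lambda, then larger alpha, i.e. the sparser
model — is used for the final all-days fits.

A naive Bayes benchmark asks whether the resulting coefficient vectors
predict a DHS's temporal cluster better than raw motif counts do: counts
are modeled per (class, TF) as Poisson, coefficients as Gaussian, under
stratified cross-validation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.model_selection import StratifiedKFold

from .io_formats import MotifHitTable

__all__ = [
    "ElasticNetConfig",
    "Design",
    "TFCoefficientMatrix",
    "NBResult",
    "build_design",
    "fit_elastic_net_final",
    "elastic_net_objective",
    "kkt_violations",
    "cv_select_cluster_params",
    "fit_cluster_models",
    "model_summary",
    "naive_bayes_cluster_benchmark",
]


def _default_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def _default_lambda_grid() -> np.ndarray:
    return np.logspace(-5.0, 5.0, 100)


@dataclass
class ElasticNetConfig:
    """Hyperparameter search grid and validation protocol."""

    alpha_grid: np.ndarray = field(default_factory=_default_alpha_grid)
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    n_heldout_days: int = 4
    n_repeats: int = 100
    seed: int = 0
    tol: float = 1e-7
    max_iter: int = 1000
    objective: str = "mse_plus_se"  # or "mse"

    def validate(self, n_days: int) -> None:
        a = np.asarray(self.alpha_grid, float)
        l = np.asarray(self.lambda_grid, float)
        if a.size == 0 or l.size == 0:
            raise ValueError("empty hyperparameter grid")
        if (a < 0).any() or (a > 1).any():
            raise ValueError("alpha must be in [0, 1]")
        if (l <= 0).any():
            raise ValueError("lambda must be > 0")
        if self.n_heldout_days >= n_days:
            raise ValueError("n_heldout_days must be < n_days")
        if n_days - self.n_heldout_days < 6:
            raise ValueError(
                f"held-out set leaves {n_days - self.n_heldout_days} training "
                "days; at least 6 required"
            )
        if self.objective not in {"mse_plus_se", "mse"}:
            raise ValueError(f"unknown objective {self.objective!r}")


# ---------------------------------------------------------------------------
# coordinate descent kernel
# ---------------------------------------------------------------------------

def _cd_kernel_py(G, c, n, lam, alpha, beta, max_iter, tol):
    p = G.shape[0]
    for _ in range(max_iter):
        maxd = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                beta[j] = 0.0
                continue
            rho = c[j]
            for kk in range(p):
                if kk != j:
                    rho -= G[j, kk] * beta[kk]
            rho /= n
            t = lam * alpha
            if rho > t:
                z = rho - t
            elif rho < -t:
                z = rho + t
            else:
                z = 0.0
            nb = z / (gjj / n + lam * (1.0 - alpha))
            d = abs(nb - beta[j])
            if d > maxd:
                maxd = d
            beta[j] = nb
        if maxd < tol:
            break
    return beta


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _cd_kernel = njit(cache=False)(_cd_kernel_py)
except Exception:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def fit_elastic_net_final(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 1000,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Solve the elastic-net problem on all days; returns (beta, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite design or response")
    n = len(y)
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = y.mean()
    yc = y - ym
    G = Xc.T @ Xc
    c = Xc.T @ yc
    beta = np.zeros(X.shape[1]) if beta0 is None else np.asarray(beta0, float).copy()
    beta = _cd_kernel(G, c, float(n), float(lam), float(alpha), beta, max_iter, tol)
    intercept = ym - float(xm @ beta)
    return np.asarray(beta), intercept


def elastic_net_objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    alpha: float, lam: float,
) -> float:
    n = len(y)
    r = y - intercept - X @ beta
    return float(
        (r @ r) / (2 * n)
        + lam * (alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta)
    )


def kkt_violations(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    alpha: float, lam: float,
) -> np.ndarray:
    """Per-coefficient violation of the elastic-net stationarity conditions.

    For inactive coefficients the subgradient condition requires
    |(1/n) X_j'(y - yhat)| <= lambda * alpha; for active ones the gradient
    must vanish.  Returns max(violation, 0) per coefficient.
    """
    n = len(y)
    r = y - intercept - X @ beta
    Xc = X - X.mean(axis=0)
    g = Xc.T @ r / n - lam * (1 - alpha) * beta
    out = np.empty_like(beta)
    for j in range(len(beta)):
        if beta[j] == 0.0:
            out[j] = max(abs(g[j]) - lam * alpha, 0.0)
        else:
            out[j] = abs(g[j] - lam * alpha * np.sign(beta[j]))
    return out


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Standardized predictors for one DHS: days x candidate TFs."""

    dhs_id: str
    tf_names: list[str]
    X: np.ndarray  # days x TFs, z-scored per TF
    y: np.ndarray  # per-day mean DHS density, centered
    y_mean: float
    modelable: bool
    dropped_constant: list[str] = field(default_factory=list)


def build_design(
    dhs_id: str,
    motif_hits: MotifHitTable,
    tf_expression: pd.DataFrame,
    dhs_profile: pd.Series | np.ndarray,
    min_max_fpkm: float = 2.0,
    require_regulated_tf: bool = True,
    regulated_tfs: set[str] | None = None,
) -> Design:
    """Assemble the candidate-TF design for one DHS.

    Candidates are TFs with >= 1 motif hit in the DHS, maximum daily mean
    expression > ``min_max_fpkm`` and, when ``require_regulated_tf``, a
    developmental-regulation call (``regulated_tfs``).  Predictors are
    z-scored across days; the response is the centered per-day mean DHS
    density.  A DHS with no candidates is returned unmodelable.
    """
    if require_regulated_tf and regulated_tfs is None:
        raise ValueError("require_regulated_tf=True needs regulated_tfs")
    t = motif_hits.table
    with_hit = set(t.loc[(t["dhs_id"] == dhs_id) & (t["hit_count"] >= 1), "tf_name"])
    y_raw = np.asarray(dhs_profile, dtype=float)
    candidates = []
    dropped = []
    for tf in sorted(with_hit):
        if tf not in tf_expression.index:
            continue
        expr = tf_expression.loc[tf].to_numpy(dtype=float)
        if expr.max() <= min_max_fpkm:
            continue
        if require_regulated_tf and tf not in regulated_tfs:
            continue
        sd = expr.std()
        if sd == 0:
            dropped.append(tf)
            continue
        candidates.append((tf, (expr - expr.mean()) / sd))
    if dropped:
        warnings.warn(f"{dhs_id}: dropped constant TF profile(s): {dropped}")
    y_mean = float(y_raw.mean())
    if not candidates:
        return Design(dhs_id, [], np.zeros((len(y_raw), 0)), y_raw - y_mean,
                      y_mean, False, dropped)
    names = [t_ for t_, _ in candidates]
    X = np.column_stack([v for _, v in candidates])
    return Design(dhs_id, names, X, y_raw - y_mean, y_mean, True, dropped)


def build_designs_for_cluster(
    dhs_ids: list[str],
    motif_hits: MotifHitTable,
    tf_expression: pd.DataFrame,
    dhs_day_means: pd.DataFrame,
    **kwargs,
) -> list[Design]:
    return [
        build_design(d, motif_hits, tf_expression, dhs_day_means.loc[d], **kwargs)
        for d in dhs_ids
    ]


# ---------------------------------------------------------------------------
# cluster-level hyperparameter selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterParams:
    alpha: float
    lam: float
    objective: pd.DataFrame  # alpha x lambda cluster objective surface


def cv_select_cluster_params(
    designs: list[Design], config: ElasticNetConfig
) -> ClusterParams:
    """Choose (alpha, lambda) for one DHS cluster by repeated leave-days-out.

    Deterministic for a given ``config.seed``: the same held-out day sets
    are reused across the whole grid and across DHSs, so comparisons are
    paired.
    """
    designs = [d for d in designs if d.modelable]
    if not designs:
        raise ValueError("no modelable DHS in cluster")
    n_days = len(designs[0].y)
    config.validate(n_days)
    alphas = np.asarray(config.alpha_grid, float)
    lams = np.asarray(config.lambda_grid, float)
    lam_order = np.argsort(lams)[::-1]  # descending for warm starts
    rng = np.random.default_rng(config.seed)
    heldout = [
        np.sort(rng.choice(n_days, size=config.n_heldout_days, replace=False))
        for _ in range(config.n_repeats)
    ]
    A, L, R = len(alphas), len(lams), config.n_repeats
    mse = np.empty((len(designs), R, A, L))
    for di, des in enumerate(designs):
        X, y = des.X, des.y
        for ri, te in enumerate(heldout):
            mask = np.ones(n_days, dtype=bool)
            mask[te] = False
            Xtr, ytr = X[mask], y[mask]
            Xte, yte = X[te], y[te]
            xm = Xtr.mean(axis=0)
            ym = ytr.mean()
            Xc = Xtr - xm
            yc = ytr - ym
            G = Xc.T @ Xc
            cvec = Xc.T @ yc
            ntr = float(len(ytr))
            Xte_c = Xte - xm
            for ai, a in enumerate(alphas):
                beta = np.zeros(X.shape[1])
                for li in lam_order:
                    beta = _cd_kernel(
                        G, cvec, ntr, float(lams[li]), float(a), beta,
                        config.max_iter, config.tol,
                    )
                    pred = Xte_c @ beta + ym
                    err = yte - pred
                    mse[di, ri, ai, li] = float(err @ err) / len(yte)
    mean_mse = mse.mean(axis=1)  # dhs x A x L
    if R > 1:
        se = mse.std(axis=1, ddof=1) / np.sqrt(R)
    else:
        se = np.zeros_like(mean_mse)
    if config.objective == "mse_plus_se":
        surface = (mean_mse + se).sum(axis=0)
    else:
        surface = mean_mse.sum(axis=0)
    best = surface.min()
    tie_tol = 1e-12 * max(1.0, abs(best))
    cand = np.argwhere(surface <= best + tie_tol)
    # sparser wins ties: larger lambda, then larger alpha
    order = sorted(
        (tuple(ij) for ij in cand),
        key=lambda ij: (lams[ij[1]], alphas[ij[0]]),
        reverse=True,
    )
    ai, li = order[0]
    return ClusterParams(
        alpha=float(alphas[ai]),
        lam=float(lams[li]),
        objective=pd.DataFrame(surface, index=alphas, columns=lams),
    )


# ---------------------------------------------------------------------------
# final fits and summaries
# ---------------------------------------------------------------------------

@dataclass
class TFCoefficientMatrix:
    """Final per-(DHS, TF) elastic-net coefficients and fit metadata."""

    coefficients: pd.DataFrame  # columns dhs_id, tf_name, coefficient
    intercepts: pd.Series  # dhs_id -> intercept (original scale)
    train_mse: pd.Series  # dhs_id -> training MSE
    cluster_params: pd.DataFrame  # columns cluster, alpha, lam
    unmodelable: list[str] = field(default_factory=list)

    def to_wide(self, dhs_ids=None, tf_names=None) -> pd.DataFrame:
        c = self.coefficients
        wide = c.pivot(index="dhs_id", columns="tf_name", values="coefficient")
        if dhs_ids is not None:
            wide = wide.reindex(index=list(dhs_ids))
        if tf_names is not None:
            wide = wide.reindex(columns=list(tf_names))
        return wide.fillna(0.0)


def fit_cluster_models(
    cluster_designs: dict, config: ElasticNetConfig
) -> TFCoefficientMatrix:
    """CV-select (alpha, lambda) per cluster, then refit every DHS on all days."""
    coef_rows = []
    intercepts = {}
    train_mse = {}
    params_rows = []
    unmodelable = []
    for cluster in sorted(cluster_designs):
        designs = cluster_designs[cluster]
        modelable = [d for d in designs if d.modelable]
        unmodelable.extend(d.dhs_id for d in designs if not d.modelable)
        if not modelable:
            params_rows.append({"cluster": cluster, "alpha": np.nan, "lam": np.nan})
            continue
        params = cv_select_cluster_params(modelable, config)
        params_rows.append(
            {"cluster": cluster, "alpha": params.alpha, "lam": params.lam}
        )
        for des in modelable:
            beta, b0 = fit_elastic_net_final(
                des.X, des.y, params.alpha, params.lam,
                tol=config.tol, max_iter=config.max_iter,
            )
            resid = des.y - b0 - des.X @ beta
            train_mse[des.dhs_id] = float(resid @ resid) / len(des.y)
            intercepts[des.dhs_id] = b0 + des.y_mean
            for tf, b in zip(des.tf_names, beta):
                if b != 0.0:
                    coef_rows.append(
                        {"dhs_id": des.dhs_id, "tf_name": tf, "coefficient": float(b)}
                    )
    coefficients = pd.DataFrame(coef_rows, columns=["dhs_id", "tf_name", "coefficient"])
    return TFCoefficientMatrix(
        coefficients=coefficients,
        intercepts=pd.Series(intercepts, name="intercept", dtype=float),
        train_mse=pd.Series(train_mse, name="train_mse", dtype=float),
        cluster_params=pd.DataFrame(params_rows, columns=["cluster", "alpha", "lam"]),
        unmodelable=unmodelable,
    )


def model_summary(coefs: TFCoefficientMatrix, all_dhs_ids: list[str]) -> dict:
    """Connectivity summary of the final coefficient matrix."""
    c = coefs.coefficients
    nz_per_dhs = c.groupby("dhs_id").size().reindex(all_dhs_ids, fill_value=0)
    pos = c[c["coefficient"] > 0]
    pos_per_dhs = pos.groupby("dhs_id").size().reindex(all_dhs_ids, fill_value=0)
    pos_per_tf = pos.groupby("tf_name").size().sort_index()
    return {
        "n_dhs": len(all_dhs_ids),
        "frac_modeled": float((nz_per_dhs > 0).mean()) if len(all_dhs_ids) else 0.0,
        "mean_positive_tfs_per_dhs": float(pos_per_dhs.mean()) if len(all_dhs_ids) else 0.0,
        "nonzero_per_dhs": nz_per_dhs,
        "positive_per_dhs": pos_per_dhs,
        "positive_dhs_per_tf": pos_per_tf,
    }


# ---------------------------------------------------------------------------
# naive Bayes benchmark
# ---------------------------------------------------------------------------

@dataclass
class NBResult:
    feature_mode: str
    fold_accuracy: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame  # true class x predicted class


POISSON_PSEUDORATE = 0.1
GAUSSIAN_VAR_FLOOR = 1e-6


def _nb_predict_poisson(train_X, train_y, test_X, classes):
    log_post = np.zeros((len(test_X), len(classes)))
    for ci, c in enumerate(classes):
        sub = train_X[train_y == c]
        prior = len(sub) / len(train_X)
        rate = sub.mean(axis=0) + POISSON_PSEUDORATE
        log_post[:, ci] = (
            np.log(prior)
            + (test_X * np.log(rate) - rate - gammaln(test_X + 1)).sum(axis=1)
        )
    return log_post


def _nb_predict_gaussian(train_X, train_y, test_X, classes):
    log_post = np.zeros((len(test_X), len(classes)))
    for ci, c in enumerate(classes):
        sub = train_X[train_y == c]
        prior = len(sub) / len(train_X)
        mu = sub.mean(axis=0)
        var = np.maximum(sub.var(axis=0), GAUSSIAN_VAR_FLOOR)
        log_post[:, ci] = np.log(prior) + (
            -0.5 * np.log(2 * np.pi * var) - 0.5 * (test_X - mu) ** 2 / var
        ).sum(axis=1)
    return log_post


def _nb_cv(X, y, classes, predictor, cv_folds, seed, resubstitution=False):
    n = len(y)
    accs = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    if resubstitution:
        splits = [(np.arange(n), np.arange(n))]
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    for tr, te in splits:
        log_post = predictor(X[tr], y[tr], X[te], classes)
        pred = np.asarray(classes)[np.argmax(log_post, axis=1)]
        accs.append(float((pred == y[te]).mean()))
        for t, p in zip(y[te], pred):
            confusion[class_index[t], class_index[p]] += 1
    return np.array(accs), confusion


def naive_bayes_cluster_benchmark(
    motif_counts: pd.DataFrame,
    coef_wide: pd.DataFrame,
    cluster_labels: pd.Series,
    tf_subset: list[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    resubstitution: bool = False,
) -> tuple[NBResult, NBResult, float]:
    """Predict each DHS's temporal cluster from motif counts vs coefficients.

    Returns (counts result, coefficients result, accuracy ratio
    coefficients/counts).  Both feature tables must cover the labeled DHSs;
    ``tf_subset`` defaults to TFs with at least one nonzero coefficient.
    """
    dhs_ids = list(cluster_labels.index)
    if tf_subset is None:
        nz = (coef_wide.reindex(index=dhs_ids).fillna(0.0) != 0).any(axis=0)
        tf_subset = list(coef_wide.columns[nz])
    if not tf_subset:
        raise ValueError("empty TF subset for naive Bayes benchmark")
    counts = motif_counts.reindex(index=dhs_ids, columns=tf_subset).fillna(0.0).to_numpy()
    coefs = coef_wide.reindex(index=dhs_ids, columns=tf_subset).fillna(0.0).to_numpy()
    y = cluster_labels.to_numpy()
    classes = sorted(pd.unique(y))
    smallest = min((y == c).sum() for c in classes)
    if not resubstitution and smallest < cv_folds:
        raise ValueError(
            f"smallest class has {smallest} members < {cv_folds} folds; "
            "use fewer folds"
        )
    acc_c, conf_c = _nb_cv(counts, y, classes, _nb_predict_poisson, cv_folds, seed,
                           resubstitution)
    acc_b, conf_b = _nb_cv(coefs, y, classes, _nb_predict_gaussian, cv_folds, seed,
                           resubstitution)
    labels = [str(c) for c in classes]
    res_counts = NBResult(
        "motif_counts_poisson", acc_c, float(acc_c.mean()),
        pd.DataFrame(conf_c, index=labels, columns=labels),
    )
    res_coefs = NBResult(
        "coefficients_gaussian", acc_b, float(acc_b.mean()),
        pd.DataFrame(conf_b, index=labels, columns=labels),
    )
    ratio = res_coefs.mean_accuracy / res_counts.mean_accuracy if res_counts.mean_accuracy > 0 else float("inf")
    return res_counts, res_coefs, float(ratio)
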