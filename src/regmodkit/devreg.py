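"""Calling developmentally regulated features.

Normalization is quantile normalization across samples.  Each feature's
temporal profile is then mean-centered and regressed on a natural cubic
spline of day with 3 degrees of freedom (boundary knots at the first and
last day, internal knots at the day tertiles).  Significance comes from a
likelihood-ratio test of the full model against an intercept-only null,
referred to chi-square with 3 df, followed by Benjamini-Hochberg FDR
control and abundance / fold-change filters:

* adjusted p < 1e-5,
* log2 range of daily means >= 1 (pseudocount 0.5 on both extremes),
* maximum daily mean >= 30 (DHS density) or >= 2 (gene FPKM).

Two fitting modes are provided.  ``ols`` is exact least squares with
LRT statistic ``n * log(RSS_reduced / RSS_full)``; it is the testable
reference.  ``robust`` uses iteratively reweighted least squares with the
Tukey bisquare psi (tuning constant 4.685) and an analogous robustified
deviance difference, for resilience to outlying replicates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import TimeCourseMatrix

__all__ = [
    "DevelopmentalFit",
    "quantile_normalize",
    "natural_spline_basis",
    "fit_developmental_model",
    "fit_matrix",
    "call_regulated",
]

BISQUARE_C = 4.685
SPLINE_DF = 3


@dataclass
class DevelopmentalFit:
    feature_id: str
    fitted_daily: np.ndarray  # fitted value at each unique day, original scale
    lrt_stat: float
    p_raw: float
    p_adj: float = float("nan")
    log2_range: float = float("nan")
    max_daily_mean: float = float("nan")
    regulated: bool = False
    direction: str = "other"


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to their common mean reference distribution.

    Each column's sorted values are replaced by the across-column mean of
    the sorted values at the same rank; tied values within a column receive
    the mean of the reference slots they occupy.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("quantile normalization requires non-negative values")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference slots within tie groups
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# spline basis and fits
# ---------------------------------------------------------------------------

def natural_spline_basis(days: np.ndarray, df: int = SPLINE_DF) -> np.ndarray:
    """Natural cubic spline basis of day with ``df`` degrees of freedom.

    Knots follow the usual df-based placement: boundary knots at the day
    range extremes, internal knots at evenly spaced quantiles of the sample
    days (the tertiles for df=3).  Uses the truncated-power natural basis;
    the intercept column is not included.
    """
    x = np.asarray(days, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_internal = df - 1
    qs = np.linspace(0, 1, n_internal + 2)
    knots = np.quantile(x, qs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate knot placement; need more distinct days")
    xi = knots
    K = len(xi)

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def _ols_lrt(y: np.ndarray, X_full: np.ndarray) -> tuple[float, float, np.ndarray]:
    """LRT of full spline model vs intercept-only by exact least squares."""
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    rss1 = float(resid @ resid)
    if rss0 <= 0:
        return 0.0, 1.0, beta
    if rss1 <= 0:
        return float("inf"), 0.0, beta
    lrt = n * np.log(rss0 / rss1)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, SPLINE_DF))
    return lrt, p, beta


def _bisquare_rho(u: np.ndarray, c: float = BISQUARE_C) -> np.ndarray:
    w = np.clip(1 - (u / c) ** 2, 0, None)
    return (c**2 / 6.0) * (1 - w**3)


def _robust_lrt(y: np.ndarray, X_full: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Robustified deviance difference between full and null IRLS fits.

    Both models are fit by Tukey-bisquare IRLS (statsmodels RLM); the
    statistic is 2 * (sum rho(r0/s) - sum rho(r1/s)) at the full-model
    scale s, referred to chi-square with 3 df.  Degenerate fits fall back
    to the exact least-squares LRT.
    """
    import statsmodels.api as sm

    norm = sm.robust.norms.TukeyBiweight(c=BISQUARE_C)
    try:
        m_full = sm.RLM(y, sm.add_constant(X_full), M=norm).fit()
        m_null = sm.RLM(y, np.ones((len(y), 1)), M=norm).fit()
        s = float(m_full.scale)
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError("degenerate robust scale")
        r1 = y - m_full.fittedvalues
        r0 = y - m_null.fittedvalues
        lrt = 2.0 * float(_bisquare_rho(r0 / s).sum() - _bisquare_rho(r1 / s).sum())
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, SPLINE_DF))
        return lrt, p, np.asarray(m_full.params)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError, FloatingPointError):
        X1 = np.column_stack([np.ones(len(y)), X_full])
        lrt, p, beta = _ols_lrt(y, X1)
        return lrt, p, beta


def fit_developmental_model(
    profile: np.ndarray,
    days: np.ndarray,
    mode: str = "ols",
    feature_id: str = "",
) -> DevelopmentalFit:
    """Fit one feature's temporal profile and test for developmental change.

    ``profile`` holds per-sample values, ``days`` the day of each sample.
    Requires >= 8 samples over >= 4 distinct days so the 3-df spline plus
    intercept is identifiable.
    """
    y = np.asarray(profile, dtype=float)
    days = np.asarray(days)
    if len(y) != len(days):
        raise ValueError("profile and days differ in length")
    uniq = np.unique(days)
    if len(uniq) < 4:
        raise ValueError(f"need >= 4 distinct days, got {len(uniq)}")
    if len(y) < 8:
        raise ValueError(f"need >= 8 samples, got {len(y)}")
    if mode not in {"ols", "robust"}:
        raise ValueError(f"unknown mode {mode!r}")
    mean = y.mean()
    yc = y - mean
    if np.allclose(yc, 0.0):
        return DevelopmentalFit(feature_id, np.full(len(uniq), mean), 0.0, 1.0)
    basis = natural_spline_basis(days)
    basis_days = natural_spline_basis_at(uniq, days)
    if mode == "ols":
        X1 = np.column_stack([np.ones(len(y)), basis])
        lrt, p, beta = _ols_lrt(yc, X1)
        fitted = np.column_stack([np.ones(len(uniq)), basis_days]) @ beta + mean
    else:
        lrt, p, beta = _robust_lrt(yc, basis)
        if beta is None or len(beta) != basis.shape[1] + 1:
            X1 = np.column_stack([np.ones(len(y)), basis])
            _, _, beta = _ols_lrt(yc, X1)
        fitted = np.column_stack([np.ones(len(uniq)), basis_days]) @ np.asarray(beta) + mean
    return DevelopmentalFit(feature_id, fitted, float(lrt), float(p))


def natural_spline_basis_at(
    eval_days: np.ndarray, fit_days: np.ndarray, df: int = SPLINE_DF
) -> np.ndarray:
    """Evaluate the basis (knots from ``fit_days``) at ``eval_days``."""
    x = np.asarray(eval_days, dtype=float)
    ref = np.asarray(fit_days, dtype=float)
    n_internal = df - 1
    knots = np.quantile(ref, np.linspace(0, 1, n_internal + 2))
    xi = knots
    K = len(xi)

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def fit_matrix(tcm: TimeCourseMatrix, mode: str = "ols") -> pd.DataFrame:
    """Fit every feature of a time-course matrix; vectorized in ols mode.

    Returns a DataFrame with one row per feature: lrt_stat, p_raw, p_adj
    (NaN until :func:`call_regulated`), log2_range and max_daily_mean of
    the raw daily means (pseudocount 0.5), and fitted_day_<d> columns.
    """
    days = tcm.days
    uniq = tcm.unique_days
    Y = tcm.values.to_numpy(dtype=float)
    n = Y.shape[1]
    day_means = tcm.day_means().to_numpy()
    max_daily = day_means.max(axis=1)
    min_daily = day_means.min(axis=1)
    log2_range = np.log2((max_daily + 0.5) / (min_daily + 0.5))

    basis = natural_spline_basis(days)
    X1 = np.column_stack([np.ones(n), basis])
    if mode == "ols":
        means = Y.mean(axis=1, keepdims=True)
        Yc = Y - means
        pinv = np.linalg.pinv(X1)
        B = pinv @ Yc.T  # (p, features)
        resid = Yc.T - X1 @ B
        rss1 = np.einsum("ij,ij->j", resid, resid)
        rss0 = np.einsum("ij,ij->j", Yc.T, Yc.T)
        with np.errstate(divide="ignore", invalid="ignore"):
            lrt = n * np.log(rss0 / rss1)
        lrt = np.where(rss0 <= 1e-300, 0.0, lrt)
        lrt = np.where((rss1 <= 1e-300) & (rss0 > 1e-300), np.inf, lrt)
        lrt = np.clip(lrt, 0.0, None)
        p = stats.chi2.sf(lrt, SPLINE_DF)
        p = np.where(lrt == 0.0, 1.0, p)
        basis_days = natural_spline_basis_at(uniq, days)
        fitted = (np.column_stack([np.ones(len(uniq)), basis_days]) @ B).T + means
    else:
        lrt = np.empty(Y.shape[0])
        p = np.empty(Y.shape[0])
        fitted = np.empty((Y.shape[0], len(uniq)))
        for i, fid in enumerate(tcm.feature_ids):
            fit = fit_developmental_model(Y[i], days, mode=mode, feature_id=fid)
            lrt[i], p[i], fitted[i] = fit.lrt_stat, fit.p_raw, fit.fitted_daily
    out = pd.DataFrame(
        {
            "feature_id": tcm.feature_ids,
            "lrt_stat": lrt,
            "p_raw": p,
            "p_adj": np.nan,
            "log2_range": log2_range,
            "max_daily_mean": max_daily,
            "regulated": False,
            "direction": "other",
        }
    )
    for j, d in enumerate(uniq):
        out[f"fitted_day_{int(d)}"] = fitted[:, j]
    return out


# ---------------------------------------------------------------------------
# regulated calls
# ---------------------------------------------------------------------------

def call_regulated(
    fits: pd.DataFrame,
    feature_kind: str,
    p_adj_max: float = 1e-5,
    min_log2_range: float = 1.0,
    min_max_density: float = 30.0,
    min_max_fpkm: float = 2.0,
) -> pd.DataFrame:
    """BH-adjust p-values and set regulated/direction flags.

    A DHS is regulated iff adjusted p < ``p_adj_max``, log2 daily-mean range
    >= ``min_log2_range`` and max daily mean >= ``min_max_density``; genes
    use ``min_max_fpkm`` for the abundance filter.  Direction compares the
    mean fitted value over the last two days against the first two days;
    differences under 5% of the fitted range are called "other".
    """
    if feature_kind not in {"dhs", "gene"}:
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    out = fits.copy()
    p_raw = out["p_raw"].to_numpy()
    out["p_adj"] = multipletests(p_raw, method="fdr_bh")[1]
    min_abund = min_max_density if feature_kind == "dhs" else min_max_fpkm
    out["regulated"] = (
        (out["p_adj"] < p_adj_max)
        & (out["log2_range"] >= min_log2_range)
        & (out["max_daily_mean"] >= min_abund)
    )
    fitted_cols = [c for c in out.columns if c.startswith("fitted_day_")]
    fitted = out[fitted_cols].to_numpy()
    if fitted.shape[1] >= 2:
        delta = fitted[:, -2:].mean(axis=1) - fitted[:, :2].mean(axis=1)
        rng_ = fitted.max(axis=1) - fitted.min(axis=1)
        direction = np.where(delta > 0, "activated", "silenced")
        direction = np.where(np.abs(delta) < 0.05 * np.where(rng_ > 0, rng_, np.inf),
                             "other", direction)
        out["direction"] = direction
    return out
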