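"""Independent oracles shared across test modules."""
from fractions import Fraction

import numpy as np

from regmodkit.devreg import natural_spline_basis


def hypergeom_tail_oracle(k, N, K, n):
    """P[X >= k] for Hypergeometric(N, K, n) by exact dynamic programming
    on the pmf recurrence in rational arithmetic."""

    def comb(a, b):
        out = Fraction(1)
        for i in range(b):
            out *= Fraction(a - i, i + 1)
        return out

    lo = max(0, n + K - N)
    hi = min(n, K)
    pmf = comb(K, lo) * comb(N - K, n - lo) / comb(N, n)
    total = Fraction(0)
    x = lo
    while True:
        if x >= k:
            total += pmf
        if x == hi:
            break
        pmf = pmf * Fraction((K - x) * (n - x), (x + 1) * (N - K - n + x + 1))
        x += 1
    return float(total)


def ols_lrt_oracle(y, days):
    """LRT statistic by explicit normal-equation least squares for the full
    (intercept + 3-df natural spline) vs intercept-only models."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), natural_spline_basis(days)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return len(y) * np.log(rss0 / rss1)
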