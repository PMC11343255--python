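"""Small vectorized statistical primitives shared across modules.

These are kept separate so hot loops (label-permutation nulls recompute
thousands of enrichment tables) can run on plain ndarrays without per-test
Python overhead.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored (returned as NaN) and do not count toward the
    number of tests in their family.  Vectorized along ``axis``.
    """
    p = np.asarray(p, dtype=float)
    q = np.moveaxis(p.copy(), axis, -1)
    shape = q.shape
    flat = q.reshape(-1, shape[-1])
    for row in flat:
        ok = ~np.isnan(row)
        m = int(ok.sum())
        if m == 0:
            continue
        vals = row[ok]
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        row[ok] = adj
    return np.moveaxis(flat.reshape(shape), -1, axis)


def binom_tails(k: np.ndarray, n: np.ndarray, p0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-sided binomial tail probabilities.

    Returns (upper, lower) where upper = P(X >= k) and lower = P(X <= k)
    for X ~ Binomial(n, p0).  All arguments broadcast.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    upper = stats.binom.sf(k - 1, n, p0)
    lower = stats.binom.cdf(k, n, p0)
    return np.clip(upper, 0.0, 1.0), np.clip(lower, 0.0, 1.0)


def t_test_from_stats(
    m1: np.ndarray,
    v1: np.ndarray,
    n1: np.ndarray,
    m2: np.ndarray,
    v2: np.ndarray,
    n2: np.ndarray,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t statistic and degrees of freedom from summary stats.

    ``v1``/``v2`` are unbiased (ddof=1) sample variances.  With
    ``equal_var`` the classic pooled-variance statistic is used, otherwise
    Welch's statistic with Satterthwaite df.  Degenerate cells (n < 2 on
    either side, or zero variance on both sides) yield NaN.
    """
    m1, v1, n1 = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (m1, v1, n1)))
    m2, v2, n2 = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (m2, v2, n2)))
    m1, m2, v1, v2, n1, n2 = np.broadcast_arrays(m1, m2, v1, v2, n1, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            a, b = v1 / n1, v2 / n2
            se = np.sqrt(a + b)
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        t = (m1 - m2) / se
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    return t, df


def t_tail_p(t: np.ndarray, df: np.ndarray, alternative: str) -> np.ndarray:
    """One- or two-sided p-value for a t statistic (NaN-safe)."""
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    with np.errstate(invalid="ignore"):
        if alternative == "greater":
            p = stats.t.sf(t, df)
        elif alternative == "less":
            p = stats.t.cdf(t, df)
        elif alternative == "two-sided":
            p = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return np.where(np.isnan(t), np.nan, np.clip(p, 0.0, 1.0))


def group_mean_var(x: np.ndarray, onehot: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group mean and ddof=1 variance of columns of ``x``.

    ``onehot`` is (n, G); returns (means (G, F), vars (G, F), counts (G,)).
    """
    counts = onehot.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sums = onehot.T @ x
        means = sums / counts[:, None]
        sq = onehot.T @ (x * x)
        var = (sq - counts[:, None] * means**2) / (counts[:, None] - 1)
    var = np.where(counts[:, None] >= 2, np.maximum(var, 0.0), np.nan)
    return means, var, counts


def normal_ci(mean: np.ndarray, sd: np.ndarray, n: np.ndarray, level: float = 0.95):
    """Normal-approximation confidence interval for a mean."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / np.sqrt(n)
    return mean - half, mean + half
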