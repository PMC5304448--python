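"""Shared statistical utilities: empirical p-values, BH adjustment, hypergeometric tails."""

from __future__ import annotations

import numpy as np
from scipy import stats as _scipy_stats

__all__ = ["bh_adjust", "empirical_pvalue", "hypergeometric_pvalue"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Implements q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def empirical_pvalue(null: np.ndarray, observed: float) -> float:
    """One-sided empirical p with the +1/(n+1) correction (never returns 0)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return (1.0 + np.count_nonzero(null >= observed)) / (null.size + 1.0)


def hypergeometric_pvalue(x: int, K: int, N: int, n: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= x <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric parameters: x={x}, K={K}, N={N}, n={n}"
        )
    return float(_scipy_stats.hypergeom.sf(x - 1, N, K, n))
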