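"""Shared numerical helpers: row-wise correlations and rank utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats


def rowwise_nan_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with the matching row of ``b``,
    using only columns where both entries are finite (pairwise complete).

    Rows with fewer than 3 complete pairs, or zero variance in either
    variable, yield NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mask = np.isfinite(a) & np.isfinite(b)
    n = mask.sum(axis=1)
    az = np.where(mask, a, 0.0)
    bz = np.where(mask, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = az.sum(axis=1)
        sb = bz.sum(axis=1)
        cov = (az * bz).sum(axis=1) - sa * sb / n
        va = (az * az).sum(axis=1) - sa * sa / n
        vb = (bz * bz).sum(axis=1) - sb * sb / n
        denom = np.sqrt(va * vb)
        r = cov / denom
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    # numerical safety: clamp tiny overshoots
    return np.clip(r, -1.0, 1.0, out=r)


def rowwise_nan_rank(x: np.ndarray) -> np.ndarray:
    """Midrank-transform each row, ignoring NaNs (NaNs stay NaN)."""
    return stats.rankdata(x, axis=1, nan_policy="omit")


def spearman_t_pvalue(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value for a Spearman coefficient via the t approximation.

    ``t = rho * sqrt((n-2)/(1-rho^2))`` on ``n-2`` degrees of freedom; at
    |rho| = 1 the p-value is 0 by convention.
    """
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho) & (n > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[ok] * np.sqrt((n[ok] - 2) / (1.0 - rho[ok] ** 2))
    p_ok = 2.0 * stats.t.sf(np.abs(t), n[ok] - 2)
    p_ok[np.abs(rho[ok]) >= 1.0] = 0.0
    p[ok] = np.clip(p_ok, 0.0, 1.0)
    return p


def blom_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) scores: Phi^-1((r - 3/8)/(n + 1/4)).

    Ties share midranks; a fully tied vector maps to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(values)) < 3:
        raise ValueError("need at least 3 non-missing values")
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    r = stats.rankdata(values[ok])
    n = ok.sum()
    out[ok] = stats.norm.ppf((r - 0.375) / (n + 0.25))
    return out
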