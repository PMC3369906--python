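"""Per-disease differential expression via the Rank Product statistic.

For an unpaired case/control study the Rank Product forms every case-vs-
control sample pair, ranks the genes by their expression difference within
each pairwise comparison, and summarizes each gene by the geometric mean of
its ranks across comparisons.  A gene consistently near the top of every
comparison gets a rank product near 1; significance comes from permuting the
within-comparison ranks.  Two one-sided runs (up- and down-regulation) are
combined and genes passing a q-value cutoff in either direction are retained,
with a signed log2 fold change carrying the direction into the downstream
correlation screen.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .errors import ConfigError, DataError

#: genes pass the differential-expression filter at q <= this value
DEFAULT_Q_THRESHOLD = 0.05


@dataclass
class ExpressionStudy:
    """One disease's case/control expression matrices (log2-scale intensities).

    Both matrices are genes x samples DataFrames sharing the same gene index.
    """

    disease_id: str
    case: pd.DataFrame
    control: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.case.index.equals(self.control.index):
            raise DataError(f"{self.disease_id}: case/control gene ids differ")
        if self.case.shape[1] < 1 or self.control.shape[1] < 1:
            raise DataError(f"{self.disease_id}: need >=1 case and >=1 control sample")
        self.case.index.name = "gene_id"
        self.control.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return self.case.index.tolist()


def fold_change(study: ExpressionStudy) -> pd.Series:
    """Signed log2 fold change per gene: mean(case) - mean(control).

    Inputs are assumed already on log2 scale, so the difference of means is
    the log ratio.  A gene whose row is entirely missing on either side gets
    a missing fold change.
    """
    return study.case.mean(axis=1) - study.control.mean(axis=1)


def rank_product(
    study: ExpressionStudy,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Rank Product statistics and permutation p-values for one study.

    Comparisons are all case x control sample pairs (the unpaired-design
    convention).  Within each comparison genes are ranked by the case-minus-
    control difference, descending for the up-regulation run and ascending
    for the down-regulation run; ``rp_up``/``rp_down`` are geometric means of
    those ranks.  p-values come from random within-comparison rank
    permutations: for gene g, ``p = (1 + #{b : RP_b(g) <= RP_obs(g)}) /
    (n_perm + 1)``.  With ``exhaustive=True`` all ``(G!)^K`` rank assignments
    are enumerated and the p-value is the exact fraction (no smoothing);
    only feasible for tiny G and K.
    """
    diffs = _comparison_diffs(study)
    g, k = diffs.shape
    ranks_up = stats.rankdata(-diffs, axis=0)
    ranks_down = stats.rankdata(diffs, axis=0)
    rp_up = _geom_mean_rows(ranks_up)
    rp_down = _geom_mean_rows(ranks_down)

    if exhaustive:
        p_up = _exhaustive_p(rp_up, g, k)
        p_down = _exhaustive_p(rp_down, g, k)
    else:
        if n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count_up = np.zeros(g)
        count_down = np.zeros(g)
        log_obs_up = np.log(rp_up)
        log_obs_down = np.log(rp_down)
        base = np.arange(1, g + 1, dtype=float)
        for _ in range(n_perm):
            null_log = np.zeros(g)
            for _ in range(k):
                null_log += np.log(rng.permutation(base))
            null_log /= k
            # null distribution of log RP is the same for both directions
            count_up += null_log <= log_obs_up + 1e-12
            count_down += null_log <= log_obs_down + 1e-12
        p_up = (count_up + 1.0) / (n_perm + 1.0)
        p_down = (count_down + 1.0) / (n_perm + 1.0)

    return pd.DataFrame(
        {"rp_up": rp_up, "rp_down": rp_down, "p_up": p_up, "p_down": p_down},
        index=study.case.index,
    )


def _comparison_diffs(study: ExpressionStudy) -> np.ndarray:
    case = study.case.to_numpy(dtype=float)
    control = study.control.to_numpy(dtype=float)
    # genes x (n_case * n_control) matrix of pairwise differences
    diffs = case[:, :, None] - control[:, None, :]
    diffs = diffs.reshape(case.shape[0], -1)
    if diffs.shape[1] < 1:
        raise DataError("no case/control comparisons derivable")
    if np.isnan(diffs).any():
        raise DataError("missing intensities; drop unmeasured genes before ranking")
    return diffs


def _geom_mean_rows(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=1))


def _exhaustive_p(rp_obs: np.ndarray, g: int, k: int) -> np.ndarray:
    """Exact permutation p-values by enumerating all (g!)^k rank matrices."""
    n_total = math.factorial(g) ** k
    if n_total > 2_000_000:
        raise ConfigError(f"exhaustive enumeration infeasible: (G!)^K = {n_total}")
    log_obs = np.log(rp_obs)
    counts = np.zeros(g)
    perms = list(itertools.permutations(range(1, g + 1)))
    for assignment in itertools.product(perms, repeat=k):
        null_log = np.log(np.array(assignment, dtype=float)).mean(axis=0)
        counts += null_log <= log_obs + 1e-12
    return counts / n_total


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values (gene-specific false-discovery rates).

    pi0 (the null proportion) is estimated on the 0.05..0.95 lambda grid with
    a cubic-smoother extrapolation at the largest lambda, clipped to (0, 1];
    pass ``pi0`` explicitly to override (pi0=1 reduces to Benjamini-Hochberg).
    q-values are made monotone nondecreasing in p by the usual step-up
    enforcement.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ConfigError(f"pi0 must be in (0, 1], got {pi0}")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up: monotone in p
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the proportion of null hypotheses."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    p = np.asarray(p, dtype=float)
    n = p.size
    if n < 20:
        # too few p-values to estimate the plateau; be conservative
        return 1.0
    pi0_lambda = np.array([(p > lam).sum() / (n * (1 - lam)) for lam in lambdas])
    try:
        spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float(pi0_lambda[-1])
    return float(min(max(pi0, 1.0 / n), 1.0))


def differential_expression(
    study: ExpressionStudy,
    n_perm: int = 1000,
    seed: int | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Full per-disease DE call: fold changes, RP p-values, q-values, retention.

    A gene is retained when the smaller of its up/down q-values is <=
    ``q_threshold`` (default 0.05).  The signed fold change carries direction.
    """
    rp = rank_product(study, n_perm=n_perm, seed=seed)
    fc = fold_change(study)
    q_up = qvalues(rp["p_up"].to_numpy())
    q_down = qvalues(rp["p_down"].to_numpy())
    q = np.minimum(q_up, q_down)
    out = rp.copy()
    out.insert(0, "fold_change", fc)
    out["q"] = q
    out["retained"] = q <= q_threshold
    out.index.name = "gene_id"
    return out
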