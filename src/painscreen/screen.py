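"""Gene x disease correlation screen against the phenotype index.

The screen assembles a matrix of signed fold changes with diseases as
columns (ordered by the phenotype index) and genes as rows, drops genes
measured in fewer than a minimum fraction of diseases, computes each gene's
Spearman correlation with the index midranks on its pairwise-complete
diseases, and attaches a permutation-based positive false discovery rate:
the disease ranks are shuffled, every gene's correlation is recomputed on
its own missingness pattern, and for each gene pFDR = E[V]/R where V counts
null correlations at least as extreme as the gene's observed |rho| and R
counts observed genes at least that extreme.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._stats import rowwise_nan_pearson, rowwise_nan_rank, spearman_t_pvalue
from .dspi import PhenotypeIndex
from .errors import ConfigError, DataError, EmptyResultError

DEFAULT_MIN_FRACTION = 0.10
DEFAULT_PFDR_ALPHA = 0.01


def representation_floor(n_diseases: int, min_fraction: float) -> int:
    """Minimum number of observed diseases for a gene to be retained.

    'Present in at least `min_fraction` of the diseases' is a floor on
    inclusion, so the count threshold is ceil(min_fraction * n_diseases).
    """
    return math.ceil(min_fraction * n_diseases)


def assemble_matrix(
    de_tables: Mapping[str, pd.DataFrame],
    index: PhenotypeIndex,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Fold-change matrix (genes x index-ordered diseases) from per-disease DE tables.

    ``de_tables`` maps disease_id to a table indexed by gene_id with at least
    a ``fold_change`` column (and, if present and ``retained_only``, a
    ``retained`` flag restricting to DE-significant genes).  Diseases absent
    from the index are ignored.  Genes observed in fewer than
    ``ceil(min_fraction * n_diseases)`` diseases are dropped.  Missing
    entries stay NaN.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    diseases = [d for d in index.disease_ids if d in de_tables]
    if not diseases:
        raise EmptyResultError("no DE table matches an index disease")
    columns = {}
    for d in diseases:
        t = de_tables[d]
        if "fold_change" not in t.columns:
            raise DataError(f"{d}: DE table lacks a fold_change column")
        fc = t["fold_change"]
        if retained_only and "retained" in t.columns:
            fc = fc[t["retained"].astype(bool)]
        columns[d] = fc
    matrix = pd.DataFrame(columns)[diseases]
    floor = representation_floor(len(diseases), min_fraction)
    matrix = matrix[matrix.notna().sum(axis=1) >= floor]
    if matrix.empty:
        raise EmptyResultError("no gene passes the representation filter")
    matrix.index.name = "gene_id"
    return matrix


def _aligned_midranks(matrix: pd.DataFrame, index: PhenotypeIndex) -> np.ndarray:
    mid = index.midranks
    missing = [c for c in matrix.columns if c not in mid.index]
    if missing:
        raise DataError(f"matrix columns not in index: {missing}")
    return mid.loc[list(matrix.columns)].to_numpy(dtype=float)


def gene_index_correlation(
    matrix: pd.DataFrame, index: PhenotypeIndex
) -> pd.DataFrame:
    """Per-gene Spearman correlation of fold changes with the index midranks.

    Pairwise-complete per gene; ties get midranks (the tie-corrected
    convention); the p-value uses the t approximation.  Genes with fewer
    than 3 observed diseases, or constant values, get NaN rho and are
    excluded downstream.
    """
    mids = _aligned_midranks(matrix, index)
    vals = matrix.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    xr = rowwise_nan_rank(vals)
    yr = rowwise_nan_rank(np.where(obs, mids[None, :], np.nan))
    rho = rowwise_nan_pearson(xr, yr)
    n_obs = obs.sum(axis=1)
    return pd.DataFrame(
        {"rho": rho, "n_obs": n_obs, "p_raw": spearman_t_pvalue(rho, n_obs)},
        index=matrix.index,
    )


def permutation_pfdr(
    matrix: pd.DataFrame,
    index: PhenotypeIndex,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.Series:
    """Permutation pFDR per gene from a disease-rank shuffle null.

    Each permutation shuffles the disease midranks once and recomputes every
    gene's Spearman correlation on its own missingness pattern.  For a gene
    with observed |rho| = t:

        R    = number of genes with observed |rho| >= t,
        E[V] = mean over permutations of the number of genes with null
               |rho| >= t,
        pFDR = E[V] / R, clipped to <= 1 and made monotone nonincreasing
               in |rho|.

    ``exhaustive=True`` enumerates all D! disease permutations (D <= 8 only)
    and is the n_perm -> infinity limit used as an oracle in testing.
    """
    if matrix.empty:
        raise EmptyResultError("empty fold-change matrix")
    mids = _aligned_midranks(matrix, index)
    vals = matrix.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    xr = rowwise_nan_rank(vals)

    def null_abs_rho(perm: np.ndarray) -> np.ndarray:
        permuted = np.where(obs, mids[perm][None, :], np.nan)
        return np.abs(rowwise_nan_pearson(xr, rowwise_nan_rank(permuted)))

    obs_abs = np.abs(rowwise_nan_pearson(xr, rowwise_nan_rank(np.where(obs, mids[None, :], np.nan))))
    scored = np.isfinite(obs_abs)
    if not scored.any():
        raise EmptyResultError("no gene has a defined correlation")
    d = len(matrix.columns)

    if exhaustive:
        if d > 8:
            raise ConfigError("exhaustive pFDR limited to <= 8 diseases")
        perms: Iterable[np.ndarray] = (
            np.array(p) for p in itertools.permutations(range(d))
        )
        n_used = math.factorial(d)
    else:
        if n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(d) for _ in range(n_perm))
        n_used = n_perm

    thresholds = obs_abs[scored]
    ev = np.zeros(thresholds.shape)
    for perm in perms:
        null_abs = null_abs_rho(perm)
        null_sorted = np.sort(null_abs[np.isfinite(null_abs)])
        # count of null |rho| >= each gene's threshold
        ev += null_sorted.size - np.searchsorted(
            null_sorted, thresholds - 1e-12, side="left"
        )
    ev /= n_used
    obs_sorted = np.sort(thresholds)
    r = thresholds.size - np.searchsorted(obs_sorted, thresholds - 1e-12, side="left")
    pfdr = np.minimum(ev / r, 1.0)

    # monotone in |rho|: a stronger correlation never gets a larger pFDR
    order = np.argsort(-thresholds, kind="mergesort")
    pfdr[order] = np.maximum.accumulate(pfdr[order])

    out = np.full(len(matrix), np.nan)
    out[scored] = pfdr
    return pd.Series(out, index=matrix.index, name="pfdr")


def score_genes(
    matrix: pd.DataFrame,
    index: PhenotypeIndex,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = DEFAULT_PFDR_ALPHA,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Correlations plus pFDR and the significance flag in one table."""
    scores = gene_index_correlation(matrix, index)
    scores["pfdr"] = permutation_pfdr(
        matrix, index, n_perm=n_perm, seed=seed, exhaustive=exhaustive
    )
    scores["significant"] = scores["pfdr"] < alpha
    return scores


def select_candidates(scores: pd.DataFrame, alpha: float = DEFAULT_PFDR_ALPHA) -> pd.DataFrame:
    """Significant genes (pFDR < alpha) with a direction label.

    Positively correlated genes come first, then negatively correlated ones,
    each block ordered by |rho| descending.
    """
    if scores.empty:
        raise DataError("empty score table")
    hits = scores[scores["pfdr"] < alpha].copy()
    hits["direction"] = np.where(hits["rho"] >= 0, "positive", "negative")
    hits["_absrho"] = hits["rho"].abs()
    hits = hits.sort_values(
        ["direction", "_absrho"], ascending=[False, False], kind="mergesort"
    ).drop(columns="_absrho")
    return hits
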