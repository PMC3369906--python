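"""ROC validation of a gene prioritization against a gold-standard gene set.

A candidate ranking is useful if known phenotype genes concentrate near its
top.  We score that with a ROC curve over the evaluable genes (gold genes
actually present among the scored genes versus the rest), summarized by the
AUC in its Mann-Whitney concordance-probability form, and attach resampling
confidence bands obtained by repeatedly rerunning the screen on random
subsets of the diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import ConfigError, DataError, EmptyResultError


@dataclass(frozen=True)
class GoldStandard:
    """A set of known phenotype genes (human symbols, uppercase-normalized)."""

    gene_ids: frozenset[str]
    label: str = "gold"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise DataError("empty gold-standard gene set")
        object.__setattr__(
            self, "gene_ids", frozenset(g.upper() for g in self.gene_ids)
        )

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], label: str = "gold") -> "GoldStandard":
        return cls(frozenset(s.strip() for s in symbols if s.strip()), label)


@dataclass
class RocResult:
    """ROC curve, AUC, optimal cutoff, and optional resampling bands."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    best_cutoff: tuple[float, float]  # (sensitivity, specificity) at max Youden J
    n_gold: int
    n_background: int
    band: pd.DataFrame | None = None
    auc_replicates: np.ndarray | None = None


def priority_scores(scores: pd.DataFrame) -> pd.Series:
    """Scalar priority per gene: pFDR ascending, |rho| descending as tie-break.

    Returned values are 'larger is better' so they can feed the ROC directly.
    """
    if scores.empty:
        raise DataError("empty score table")
    key = scores.assign(_a=scores["pfdr"], _b=-scores["rho"].abs())
    order = key.sort_values(["_a", "_b"], kind="mergesort").index
    ranks = pd.Series(np.arange(len(order), 0, -1, dtype=float), index=order)
    return ranks.reindex(scores.index).rename("priority")


def evaluable_subset(
    scores: pd.Series | pd.DataFrame, gold: GoldStandard
) -> tuple[int, int]:
    """(gold genes present among scored genes, background genes) — the ROC's
    actual evaluable set, logged for transparency since a gold list is rarely
    fully measurable."""
    genes = {str(g).upper() for g in scores.index}
    n_gold = len(genes & gold.gene_ids)
    return n_gold, len(genes) - n_gold


def roc_auc(scores: pd.Series, gold: GoldStandard) -> RocResult:
    """ROC of a priority score (larger = higher priority) against the gold set.

    AUC is the tie-corrected Mann-Whitney concordance probability:
    P(random gold gene outranks random background gene), with ties counting
    half.  ``best_cutoff`` reports (sensitivity, specificity) at the point
    maximizing Youden's J.
    """
    scores = scores.dropna()
    labels = np.array([str(g).upper() in gold.gene_ids for g in scores.index])
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    if n1 == 0 or n0 == 0:
        raise EmptyResultError(
            f"gold set not evaluable: {n1} gold and {n0} background genes among scores"
        )
    values = scores.to_numpy(dtype=float)
    ranks = stats.rankdata(values)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thresholds = roc_curve(labels, values)
    j = tpr - fpr
    best = int(np.argmax(j))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(auc),
        best_cutoff=(float(tpr[best]), float(1 - fpr[best])),
        n_gold=n1,
        n_background=n0,
    )


def resampling_band(
    rerun: Callable[[Sequence[str]], pd.Series],
    diseases: Sequence[str],
    gold: GoldStandard,
    fraction: float = 0.9,
    n_replicates: int = 50,
    seed: int | None = None,
    grid_size: int = 101,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pointwise ROC confidence band from delete-d disease resampling.

    ``rerun`` maps a disease subset to a priority Series (the screen rerun on
    those diseases).  Each replicate keeps a random ``fraction`` of the
    diseases, recomputes priorities, and records the ROC interpolated on a
    common false-positive-rate grid.  The band reports the mean curve, its
    standard-error envelope, and the empirical 2.5/97.5% quantiles (both
    conventions are emitted); the replicate AUCs come back alongside.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    if n_replicates < 2:
        raise ConfigError("need at least 2 replicates for a band")
    rng = np.random.default_rng(seed)
    diseases = list(diseases)
    n_keep = max(1, round(fraction * len(diseases)))
    grid = np.linspace(0.0, 1.0, grid_size)
    curves, aucs = [], []
    for _ in range(n_replicates):
        keep = rng.choice(len(diseases), size=n_keep, replace=False)
        subset = [diseases[i] for i in sorted(keep)]
        try:
            priorities = rerun(subset)
            roc = roc_auc(priorities, gold)
        except (EmptyResultError, DataError):
            continue  # replicate produced nothing evaluable; skip and move on
        curves.append(np.interp(grid, roc.fpr, roc.tpr))
        aucs.append(roc.auc)
    if len(curves) < 2:
        raise EmptyResultError("too few successful resampling replicates")
    curves = np.vstack(curves)
    band = pd.DataFrame(
        {
            "fpr": grid,
            "tpr_mean": curves.mean(axis=0),
            "tpr_se": curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]),
            "tpr_lo": np.quantile(curves, 0.025, axis=0),
            "tpr_hi": np.quantile(curves, 0.975, axis=0),
        }
    )
    return band, np.asarray(aucs)
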