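"""Disease-specific phenotype index (DSPI / DSII) from literature co-citation counts.

For every disease MeSH term we have two citation counts: the total number of
publications annotated with the disease, and the number of those also
annotated with a phenotype heading such as "pain" (or "Inflammation" for the
DSII configuration).  Their ratio is the disease-phenotype ratio; ranking all
diseases by this ratio yields the index used as the ordering axis of the
gene-expression correlation screen.

Inclusion rule: a disease enters the index only if it has at least one
phenotype co-citation.  Diseases with zero total citations cannot be scored
at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, EmptyResultError

CITATION_COLUMNS = ["disease_id", "disease_name", "n_total", "n_phenotype"]


@dataclass(frozen=True)
class CitationRecord:
    """Per-disease citation totals and phenotype co-citation count."""

    disease_id: str
    disease_name: str
    n_total: int
    n_phenotype: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_phenotype < 0:
            raise DataError(f"{self.disease_id}: negative citation count")
        if self.n_phenotype > self.n_total:
            raise DataError(
                f"{self.disease_id}: phenotype co-citations ({self.n_phenotype}) "
                f"exceed total citations ({self.n_total})"
            )


@dataclass
class PhenotypeIndex:
    """Ordered diseases with disease-phenotype ratios and midranks.

    ``entries`` has columns (disease_id, ratio, midrank), sorted by ratio
    (ascending by default: lowest phenotype index first, as used by the
    downstream screen).  Tied ratios share the average (mid) rank, so
    midranks always sum to n(n+1)/2.
    """

    entries: pd.DataFrame
    ordering: str = "ascending"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.ordering not in ("ascending", "descending"):
            raise ConfigError(f"unknown ordering {self.ordering!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def disease_ids(self) -> list[str]:
        return self.entries["disease_id"].tolist()

    @property
    def midranks(self) -> pd.Series:
        """Midrank per disease, indexed by disease_id."""
        return self.entries.set_index("disease_id")["midrank"]

    def subset(self, disease_ids: Iterable[str]) -> "PhenotypeIndex":
        """Index restricted to ``disease_ids``, with midranks recomputed.

        Relative order of shared diseases is preserved, which is what the
        delete-d resampling of the ROC band relies on.
        """
        keep = set(disease_ids)
        sub = self.entries[self.entries["disease_id"].isin(keep)].copy()
        if sub.empty:
            raise EmptyResultError("subset leaves no diseases in the index")
        ranks = stats.rankdata(sub["ratio"].to_numpy())
        if self.ordering == "descending":
            ranks = len(ranks) + 1 - ranks
        sub["midrank"] = ranks
        return PhenotypeIndex(sub.reset_index(drop=True), ordering=self.ordering)


def disease_phenotype_ratio(n_phenotype: int, n_total: int) -> float:
    """Fraction of a disease's citations co-annotated with the phenotype term.

    Raises if the total is zero (ratio undefined) or the phenotype count
    exceeds the total.
    """
    if n_total < 1:
        raise DataError("ratio undefined: disease has no citations")
    if n_phenotype < 0 or n_phenotype > n_total:
        raise DataError(
            f"phenotype count {n_phenotype} outside [0, {n_total}]"
        )
    return n_phenotype / n_total


def build_index(
    records: pd.DataFrame | Sequence[CitationRecord],
    ordering: str = "ascending",
    exclude: Iterable[str] = (),
) -> PhenotypeIndex:
    """Build the phenotype index from citation records.

    Diseases with zero phenotype co-citations are dropped (the inclusion
    rule), as are any ids in ``exclude`` (e.g. a user-supplied blocklist of
    animal diseases).  Remaining diseases are ranked by ratio with midranks
    for ties.  Presentation order is deterministic: ratio, then n_total
    descending, then disease_id — a tie-break for reproducibility only, the
    midranks are what downstream analysis consumes.
    """
    df = _coerce_records(records)
    if df.empty:
        raise DataError("no citation records supplied")
    excluded = df["n_phenotype"] < 1
    blocked = df["disease_id"].isin(set(exclude))
    kept = df[~excluded & ~blocked].copy()
    if kept.empty:
        raise EmptyResultError("all diseases excluded from the index")
    if (kept["n_total"] < 1).any():
        raise DataError("disease with zero total citations cannot be ranked")

    kept["ratio"] = kept["n_phenotype"] / kept["n_total"]
    ranks = stats.rankdata(kept["ratio"].to_numpy())
    if ordering == "descending":
        ranks = len(ranks) + 1 - ranks
    kept["midrank"] = ranks
    kept = kept.sort_values(
        ["ratio", "n_total", "disease_id"],
        ascending=[ordering == "ascending", False, True],
        kind="mergesort",
    )
    entries = kept[["disease_id", "ratio", "midrank"]].reset_index(drop=True)
    return PhenotypeIndex(
        entries,
        ordering=ordering,
        n_excluded=int(excluded.sum() + (blocked & ~excluded).sum()),
    )


def _coerce_records(records: pd.DataFrame | Sequence[CitationRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in CITATION_COLUMNS if c not in records.columns]
        if missing:
            raise DataError(f"citation table missing columns: {missing}")
        df = records[CITATION_COLUMNS].copy()
        dup = df["disease_id"].duplicated(keep=False)
        if dup.any():
            where = df.index[dup].tolist()
            raise DataError(f"duplicate disease_id at rows {where}")
        if (df["n_phenotype"] > df["n_total"]).any() or (df[["n_total", "n_phenotype"]] < 0).any().any():
            raise DataError("citation counts violate 0 <= n_phenotype <= n_total")
        return df
    return pd.DataFrame(
        [(r.disease_id, r.disease_name, r.n_total, r.n_phenotype) for r in records],
        columns=CITATION_COLUMNS,
    )
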