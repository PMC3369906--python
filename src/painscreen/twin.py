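"""Candidate-SNP association testing in a twin cohort.

Instead of modelling the correlation between co-twins explicitly, each twin
pair is collapsed to a single observation by averaging genotypes and
(transformed) phenotypes within the pair; singletons pass through unchanged.
The averaged phenotype is regressed on the averaged allele dosage plus sex
and depression covariates by feasible generalized least squares with a
diagonal error covariance whose variance is constant within variance groups
(zygosity x sex composition) — monozygotic and dizygotic pairs, and males
and females, are allowed different residual variances.

Also here: the SNP QC filters (call rate, minor allele frequency,
Hardy-Weinberg equilibrium), homozygous-wildtype imputation of missing
genotypes, Bonferroni correction, Cohen's d, Welch's t-test, rank-based
inverse-normal phenotype transformation, composite LD r^2, and the
ceiling-value outlier rule for the cold pressor test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import blom_scores
from .errors import ConfigError, DataError, EmptyResultError

log = logging.getLogger(__name__)

PHENOTYPES = ("heat_c", "cold_thresh_s", "cold_tol_s")
INDIVIDUAL_COLUMNS = [
    "individual_id", "pair_id", "zygosity", "sex",
    "heat_c", "cold_thresh_s", "cold_tol_s", "depression",
]
#: cold pressor ceiling (seconds); values at the ceiling are censored, not real
COLD_CEILING_S = 180.0
#: default transform per phenotype: cold times are log-transformed
DEFAULT_TRANSFORMS = {"heat_c": "identity", "cold_thresh_s": "log", "cold_tol_s": "log"}

SEX_CODE = {"M": -1.0, "F": 1.0}


@dataclass
class TwinCohort:
    """Individual-level phenotypes and genotypes for a twin cohort.

    ``individuals``: one row per person with columns
    (individual_id, pair_id, zygosity in {MZ, DZ, NA}, sex in {M, F},
    heat_c, cold_thresh_s, cold_tol_s, depression).  Singletons have an
    empty/NA pair_id.  ``genotypes``: SNP x individual dosage matrix
    (0/1/2 of the non-wildtype allele, NaN for missing calls).
    """

    individuals: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INDIVIDUAL_COLUMNS if c not in self.individuals.columns]
        if missing:
            raise DataError(f"individual table missing columns: {missing}")
        ids = self.individuals["individual_id"]
        if ids.duplicated().any():
            raise DataError("duplicate individual_id in cohort")
        extra = [c for c in self.genotypes.columns if c not in set(ids)]
        if extra:
            raise DataError(f"genotype columns with no individual record: {extra}")
        sizes = self.individuals.dropna(subset=["pair_id"]).groupby("pair_id").size()
        if (sizes > 2).any():
            raise DataError("a pair_id groups more than 2 individuals")

    @property
    def snp_ids(self) -> list[str]:
        return self.genotypes.index.tolist()

    def one_per_mz_pair(self) -> list[str]:
        """Individual ids with one member per MZ pair (first by id), used for
        HWE and LD so duplicated MZ genomes are not double-counted."""
        ind = self.individuals
        drop: set[str] = set()
        mz = ind[ind["zygosity"] == "MZ"].dropna(subset=["pair_id"])
        for _, grp in mz.sort_values("individual_id").groupby("pair_id"):
            drop.update(grp["individual_id"].iloc[1:])
        return [i for i in ind["individual_id"] if i not in drop]


# ---------------------------------------------------------------------------
# genotype QC


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    expectations p^2, 2pq, q^2.  Monomorphic SNPs return p = 1 (no departure
    is testable)."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise DataError("no genotype calls")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    cohort: TwinCohort,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """Filter SNPs by call rate, minor allele frequency and HWE.

    Call rate and MAF use all individuals; the HWE test uses one member per
    MZ pair.  Returns the passing SNP ids and a per-SNP report with each
    metric and the removal reason (empty string if kept).
    """
    if cohort.genotypes.empty:
        raise DataError("empty genotype table")
    geno = cohort.genotypes
    dedup = geno[cohort.one_per_mz_pair()]
    rows = []
    for snp in geno.index:
        g = geno.loc[snp].to_numpy(dtype=float)
        call_rate = np.isfinite(g).mean()
        called = g[np.isfinite(g)]
        freq_alt = called.sum() / (2 * called.size) if called.size else np.nan
        maf = min(freq_alt, 1 - freq_alt) if np.isfinite(freq_alt) else np.nan
        gd = dedup.loc[snp].to_numpy(dtype=float)
        gd = gd[np.isfinite(gd)]
        counts = [(gd == k).sum() for k in (0, 1, 2)]
        hwe_p = hwe_test(*counts) if gd.size else np.nan
        reasons = []
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if not np.isfinite(maf) or maf < maf_min:
            reasons.append("maf")
        if np.isfinite(hwe_p) and hwe_p < hwe_alpha:
            reasons.append("hwe")
        rows.append((snp, call_rate, maf, hwe_p, ",".join(reasons)))
    report = pd.DataFrame(
        rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "removed_for"]
    ).set_index("snp_id")
    passing = report.index[report["removed_for"] == ""].tolist()
    if not passing:
        raise EmptyResultError("all SNPs removed by QC")
    return passing, report


def impute_missing(genotypes: pd.DataFrame, cohort: TwinCohort | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Set missing dosages to 0 (homozygous wildtype), the population-default
    imputation rule.  Returns the completed matrix and the per-SNP imputed
    count.  If a cohort is given, MZ pairs whose imputed member now disagrees
    with its observed co-twin are logged as inconsistencies (the rule is
    still applied verbatim)."""
    imputed = genotypes.isna().sum(axis=1)
    completed = genotypes.fillna(0.0)
    if cohort is not None:
        mz = cohort.individuals[
            (cohort.individuals["zygosity"] == "MZ")
            & cohort.individuals["pair_id"].notna()
        ]
        for pair_id, grp in mz.groupby("pair_id"):
            ids = [i for i in grp["individual_id"] if i in genotypes.columns]
            if len(ids) != 2:
                continue
            was_missing = genotypes[ids].isna()
            mismatch = (
                was_missing.any(axis=1)
                & ~was_missing.all(axis=1)
                & (completed[ids[0]] != completed[ids[1]])
            )
            for snp in genotypes.index[mismatch]:
                log.warning(
                    "MZ pair %s: imputed genotype at %s disagrees with observed co-twin",
                    pair_id, snp,
                )
    return completed, imputed


# ---------------------------------------------------------------------------
# phenotype handling


def censored_max_rule(values: pd.Series, max_allowed: float = COLD_CEILING_S) -> pd.Series:
    """Boolean flag of observations at the test ceiling (strict equality).

    A cold pressor measurement that hits the maximum allowed time is a
    censoring artifact, not a threshold, and is excluded from association.
    """
    if max_allowed <= 0:
        raise ConfigError("max_allowed must be positive")
    flagged = values == max_allowed
    if flagged.any():
        log.info("censored ceiling rule removed %d observation(s)", int(flagged.sum()))
    return flagged


def quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset."""
    return blom_scores(np.asarray(values, dtype=float))


def _transform(values: pd.Series, transform: str) -> pd.Series:
    if transform == "identity":
        return values.astype(float)
    if transform == "log":
        out = values.astype(float).copy()
        bad = out <= 0
        if bad.any():
            log.warning("log transform: %d non-positive value(s) dropped", int(bad.sum()))
            out[bad] = np.nan
        return np.log(out)
    if transform == "quantile-normal":
        out = values.astype(float).copy()
        ok = out.notna()
        out[ok] = blom_scores(out[ok].to_numpy())
        return out
    raise ConfigError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# pair-averaged encoding


def encode_units(
    cohort: TwinCohort,
    phenotype: str,
    transform: str = "identity",
    covariates: Sequence[str] = ("depression",),
    apply_ceiling_rule: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse individuals to pair-averaged analysis units.

    The phenotype is transformed at the individual level, the ceiling rule is
    applied to cold phenotypes, then phenotype, covariates and genotypes are
    averaged within each complete pair; singletons (and half-pairs after
    exclusions) pass through unchanged.  Sex is coded -1 for male and +1 for
    female and averaged, so mixed-sex DZ pairs are coded 0.  Each unit gets a
    variance-group label in {MZ-M, MZ-F, DZ-M, DZ-F, DZ-mixed, singleton-M,
    singleton-F}.

    Returns (units, g_bar): a unit-level design table with columns
    (unit_id, y_bar, sex_code, <covariate>_bar..., var_group, n_members) and
    the SNP x unit matrix of averaged dosages.
    """
    ind = cohort.individuals.copy()
    if phenotype not in ind.columns:
        raise DataError(f"unknown phenotype {phenotype!r}")
    y = _transform(ind[phenotype], transform)
    if apply_ceiling_rule and phenotype in ("cold_thresh_s", "cold_tol_s"):
        y[censored_max_rule(ind[phenotype].astype(float)).to_numpy()] = np.nan
    ind["_y"] = y
    ind["_sex"] = ind["sex"].map(SEX_CODE)
    if ind["_sex"].isna().any():
        raise DataError("sex must be 'M' or 'F' for every individual")
    keep = ind["_y"].notna()
    for cov in covariates:
        if cov not in ind.columns:
            raise DataError(f"unknown covariate {cov!r}")
        keep &= ind[cov].notna()
    ind = ind[keep]
    if ind.empty:
        raise EmptyResultError("no individual with complete phenotype/covariates")

    # a unit is a complete pair (both members kept) or a lone individual
    has_pair = ind["pair_id"].notna() & (ind["pair_id"] != "")
    pair_sizes = ind.loc[has_pair, "pair_id"].value_counts()
    full_pairs = set(pair_sizes.index[pair_sizes == 2])
    ind = ind.assign(
        _unit=np.where(
            has_pair & ind["pair_id"].isin(full_pairs),
            ind["pair_id"],
            ind["individual_id"],
        )
    )
    agg = ind.groupby("_unit").agg(
        y_bar=("_y", "mean"),
        sex_code=("_sex", "mean"),
        n_members=("_y", "size"),
        _zyg=("zygosity", "first"),
        _sex_first=("sex", "first"),
        _n_sex=("sex", "nunique"),
    )
    for cov in covariates:
        agg[f"{cov}_bar"] = ind.groupby("_unit")[cov].mean().astype(float)
    var_group = np.where(
        agg["n_members"] == 1,
        "singleton-" + agg["_sex_first"],
        np.where(
            agg["_zyg"] == "MZ",
            "MZ-" + agg["_sex_first"],
            np.where(agg["_n_sex"] == 2, "DZ-mixed", "DZ-" + agg["_sex_first"]),
        ),
    )
    agg["var_group"] = var_group
    units_df = agg.drop(columns=["_zyg", "_sex_first", "_n_sex"])
    units_df.index.name = "unit_id"

    kept_ids = ind["individual_id"].tolist()
    unit_of = dict(zip(ind["individual_id"], ind["_unit"]))
    geno = cohort.genotypes[[c for c in cohort.genotypes.columns if c in unit_of]]
    g_bar = geno.T.groupby(geno.columns.map(unit_of)).mean().T
    g_bar = g_bar[units_df.index]
    return units_df, g_bar


# ---------------------------------------------------------------------------
# feasible GLS


@dataclass
class AssociationResult:
    """Per-SNP GLS association summary."""

    snp_id: str
    phenotype: str
    beta: float
    se: float
    p_raw: float
    n_units: int
    group_variances: dict[str, float]
    p_bonf: float | None = None
    m_tests: int | None = None


def _merge_small_groups(groups: pd.Series, min_size: int = 2) -> pd.Series:
    """Merge variance groups with fewer than ``min_size`` units into their
    zygosity's pooled group; if the pooled group is still too small, pool
    everything."""
    groups = groups.copy()
    for _ in range(3):
        counts = groups.value_counts()
        small = counts[counts < min_size].index
        if small.empty:
            return groups
        for g in small:
            pooled = str(g).split("-")[0]
            target = pooled if pooled != g else "all"
            log.info("variance group %s has <%d units; merged into %s", g, min_size, target)
            groups[groups == g] = target
    return pd.Series("all", index=groups.index)


def gls_fit(
    y: np.ndarray,
    x: np.ndarray,
    groups: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float], int]:
    """Iterated feasible GLS with group-wise residual variances.

    Starts at OLS, estimates each group's residual variance from its
    residual sum of squares over the group's effective degrees of freedom
    (group size minus the leverage it absorbs — the REML-type denominator,
    with a small floor to keep weights finite), reweights, and iterates
    until the relative coefficient change is below ``tol``.

    Inference uses two small-sample corrections that matter at cohort
    scale, where each variance group holds only a few dozen pairs:

    * the covariance of the coefficients is built from precision-unbiased
      weights — each group's estimated precision 1/s_g^2 is deflated by
      (nu_g - 2)/nu_g, undoing the Jensen bias of inverting a chi-square
      variance estimate;
    * the Kackar-Harville term for the extra variability induced by
      estimating the weights is added to the covariance.

    Returns (beta, se, two-sided t p-values, group variances, n_iter).
    With a single variance group the coefficients are exactly OLS.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    groups = pd.Series(list(groups))
    labels = groups.unique()
    if n < p + len(labels):
        raise DataError("too few units for predictors plus variance groups")
    masks = {g: (groups == g).to_numpy() for g in labels}
    floor = max(np.var(y) * 1e-10, 1e-12)
    w = np.ones(n)
    beta_prev = None
    group_var: dict[str, float] = {}
    group_df: dict[str, float] = {}
    for it in range(1, max_iter + 1):
        xw = x * np.sqrt(w)[:, None]
        phi = np.linalg.inv(xw.T @ xw)
        beta = phi @ (xw.T @ (y * np.sqrt(w)))
        resid = y - x @ beta
        leverage = np.einsum("ij,jk,ik->i", xw, phi, xw)
        for g in labels:
            m = masks[g]
            nu = max(m.sum() - leverage[m].sum(), 1.0)
            group_df[g] = nu
            group_var[g] = max(float((resid[m] ** 2).sum() / nu), floor)
        w = 1.0 / groups.map(group_var).to_numpy()
        if beta_prev is not None and np.max(
            np.abs(beta - beta_prev) / (np.abs(beta_prev) + 1.0)
        ) < tol:
            break
        beta_prev = beta

    xw = x * np.sqrt(w)[:, None]
    phi = np.linalg.inv(xw.T @ xw)
    beta = phi @ (xw.T @ (y * np.sqrt(w)))
    # precision-unbiased covariance
    w_adj = np.array(
        [max(group_df[g] - 2.0, 1.0) / group_df[g] for g in groups]
    ) * w
    phi_adj = np.linalg.inv((x * w_adj[:, None]).T @ x)
    # Kackar-Harville allowance for estimated weights
    extra = np.zeros((p, p))
    xpx = x @ phi @ x.T
    for g in labels:
        m = masks[g]
        xg = x[m]
        s2 = group_var[g]
        b = xg.T @ xg / s2 - xg.T @ xpx[np.ix_(m, m)] @ xg / s2**2
        extra += (2.0 / group_df[g]) * phi @ b @ phi
    cov = phi_adj + extra
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    return beta, se, pvals, dict(group_var), it


def associate_snp(
    units: pd.DataFrame,
    g_bar: pd.Series,
    snp_id: str,
    phenotype: str,
    covariates: Sequence[str] = ("depression",),
) -> AssociationResult:
    """GLS association of one SNP's averaged dosage with the averaged phenotype.

    Model: y_bar = b0 + b_g * g_bar + b_sex * sex_code + b_cov * cov_bar + e,
    Var(e) constant within variance groups.  Variance groups with fewer than
    2 units are merged into their zygosity's pooled group first.
    """
    g = g_bar.reindex(units.index).to_numpy(dtype=float)
    ok = np.isfinite(g) & units["y_bar"].notna().to_numpy()
    u = units[ok]
    g = g[ok]
    if np.ptp(g) == 0:
        raise DataError(f"{snp_id}: constant genotype, degenerate design")
    cols = [np.ones(len(u)), g, u["sex_code"].to_numpy(dtype=float)]
    names = ["intercept", "g_bar", "sex_code"]
    for cov in covariates:
        cols.append(u[f"{cov}_bar"].to_numpy(dtype=float))
        names.append(f"{cov}_bar")
    # constant covariates (e.g. sex_code in a single-sex stratum) would be
    # collinear with the intercept; drop them
    keep = [0, 1] + [k for k in range(2, len(cols)) if np.ptp(cols[k]) > 0]
    x = np.column_stack([cols[k] for k in keep])
    groups = _merge_small_groups(u["var_group"])
    beta, se, pvals, group_var, _ = gls_fit(u["y_bar"].to_numpy(dtype=float), x, groups)
    return AssociationResult(
        snp_id=snp_id,
        phenotype=phenotype,
        beta=float(beta[1]),
        se=float(se[1]),
        p_raw=float(pvals[1]),
        n_units=len(u),
        group_variances=group_var,
    )


def bonferroni(p_raw: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p).  ``m`` defaults to the
    number of p-values (one test per QC-passing SNP for the phenotype)."""
    p = np.asarray(list(p_raw), dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ConfigError("m must be >= 1")
    return np.minimum(1.0, m * p)


def association_scan(
    cohort: TwinCohort,
    phenotype: str,
    transform: str | None = None,
    covariates: Sequence[str] = ("depression",),
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.01,
    bonferroni_m: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC, impute, encode and test every passing SNP against one phenotype.

    Returns (association table, QC report).  The association table has one
    row per tested SNP with beta, se, p_raw, p_bonf and n_units; Bonferroni
    uses the number of tested SNPs unless ``bonferroni_m`` overrides it.
    """
    if transform is None:
        transform = DEFAULT_TRANSFORMS.get(phenotype, "identity")
    passing, report = snp_qc(cohort, call_rate_min, maf_min, hwe_alpha)
    completed, _ = impute_missing(cohort.genotypes.loc[passing], cohort)
    working = TwinCohort(cohort.individuals, completed)
    units, g_bar_matrix = encode_units(working, phenotype, transform, covariates)
    results = []
    for snp in passing:
        try:
            res = associate_snp(units, g_bar_matrix.loc[snp], snp, phenotype, covariates)
        except DataError as exc:
            log.warning("skipping %s: %s", snp, exc)
            continue
        results.append(res)
    if not results:
        raise EmptyResultError("no SNP could be tested")
    table = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "phenotype": phenotype,
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p_raw": [r.p_raw for r in results],
            "n_units": [r.n_units for r in results],
        }
    ).set_index("snp_id")
    m = bonferroni_m if bonferroni_m is not None else len(table)
    table["p_bonf"] = bonferroni(table["p_raw"], m)
    table["m_tests"] = m
    return table, report


# ---------------------------------------------------------------------------
# effect sizes and auxiliary statistics


def cohens_d(group_a, group_b) -> float:
    """Cohen's d: mean difference over the sample-size-weighted pooled SD.

    Positive values mean group_a has the larger mean.  Benchmarks: 0.2
    small, 0.5 medium, 0.8 large.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs >= 2 values")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise DataError("zero pooled standard deviation; effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test: (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DataError("both variances zero; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ld_r2(cohort: TwinCohort, snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise composite LD r^2: squared Pearson correlation of dosages.

    Computed on one member per MZ pair, pairwise-complete over individuals.
    Monomorphic SNPs yield NaN off-diagonal entries; the diagonal is 1 for
    polymorphic SNPs.
    """
    snps = list(snp_ids) if snp_ids is not None else cohort.snp_ids
    geno = cohort.genotypes.loc[snps, cohort.one_per_mz_pair()]
    n = len(snps)
    out = np.full((n, n), np.nan)
    arrays = geno.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i, n):
            ok = np.isfinite(arrays[i]) & np.isfinite(arrays[j])
            if ok.sum() < 2:
                continue
            xi, xj = arrays[i][ok], arrays[j][ok]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                if i == j:
                    continue
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            out[i, j] = out[j, i] = r * r
    return pd.DataFrame(out, index=snps, columns=snps)
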