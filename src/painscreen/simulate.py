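"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's four input families:

* citation-count tables with heterogeneous phenotype propensity (a point
  mass at zero plus a right-skewed Beta), so disease-phenotype ratios span
  [0, 1] with most mass near 0 and a few at 1 — the shape of real
  literature co-citation tables;
* per-disease case/control expression studies in which a planted subset of
  genes has a mean log2 fold change that trends linearly (sign randomized
  per gene) with the disease's index midrank, plus a direct fold-change
  matrix generator for screen-level experiments; planted genes double as
  the gold standard for ROC validation;
* a twin cohort with Hardy-Weinberg genotypes, exact MZ genotype sharing,
  DZ sharing through explicit parental transmission (expected co-twin
  dosage correlation 1/2), group-specific residual variances, a
  pair-shared environmental term, and planted (optionally male-specific)
  SNP effects.

Every generator is a pure function of a `SimulationConfig`; identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .dspi import PhenotypeIndex, build_index
from .errors import ConfigError
from .rankprod import ExpressionStudy

#: pair-level residual variances by zygosity and sex composition
DEFAULT_VAR_COMPONENTS = {
    "MZ-M": 1.0,
    "MZ-F": 0.8,
    "DZ-M": 1.4,
    "DZ-F": 1.1,
    "DZ-mixed": 1.2,
}

#: phenotype location parameters: heat threshold in deg C, cold times as
#: log-seconds (so the log transform recovers the linear model exactly)
PHENOTYPE_BASELINES = {"heat_c": 46.0, "cold_thresh_s": 3.0, "cold_tol_s": 3.7}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators, with study-scale defaults.

    The expression defaults (40 diseases, 500 genes, 25 planted, slope
    0.175 per rank step against unit disease-level noise) put the planted
    genes' rank signal-to-noise near 2, the regime where a correlation
    screen should recover nearly all of them without being trivial.
    """

    seed: int = 0
    # citations
    n_diseases: int = 40
    propensity_zero_mass: float = 0.25
    propensity_beta: tuple[float, float] = (0.6, 2.5)
    propensity_const: float | None = None  # force a constant propensity (testing)
    citation_log_mean: float = 3.5
    citation_log_sd: float = 1.5
    # expression
    n_genes: int = 500
    n_planted_genes: int = 25
    planted_slope: float = 0.175
    noise_sd: float = 1.0
    sample_noise_sd: float | None = None  # within-study sample noise; noise_sd if None
    missing_fraction: float = 0.10
    n_case: int = 4
    n_control: int = 4
    # twin cohort
    n_pairs: int = 200
    prop_mz: float = 0.5
    singleton_fraction: float = 0.0
    n_snps: int = 8
    maf_vector: tuple[float, ...] | None = None
    causal_snps: tuple[int, ...] = (0,)
    beta_snp: float = 0.5
    sex_specific: bool = False
    beta_sex: float = 0.3
    beta_dep: float = 0.02
    pair_env_corr: float = 0.3
    var_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VAR_COMPONENTS)
    )
    geno_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            (self.n_diseases >= 2, "n_diseases must be >= 2"),
            (self.n_genes >= 1, "n_genes must be >= 1"),
            (0 <= self.n_planted_genes <= self.n_genes,
             "n_planted_genes must be in [0, n_genes]"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.sample_noise_sd is None or self.sample_noise_sd >= 0,
             "sample_noise_sd must be >= 0"),
            (0 <= self.missing_fraction < 1, "missing_fraction must be in [0, 1)"),
            (0 <= self.propensity_zero_mass <= 1, "propensity_zero_mass in [0, 1]"),
            (self.n_pairs >= 1, "n_pairs must be >= 1"),
            (0 <= self.prop_mz <= 1, "prop_mz must be in [0, 1]"),
            (0 <= self.singleton_fraction <= 1, "singleton_fraction in [0, 1]"),
            (0 <= self.pair_env_corr < 1, "pair_env_corr must be in [0, 1)"),
            (0 <= self.geno_missing_rate < 1, "geno_missing_rate in [0, 1)"),
            (all(v > 0 for v in self.var_components.values()),
             "var_components must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.maf_vector is not None:
            if len(self.maf_vector) != self.n_snps:
                raise ConfigError("maf_vector length must equal n_snps")
            if any(not 0 < m <= 0.5 for m in self.maf_vector):
                raise ConfigError("MAFs must be in (0, 0.5]")
        if self.propensity_const is not None and not 0 <= self.propensity_const <= 1:
            raise ConfigError("propensity_const must be in [0, 1]")
        if any(not 0 <= c < self.n_snps for c in self.causal_snps):
            raise ConfigError("causal_snps indices out of range")

    @property
    def mafs(self) -> np.ndarray:
        if self.maf_vector is not None:
            return np.asarray(self.maf_vector, dtype=float)
        return np.full(self.n_snps, 0.3)

    def mean_ratio(self) -> float:
        """Closed-form expected disease-phenotype ratio under the propensity
        mixture (the binomial draw leaves the propensity mean unchanged)."""
        if self.propensity_const is not None:
            return self.propensity_const
        a, b = self.propensity_beta
        return (1 - self.propensity_zero_mass) * a / (a + b)

    def substream(self, label: str) -> np.random.Generator:
        """Independent generator per stage, all derived from the one seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(sum(label.encode()),))
        )


def simulate_citations(cfg: SimulationConfig) -> pd.DataFrame:
    """Citation-count table: one row per disease with total and phenotype
    co-citation counts.

    Totals are lognormal (rounded, floored at 1); each disease's phenotype
    propensity is 0 with probability ``propensity_zero_mass`` and
    Beta(*propensity_beta*) otherwise, and the phenotype count is binomial
    in the total.  Zero-propensity diseases exercise the index inclusion
    rule.
    """
    rng = cfg.substream("citations")
    n = cfg.n_diseases
    totals = np.maximum(
        1, np.round(rng.lognormal(cfg.citation_log_mean, cfg.citation_log_sd, n))
    ).astype(int)
    if cfg.propensity_const is not None:
        propensity = np.full(n, cfg.propensity_const)
    else:
        a, b = cfg.propensity_beta
        propensity = rng.beta(a, b, n)
        propensity[rng.random(n) < cfg.propensity_zero_mass] = 0.0
    n_phen = rng.binomial(totals, propensity)
    return pd.DataFrame(
        {
            "disease_id": [f"D{i:04d}" for i in range(n)],
            "disease_name": [f"disease {i}" for i in range(n)],
            "n_total": totals,
            "n_phenotype": n_phen,
        }
    )


def simulate_index(cfg: SimulationConfig) -> PhenotypeIndex:
    """Convenience: citations -> phenotype index in one step."""
    return build_index(simulate_citations(cfg))


def _planted_registry(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_planted_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_planted_genes)
    registry = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in planted_idx],
            "sign": signs,
            "slope": cfg.planted_slope,
        }
    )
    if cfg.n_planted_genes > 0 and cfg.planted_slope == 0:
        warnings.warn("planted_slope is 0: planted genes are indistinguishable from null")
    return registry


def _true_fold_changes(
    cfg: SimulationConfig, index: PhenotypeIndex, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x disease matrix of true log2 fold changes plus the registry.

    Planted genes: sign * slope * (midrank - mean midrank) + N(0, noise_sd);
    null genes draw the same noise with zero mean, so slope 0 makes the two
    groups exchangeable.
    """
    if len(index) == 0:
        raise ConfigError("index is empty")
    registry = _planted_registry(cfg, rng)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    mids = index.midranks.to_numpy(dtype=float)
    centered = mids - mids.mean()
    fc = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(mids)))
    sign_by_gene = dict(zip(registry["gene_id"], registry["sign"]))
    for gi, gid in enumerate(gene_ids):
        if gid in sign_by_gene:
            fc[gi] += sign_by_gene[gid] * cfg.planted_slope * centered
    matrix = pd.DataFrame(fc, index=gene_ids, columns=index.disease_ids)
    matrix.index.name = "gene_id"
    return matrix, registry


def simulate_fold_change_matrix(
    cfg: SimulationConfig, index: PhenotypeIndex
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change matrix ready for the correlation screen, with missingness.

    Skips the sample-level machinery: entries are the true disease-level
    fold changes, with a ``missing_fraction`` of gene-disease cells blanked.
    """
    rng = cfg.substream("expression")
    matrix, registry = _true_fold_changes(cfg, index, rng)
    if cfg.missing_fraction > 0:
        mask = rng.random(matrix.shape) < cfg.missing_fraction
        matrix = matrix.mask(mask)
    return matrix, registry


def simulate_expression_studies(
    cfg: SimulationConfig, index: PhenotypeIndex
) -> tuple[dict[str, ExpressionStudy], pd.DataFrame]:
    """Per-disease case/control studies embedding the planted fold changes.

    Control samples are baseline + N(0, sample_noise_sd); case samples add
    the disease's true fold change for each gene.  Genes hit by the
    missingness mask are absent from that disease's study entirely (the
    disease did not measure them).
    """
    rng = cfg.substream("expression")
    truth, registry = _true_fold_changes(cfg, index, rng)
    sample_sd = cfg.noise_sd if cfg.sample_noise_sd is None else cfg.sample_noise_sd
    studies: dict[str, ExpressionStudy] = {}
    for d in index.disease_ids:
        measured = np.ones(cfg.n_genes, dtype=bool)
        if cfg.missing_fraction > 0:
            measured = rng.random(cfg.n_genes) >= cfg.missing_fraction
        genes = truth.index[measured]
        baseline = rng.normal(8.0, 2.0, size=measured.sum())
        control = baseline[:, None] + rng.normal(
            0.0, sample_sd, size=(measured.sum(), cfg.n_control)
        )
        case = (
            baseline[:, None]
            + truth.loc[genes, d].to_numpy()[:, None]
            + rng.normal(0.0, sample_sd, size=(measured.sum(), cfg.n_case))
        )
        studies[d] = ExpressionStudy(
            disease_id=d,
            case=pd.DataFrame(case, index=genes, columns=[f"case{i}" for i in range(cfg.n_case)]),
            control=pd.DataFrame(control, index=genes, columns=[f"ctrl{i}" for i in range(cfg.n_control)]),
        )
    return studies, registry


# ---------------------------------------------------------------------------
# twin cohort


def simulate_twin_cohort(cfg: SimulationConfig):
    """Twin cohort with planted SNP effects; returns (TwinCohort, truth table).

    Genotypes: each SNP is in Hardy-Weinberg equilibrium at its MAF.  MZ
    co-twins share one genotype vector; DZ co-twins each inherit one allele
    from each of two simulated parents, giving the Mendelian expected
    co-twin dosage correlation of 1/2.  Phenotypes follow

        y = baseline + beta_snp * dosage[causal] * (male if sex_specific)
            + beta_sex * sex_code + beta_dep * depression + e,

    where e splits into a pair-shared and an individual part so that the
    within-pair residual correlation is ``pair_env_corr`` and the total
    residual variance is the pair's entry in ``var_components``.  Heat
    threshold is in deg C; cold threshold/tolerance are exp() of the linear
    scale, so the standard log transform recovers the planted effect.
    """
    from .twin import TwinCohort  # local import to avoid a cycle

    rng = cfg.substream("twins")
    mafs = cfg.mafs
    n_mz = round(cfg.prop_mz * cfg.n_pairs)
    n_dz = cfg.n_pairs - n_mz
    n_single = round(cfg.singleton_fraction * cfg.n_pairs)

    rows = []       # individual metadata
    genos = []      # per-individual dosage vectors
    latent_env = [] # (shared_normal, own_normal, var_group) per individual

    def hwe_genotype() -> np.ndarray:
        return (rng.random(cfg.n_snps) < mafs).astype(float) + (
            rng.random(cfg.n_snps) < mafs
        )

    pair_counter = 0
    for _ in range(n_mz):
        pair_counter += 1
        pid = f"P{pair_counter:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        g = hwe_genotype()
        shared = rng.normal()
        vg = f"MZ-{sex}"
        for t in range(2):
            rows.append((f"{pid}_{t+1}", pid, "MZ", sex))
            genos.append(g.copy())
            latent_env.append((shared, rng.normal(), vg))
    for _ in range(n_dz):
        pair_counter += 1
        pid = f"P{pair_counter:04d}"
        father = (rng.random((cfg.n_snps, 2)) < mafs[:, None]).astype(float)
        mother = (rng.random((cfg.n_snps, 2)) < mafs[:, None]).astype(float)
        sexes = ["M" if rng.random() < 0.5 else "F" for _ in range(2)]
        if sexes[0] != sexes[1]:
            vg = "DZ-mixed"
        else:
            vg = f"DZ-{sexes[0]}"
        shared = rng.normal()
        for t in range(2):
            pick_f = rng.integers(0, 2, cfg.n_snps)
            pick_m = rng.integers(0, 2, cfg.n_snps)
            g = father[np.arange(cfg.n_snps), pick_f] + mother[np.arange(cfg.n_snps), pick_m]
            rows.append((f"{pid}_{t+1}", pid, "DZ", sexes[t]))
            genos.append(g)
            latent_env.append((shared, rng.normal(), vg))
    for s in range(n_single):
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((f"S{s:04d}", None, "NA", sex))
        genos.append(hwe_genotype())
        # singleton variance: reuse the matching MZ group's scale
        latent_env.append((rng.normal(), rng.normal(), f"MZ-{sex}"))

    ind = pd.DataFrame(rows, columns=["individual_id", "pair_id", "zygosity", "sex"])
    geno_matrix = np.vstack(genos).T  # SNP x individual
    snp_ids = [f"rs{i:06d}" for i in range(cfg.n_snps)]

    depression = np.clip(rng.poisson(6, len(ind)), 0, 63).astype(float)
    sex_code = ind["sex"].map({"M": -1.0, "F": 1.0}).to_numpy()
    male = (ind["sex"] == "M").to_numpy().astype(float)

    causal = np.zeros(cfg.n_snps)
    for c in cfg.causal_snps:
        causal[c] = cfg.beta_snp
    genetic = geno_matrix.T @ causal
    if cfg.sex_specific:
        genetic = genetic * male

    fixed = genetic + cfg.beta_sex * sex_code + cfg.beta_dep * (depression - depression.mean())

    phen = {}
    rho = cfg.pair_env_corr
    shared_arr = np.array([s for s, _, _ in latent_env])
    sd_arr = np.sqrt(np.array([cfg.var_components[vg] for _, _, vg in latent_env]))
    for name in ("heat_c", "cold_thresh_s", "cold_tol_s"):
        # fresh individual residual per phenotype; shared term reused so the
        # pair correlation structure is common across phenotypes
        z = sd_arr * (
            np.sqrt(rho) * shared_arr
            + np.sqrt(1 - rho) * rng.standard_normal(len(latent_env))
        )
        lin = PHENOTYPE_BASELINES[name] + fixed + z
        phen[name] = lin if name == "heat_c" else np.exp(lin)
    ind = ind.assign(depression=depression, **phen)
    ind = ind[["individual_id", "pair_id", "zygosity", "sex",
               "heat_c", "cold_thresh_s", "cold_tol_s", "depression"]]

    if cfg.geno_missing_rate > 0:
        mask = rng.random(geno_matrix.shape) < cfg.geno_missing_rate
        geno_matrix = np.where(mask, np.nan, geno_matrix)

    genotypes = pd.DataFrame(
        geno_matrix, index=snp_ids, columns=ind["individual_id"].tolist()
    )
    genotypes.index.name = "snp_id"
    truth = pd.DataFrame(
        {
            "snp_id": [snp_ids[c] for c in cfg.causal_snps],
            "beta": cfg.beta_snp,
            "sex_specific": cfg.sex_specific,
        }
    )
    return TwinCohort(individuals=ind, genotypes=genotypes), truth
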