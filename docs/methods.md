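# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Disease-specific phenotype index

The index treats each disease as one qualitative observation: the fraction
of its publications co-annotated with the phenotype heading, unweighted by
publication volume. A disease enters the index only with at least one
phenotype co-citation; a disease with zero total citations cannot be
scored. Because many diseases share a ratio (in particular ratio 1.0),
ranks are midranks — the standard Spearman convention — so downstream rank
correlations are tie-corrected automatically. The presentation sort order
(ratio, then total citations descending, then id) is a determinism device
only; no downstream computation depends on it. Live literature querying is
out of scope: the index is built from a delimited counts table, and an
optional id blocklist stands in for species filtering.

## Rank Product differential expression

For an unpaired study with `k` case and `m` control samples we form all
`k·m` pairwise comparisons, rank genes within each comparison by the
case-minus-control log2 difference (once descending for up-regulation,
once ascending for down-regulation), and summarize each gene by the
geometric mean of its ranks. Permutation p-values assign fresh uniform
rank permutations within each comparison; the sampled estimate uses the
add-one convention `p = (1 + #{RP_null ≤ RP_obs}) / (n_perm + 1)`, and an
exhaustive mode enumerates all `(G!)^K` assignments exactly for tiny
problems (it is the oracle the tests compare against). Two caveats are
inherent to this classical construction and documented rather than
patched: pairwise comparisons share samples, so the permutation null
neglects their positive dependence and null p-values are only
approximately uniform (exactly uniform in the single-comparison design);
and the statistic is invariant to positive-affine, not arbitrary
monotone, transforms of intensities, because monotone maps do not
preserve the cross-gene ordering of differences.

Genes are retained at Storey q ≤ 0.05, computed per direction with π₀
estimated on the λ grid 0.05–0.95 (step 0.05) with a cubic-smoother
evaluation at the largest λ, clipped to (0, 1]; with fewer than 20
p-values π₀ is conservatively fixed at 1. The retained gene carries its
signed fold change so both up- and down-regulation reach the screen.

## Correlation screen and permutation pFDR

The fold-change matrix keeps genes observed in at least
`ceil(0.10 · n_diseases)` diseases — "at least 10%" is read as a floor.
Spearman ρ per gene uses pairwise-complete observations; the p-value uses
the t approximation. The pFDR is two-sided on |ρ| with per-gene
thresholds: each of the (default 1000) permutations shuffles the disease
midranks once and recomputes all genes' correlations on their own
missingness patterns, so each gene's null is matched to its own number of
observations. Raw E[V]/R is clipped at 1 and enforced monotone
nonincreasing in |ρ| by a running maximum from the strongest gene down —
a conservative enforcement that never lowers a weaker gene below a
stronger one. An exhaustive mode enumerates all D! disease permutations
for D ≤ 8 and defines the n_perm → ∞ limit used in testing. Because the
pFDR's resolution is bounded below by roughly (expected null exceedances)
/ (rejections), small matrices (on the order of a hundred genes) cannot
reach pFDR < 0.01; the analysis drivers therefore run at 300 genes × ~86
diseases, where the threshold is attainable.

## ROC validation

The priority score orders genes by pFDR ascending with |ρ| descending as
tie-break. AUC is the tie-corrected Mann–Whitney concordance probability
(identical to trapezoidal integration of the empirical ROC when scores
are tie-free; the tests assert this to 1e-12). The optimal cutoff
maximizes Youden's J. Confidence bands repeat the screen on random 90%
subsets of the diseases and interpolate each replicate's ROC onto a
common false-positive-rate grid; both a standard-error envelope and
empirical 2.5/97.5% quantiles are emitted, since either convention is
defensible. Replicates whose subset yields an empty matrix are skipped
and logged.

## Twin-cohort association

Pairs are collapsed to single observations: phenotypes are transformed at
the individual level (identity for heat threshold; natural log for the
cold pressor times, whose values must be positive; rank-based
inverse-normal with the Blom offset (r − 3/8)/(n + 1/4) as the
sensitivity variant), then averaged within pairs, as are allele dosages
and covariates. Transforming before averaging keeps the error model on
one scale. Sex is coded −1 (male) / +1 (female) and averaged; mixed-sex
DZ pairs get 0. Cold pressor observations at the 180 s ceiling are
censoring artifacts and are excluded (strict equality). Units are labeled
with variance groups {MZ-M, MZ-F, DZ-M, DZ-F, DZ-mixed, singleton-M,
singleton-F}; groups with fewer than two units merge into their
zygosity's pooled group.

SNP QC removes markers with call rate < 90%, minor allele frequency < 5%,
or a 1-df Hardy–Weinberg χ² p < 0.01 (monomorphic SNPs return p = 1 by
convention, so they fall to the MAF filter). HWE and LD r² (composite:
squared Pearson correlation of dosages) use one member per MZ pair, since
duplicated genomes would bias both. Missing genotypes are imputed as
homozygous wildtype (dosage 0); when that contradicts an observed MZ
co-twin the rule is still applied and a warning logged.

The association model per SNP is
`ȳ = β₀ + β_g ḡ + β_sex sex + β_dep d̄ep + ε` with `Var(ε)` diagonal and
constant within variance groups, fitted by iterated feasible GLS:
ordinary least squares start, group variances from residual sums of
squares over leverage-adjusted degrees of freedom (`n_g − tr(H_g)`, with
a small floor), reweight, iterate to relative coefficient change < 1e−8
(max 50 iterations). Two small-sample corrections matter at cohort scale,
where each variance group holds only a few dozen pairs, and are applied
to the covariance: the estimated precisions are deflated by
`(ν_g − 2)/ν_g` (undoing the Jensen bias of inverting a χ²-distributed
variance estimate), and the Kackar–Harville term for the extra
variability induced by estimating the weights is added. Without these the
nominal 5% test rejects true nulls at ~6.5–7.5% under the study
conditions; with them, simulation (3000 replicates) puts the rate at
4.9%. Wald p-values use a t reference with `n − p` degrees of freedom.
With a single variance group the coefficient estimates reduce exactly to
OLS. Constant covariate columns (e.g. sex within a single-sex stratum)
are dropped to keep the design full-rank. Bonferroni uses the number of
QC-passing SNPs per phenotype by default; the multiplier is configurable
and recorded. Cohen's d uses the sample-size-weighted pooled standard
deviation; group comparisons use Welch's unequal-variance t-test.

## Synthetic generators

The generators define the study conditions used by the tests and the
acceptance script; all draw from per-stage substreams of one seed, so a
given configuration is byte-reproducible.

* **Citations.** Totals are rounded lognormal (meanlog 3.5, sdlog 1.5,
  floored at 1); each disease's phenotype propensity is 0 with
  probability 0.25 and Beta(0.6, 2.5) otherwise, and the phenotype count
  is binomial. This reproduces the shape of real co-citation tables —
  most ratios near zero, a few at 1, some exact zeros to exercise the
  inclusion rule — and gives the closed-form mean ratio
  `0.75 · 0.6/3.1` used as the distributional oracle.
* **Expression.** Planted genes' true log2 fold change is
  `sign · slope · (midrank − mean midrank) + N(0, noise_sd)` with the
  sign randomized per gene; null genes draw the same noise with zero
  mean, so slope 0 makes the two groups exchangeable. Defaults (40
  diseases, 500 genes, 25 planted, slope 0.175, unit noise) put the rank
  signal-to-noise near 2 — strong enough that a working screen recovers
  essentially all planted genes, weak enough that a broken one does not.
  Study-level matrices add baseline intensities and within-group sample
  noise (`sample_noise_sd`, defaulting to `noise_sd`); the missingness
  mask removes a gene from a disease's study entirely. Probe-level
  artifacts, batch effects and realistic LD blocks are deliberately not
  modeled, so passing tests speak to the statistics, not to microarray
  preprocessing.
* **Twin cohort.** Genotypes are Hardy–Weinberg draws at each SNP's MAF;
  MZ co-twins share a genotype vector, DZ co-twins inherit one allele
  from each of two explicit parents (expected co-twin dosage correlation
  1/2, always valid 0/1/2 genotypes). Phenotype residuals split into a
  pair-shared and an individual part so the within-pair correlation is
  `pair_env_corr` (default 0.3) and the total variance is the pair's
  variance-group entry (defaults 0.8–1.4, differing by zygosity and
  sex). The planted SNP effect enters all three phenotypes on their
  model scales (cold times are exponentiated so the log transform
  recovers the effect exactly); with `sex_specific` it is multiplied by
  a male indicator. Depression is a Beck-like non-negative integer score
  (Poisson(6) clipped to 0–63). Cohort phenotype scales are chosen for
  testability, not clinical realism.

## Problem sizes

Default test and acceptance runs use 40-disease indices with 200–500
genes, 1000 screen permutations, 200–300 pair cohorts, and a few hundred
simulation replicates for the calibration checks; the chained
demonstration study uses 150 simulated diseases (≈ 86 retained), 300
genes, and a 120-pair cohort. These sizes keep every check well inside a
desktop budget while leaving the statistical properties measurable.

## Known limitations

The permutation pFDR conditions on each gene's missingness pattern but
not on any between-gene correlation, so strongly co-expressed gene
modules share null fluctuations the method does not model. The Rank
Product permutation null ignores comparison dependence (above). The GLS
stage models heteroscedasticity but not residual relatedness between
different pairs (e.g. siblings across pairs), and the
homozygous-wildtype imputation rule biases dosages downward when
missingness is high — both inherited design choices, applied as stated.
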