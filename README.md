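# painscreen

Data-driven prioritization of pain-gene candidates from disease literature
and gene-expression compendia, with twin-cohort genetic validation.

Clinical pain phenotypes are expensive to collect at scale, which has made
pain genetics slow compared to other fields. This package implements an
integrative screen that sidesteps dedicated pain cohorts at the discovery
stage:

1. **Disease-specific pain index (DSPI).** Every disease is scored by the
   fraction of its literature co-annotated with a "pain" subject heading,
   `ratio_d = n_pain(d) / n_total(d)`, and diseases with at least one pain
   co-citation are ranked by this ratio (ties share midranks). The same
   machinery builds an inflammation index (DSII) or any other
   phenotype-heading index.
2. **Differential expression per disease.** Case/control expression studies
   are reduced to signed log2 fold changes with Rank Product statistics
   (geometric mean of a gene's ranks across all pairwise case-vs-control
   comparisons), permutation p-values, and Storey q-values; genes with
   q ≤ 0.05 are kept.
3. **Correlation screen.** Fold changes are assembled into a gene × disease
   matrix ordered by the index (genes measured in ≥ 10% of diseases), and
   each gene's Spearman ρ against the index midranks is computed on its
   pairwise-complete diseases. Significance is a permutation positive false
   discovery rate: disease ranks are shuffled (1000×), every gene's ρ is
   recomputed, and pFDR(g) = E[V]/R — expected null exceedances of |ρ_g|
   over observed exceedances. Genes with pFDR < 0.01 are the candidates.
4. **ROC validation.** The candidate ranking is scored against a
   gold-standard gene set (Mann–Whitney AUC with tie correction, Youden-J
   optimal cutoff), with confidence bands from delete-10% disease
   resampling.
5. **Twin-cohort association.** Candidate SNPs are tested against
   experimental pain measures (heat pain threshold in °C; log cold pressor
   threshold/tolerance in seconds) in a twin cohort: QC (call rate ≥ 90%,
   MAF ≥ 5%, Hardy–Weinberg p ≥ 0.01), homozygous-wildtype imputation,
   pair-averaged encoding (dosages and transformed phenotypes averaged
   within pairs; sex coded −1/+1 and averaged, so mixed-sex DZ pairs are 0),
   and a feasible GLS fit `ȳ = β₀ + β_g ḡ + β_sex sex + β_dep dep + ε`
   whose residual variance is constant within zygosity × sex groups.
   Bonferroni correction, Cohen's d, Welch t-tests, rank-based
   inverse-normal transforms, and cohort LD r² round out the stage.

Every stage is exercised end-to-end on synthetic data from the built-in
generators (`painscreen.simulate`), which plant known truths: genes whose
fold change trends monotonically with the index, and SNPs with (optionally
male-specific) phenotype effects in a cohort with MZ/DZ genotype sharing
and group-specific variances.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study into
`results/run/` (about half a minute in total):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_build_pain_index.py
python analysis/03_differential_expression.py
python analysis/04_correlation_screen.py
python analysis/05_roc_validation.py
python analysis/06_twin_association.py
```

Output from a run (seed 7, fixed in the drivers):

```
pain index: 86 diseases retained, 64 excluded for lacking a pain co-citation
differential expression on 86 diseases; mean 95.5 genes retained at q<=0.05
matrix: 300 genes x 86 diseases
candidates at pFDR < 0.01: 25
of which planted (true) genes: 25 / 25 planted
AUC = 1.000 over 25 gold / 275 background genes
resampled AUC: 1.000 +/- 0.000 (delete-10% replicates)
3 SNPs tested (0 removed by QC)
  rs000000 x cold_thresh_s: beta=0.625 p=9.89e-06 p_bonf=2.97e-05 (planted)
```

Reading: of 150 simulated diseases, 86 had a pain co-citation and an
expression study; the screen recovered exactly the 25 planted trending
genes at pFDR < 0.01 (perfect prioritization of the planted gold standard,
AUC = 1.0); and the planted causal SNP — simulated with effect 0.6
log-seconds per averaged allele on the cold pressor threshold — was
estimated at 0.625 and stayed significant after Bonferroni correction over
3 SNPs × 3 phenotypes.

The same pipeline is scriptable through the `painscreen` CLI
(`simulate | dspi | de | correlate | validate | assoc | all`), e.g.

```bash
painscreen all --out results/cli_run --seed 7
```

Exit codes: 0 ok, 1 data error, 2 configuration error. All outputs are
tab-delimited with provenance headers (stage, seed, config hash); reruns
with the same seed are byte-identical.

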