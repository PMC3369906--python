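#!/usr/bin/env python
"""Generate every pipeline input: citation counts, expression studies, twin cohort.

Writes the synthetic study to results/run/ — a citation-count table standing
in for the MEDLINE/MeSH queries, per-disease case/control expression studies
with 25 planted pain-trending genes among 300, a gold-standard gene list
(the planted registry), and a 120-pair twin cohort with one causal SNP.
"""

from pathlib import Path

from painscreen.pipeline import RunConfig, run_pipeline
from painscreen.simulate import SimulationConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "run"
SEED = 7

SIM = SimulationConfig(
    seed=SEED,
    n_diseases=150,
    n_genes=300,
    n_planted_genes=25,
    planted_slope=0.1,
    noise_sd=1.0,
    sample_noise_sd=0.5,
    missing_fraction=0.05,
    n_case=4,
    n_control=4,
    n_pairs=120,
    n_snps=3,
    maf_vector=(0.3, 0.3, 0.4),
    beta_snp=0.6,
)


def main() -> None:
    manifest = run_pipeline(
        RunConfig(out_dir=str(OUT), seed=SEED, stages=("simulate",), sim=SIM)
    )
    c = manifest["counts"]["simulate"]
    print(f"simulated {c['diseases']} diseases, {c['studies']} expression studies,")
    print(f"{c['planted_genes']} planted genes, {c['individuals']} twins, {c['snps']} SNPs")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
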