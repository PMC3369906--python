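"""Stage orchestration: simulate -> dspi -> de -> correlate -> validate -> assoc.

`run_pipeline` executes any subset of stages into an output directory,
reading each stage's inputs from the previous stage's files so stages can
also be rerun independently.  A machine-readable manifest records inputs,
parameters, the seed, and the counts at every filter.  One global seed is
expanded into per-stage substreams, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .dspi import build_index
from .errors import ConfigError, DataError
from .rankprod import differential_expression
from .screen import assemble_matrix, score_genes, select_candidates
from .simulate import SimulationConfig, simulate_citations, simulate_expression_studies, simulate_twin_cohort
from .twin import PHENOTYPES, association_scan, ld_r2
from .validate import GoldStandard, priority_scores, resampling_band, roc_auc

STAGES = ("simulate", "dspi", "de", "correlate", "validate", "assoc")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; thresholds default to study values."""

    out_dir: str
    seed: int = 0
    stages: Sequence[str] = STAGES
    sim: SimulationConfig | None = None  # built from seed if absent
    min_fraction: float = 0.10
    de_q: float = 0.05
    pfdr_alpha: float = 0.01
    n_perm: int = 1000
    de_n_perm: int = 200
    resample_fraction: float = 0.9
    resample_replicates: int = 50
    transform: str | None = None  # per-phenotype default when None
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_alpha: float = 0.01
    bonferroni_m: int | None = None
    phenotypes: Sequence[str] = PHENOTYPES

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        for name, value, lo, hi in [
            ("min_fraction", self.min_fraction, 0, 1),
            ("de_q", self.de_q, 0, 1),
            ("pfdr_alpha", self.pfdr_alpha, 0, 1),
            ("call_rate_min", self.call_rate_min, 0, 1),
            ("maf_min", self.maf_min, 0, 0.5),
            ("hwe_alpha", self.hwe_alpha, 0, 1),
            ("resample_fraction", self.resample_fraction, 0, 1),
        ]:
            if not lo < value <= hi:
                raise ConfigError(f"{name}={value} outside ({lo}, {hi}]")
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    def provenance(self, stage: str) -> dict:
        # hash only analysis-relevant parameters, not filesystem locations
        params = {k: v for k, v in asdict(self).items() if k not in ("sim", "out_dir")}
        return {
            "painscreen_stage": stage,
            "seed": self.seed,
            "config_sha": pio.config_hash(params),
        }


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": list(config.stages), "counts": {}}
    counts = manifest["counts"]

    if "simulate" in config.stages:
        cfg = config.sim
        citations = simulate_citations(cfg)
        pio.write_citations(citations, out / "citations.tsv", config.provenance("simulate"))
        index = build_index(citations)
        studies, registry = simulate_expression_studies(cfg, index)
        for d, study in studies.items():
            pio.write_expression_study(
                study, out / "studies" / f"{d}.expr.tsv", out / "studies" / f"{d}.design.tsv"
            )
        pio.write_table(registry, out / "planted_genes.tsv", config.provenance("simulate"), index=False)
        pio.write_gene_list(sorted(registry["gene_id"]), out / "gold_standard.txt")
        cohort, truth = simulate_twin_cohort(cfg)
        pio.write_cohort(cohort, out / "individuals.tsv", out / "dosages.tsv", config.provenance("simulate"))
        pio.write_table(truth, out / "planted_snps.tsv", config.provenance("simulate"), index=False)
        counts["simulate"] = {
            "diseases": len(citations),
            "studies": len(studies),
            "planted_genes": len(registry),
            "individuals": len(cohort.individuals),
            "snps": len(cohort.genotypes),
        }

    if "dspi" in config.stages:
        citations = pio.read_citations(out / "citations.tsv")
        index = build_index(citations)
        pio.write_index(index, out / "index.tsv", config.provenance("dspi"))
        counts["dspi"] = {"retained": len(index), "excluded": index.n_excluded}

    if "de" in config.stages:
        index = pio.read_index(out / "index.tsv")
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
        de_dir = out / "de"
        n_retained = {}
        for i, d in enumerate(index.disease_ids):
            expr = out / "studies" / f"{d}.expr.tsv"
            if not expr.exists():
                continue
            study = pio.read_expression_study(expr, out / "studies" / f"{d}.design.tsv", d)
            seed_d = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            de = differential_expression(
                study, n_perm=config.de_n_perm, seed=seed_d, q_threshold=config.de_q
            )
            pio.write_table(de, de_dir / f"{d}.de.tsv", config.provenance("de"))
            n_retained[d] = int(de["retained"].sum())
        if not n_retained:
            raise DataError("no expression study matched an index disease")
        counts["de"] = {"diseases": len(n_retained), "retained_genes": n_retained}

    if "correlate" in config.stages:
        index = pio.read_index(out / "index.tsv")
        de_tables = {
            p.name.removesuffix(".de.tsv"): pio.read_table(p, required=["gene_id"], index_col="gene_id")
            for p in sorted((out / "de").glob("*.de.tsv"))
        }
        matrix = assemble_matrix(de_tables, index, config.min_fraction)
        pio.write_matrix(matrix, out / "matrix.tsv", config.provenance("correlate"))
        seed_c = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(3,)).generate_state(1)[0]
            % (2**31)
        )
        scores = score_genes(
            matrix, index, n_perm=config.n_perm, seed=seed_c, alpha=config.pfdr_alpha
        )
        pio.write_table(scores, out / "scores.tsv", config.provenance("correlate"))
        candidates = select_candidates(scores, config.pfdr_alpha)
        pio.write_table(candidates, out / "candidates.tsv", config.provenance("correlate"))
        counts["correlate"] = {
            "matrix_genes": len(matrix),
            "matrix_diseases": matrix.shape[1],
            "candidates": len(candidates),
        }

    if "validate" in config.stages:
        index = pio.read_index(out / "index.tsv")
        scores = pio.read_table(out / "scores.tsv", required=["gene_id"], index_col="gene_id")
        gold = GoldStandard.from_symbols(pio.read_gene_list(out / "gold_standard.txt"))
        roc = roc_auc(priority_scores(scores), gold)
        de_tables = {
            p.name.removesuffix(".de.tsv"): pio.read_table(p, required=["gene_id"], index_col="gene_id")
            for p in sorted((out / "de").glob("*.de.tsv"))
        }
        seed_v = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(4,)).generate_state(1)[0]
            % (2**31)
        )

        def rerun(disease_subset):
            sub_index = index.subset(disease_subset)
            sub_tables = {d: de_tables[d] for d in disease_subset if d in de_tables}
            sub_matrix = assemble_matrix(sub_tables, sub_index, config.min_fraction)
            sub_scores = score_genes(
                sub_matrix, sub_index, n_perm=max(100, config.n_perm // 4), seed=seed_v
            )
            return priority_scores(sub_scores)

        band, aucs = resampling_band(
            rerun,
            index.disease_ids,
            gold,
            fraction=config.resample_fraction,
            n_replicates=config.resample_replicates,
            seed=seed_v,
        )
        curve = pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds})
        pio.write_table(curve, out / "roc.tsv", config.provenance("validate"), index=False)
        pio.write_table(band, out / "roc_band.tsv", config.provenance("validate"), index=False)
        summary = pd.DataFrame(
            {
                "auc": [roc.auc],
                "best_sensitivity": [roc.best_cutoff[0]],
                "best_specificity": [roc.best_cutoff[1]],
                "n_gold_evaluable": [roc.n_gold],
                "n_background": [roc.n_background],
                "auc_replicate_mean": [float(np.mean(aucs))],
                "auc_replicate_sd": [float(np.std(aucs, ddof=1))],
            }
        )
        pio.write_table(summary, out / "roc_summary.tsv", config.provenance("validate"), index=False)
        counts["validate"] = {"n_gold_evaluable": roc.n_gold, "auc": roc.auc}

    if "assoc" in config.stages:
        cohort = pio.read_cohort(out / "individuals.tsv", out / "dosages.tsv")
        tables = []
        report = None
        for phen in config.phenotypes:
            table, report = association_scan(
                cohort,
                phen,
                transform=config.transform,
                call_rate_min=config.call_rate_min,
                maf_min=config.maf_min,
                hwe_alpha=config.hwe_alpha,
                bonferroni_m=config.bonferroni_m,
            )
            tables.append(table.reset_index())
        assoc = pd.concat(tables, ignore_index=True)
        pio.write_table(assoc, out / "association.tsv", config.provenance("assoc"), index=False)
        pio.write_table(report.reset_index(), out / "qc_report.tsv", config.provenance("assoc"), index=False)
        tested = sorted(assoc["snp_id"].unique())
        ld = ld_r2(cohort, tested)
        ld.index.name = "snp_id"
        pio.write_table(ld, out / "ld_r2.tsv", config.provenance("assoc"))
        manhattan = assoc[["snp_id", "phenotype", "p_raw"]].copy()
        manhattan["position"] = manhattan["snp_id"].map(
            {s: i + 1 for i, s in enumerate(cohort.snp_ids)}
        )
        manhattan["neg_log10_p"] = -np.log10(manhattan["p_raw"].clip(lower=1e-300))
        pio.write_table(
            manhattan[["snp_id", "position", "phenotype", "neg_log10_p"]],
            out / "manhattan.tsv",
            config.provenance("assoc"),
            index=False,
        )
        counts["assoc"] = {
            "snps_tested": len(tested),
            "qc_removed": int((report["removed_for"] != "").sum()),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
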