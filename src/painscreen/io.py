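"""Readers and writers for every format the pipeline touches.

Native interchange is tab-delimited text with required headers.  Every file
the pipeline writes starts with provenance comment lines (``# key=value``:
stage, seed, config hash) which readers skip.  Genotypes can additionally
arrive as an uncompressed VCF (GT field mapped to the dosage of the
non-reference allele).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dspi import CITATION_COLUMNS, PhenotypeIndex
from .errors import ConfigError, DataError
from .twin import INDIVIDUAL_COLUMNS, TwinCohort


def config_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping, for provenance headers."""
    blob = json.dumps({k: str(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: Mapping | None = None, index: bool = True
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    index_col: str | None = None,
    unique: str | None = None,
) -> pd.DataFrame:
    """Header-checked delimited read; '#' lines are provenance and skipped."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    if unique is not None and df[unique].duplicated().any():
        dups = df.index[df[unique].duplicated(keep=False)] + 2  # 1-based + header
        raise DataError(f"{path}: duplicate {unique} at data line(s) {list(dups)}")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


# ---------------------------------------------------------------------------
# stage-specific tables


def read_citations(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=CITATION_COLUMNS, unique="disease_id")


def write_citations(df: pd.DataFrame, path, provenance=None) -> None:
    write_table(df[CITATION_COLUMNS], path, provenance, index=False)


def write_index(index: PhenotypeIndex, path, provenance=None) -> None:
    write_table(index.entries, path, provenance, index=False)


def read_index(path: str | Path) -> PhenotypeIndex:
    df = read_table(path, required=["disease_id", "ratio", "midrank"], unique="disease_id")
    return PhenotypeIndex(df[["disease_id", "ratio", "midrank"]])


def write_matrix(matrix: pd.DataFrame, path, provenance=None) -> None:
    write_table(matrix, path, provenance)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=["gene_id"], index_col="gene_id")
    return df.astype(float)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s.upper())
    if not out:
        raise DataError(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(genes) + "\n")


def read_expression_study(matrix_path, design_path, disease_id: str):
    """Gene x sample intensity table plus a (sample_id, group) design table."""
    from .rankprod import ExpressionStudy

    expr = read_table(matrix_path, required=["gene_id"], index_col="gene_id", unique="gene_id")
    design = read_table(design_path, required=["sample_id", "group"], unique="sample_id")
    bad = set(design["group"]) - {"case", "control"}
    if bad:
        raise DataError(f"{design_path}: group must be case/control, got {bad}")
    missing = [s for s in design["sample_id"] if s not in expr.columns]
    if missing:
        raise DataError(f"{matrix_path}: samples absent from matrix: {missing}")
    case = expr[design.loc[design["group"] == "case", "sample_id"]]
    control = expr[design.loc[design["group"] == "control", "sample_id"]]
    return ExpressionStudy(disease_id=disease_id, case=case, control=control)


def write_expression_study(study, matrix_path, design_path, provenance=None) -> None:
    expr = pd.concat([study.case, study.control], axis=1)
    expr.index.name = "gene_id"
    write_table(expr, matrix_path, provenance)
    design = pd.DataFrame(
        {
            "sample_id": list(study.case.columns) + list(study.control.columns),
            "group": ["case"] * study.case.shape[1] + ["control"] * study.control.shape[1],
        }
    )
    write_table(design, design_path, provenance, index=False)


# ---------------------------------------------------------------------------
# twin cohort files


def read_individuals(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=INDIVIDUAL_COLUMNS, unique="individual_id")
    return df


def read_dosage_table(path: str | Path) -> pd.DataFrame:
    """SNP x individual dosage table; values 0/1/2 or NA."""
    df = read_table(path, required=["snp_id"], index_col="snp_id", unique="snp_id")
    values = df.to_numpy(dtype=float)
    ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise DataError(
            f"{path}: unparseable dosage at snp {df.index[bad[0]]}, "
            f"individual {df.columns[bad[1]]}"
        )
    return df.astype(float)


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Dosage matrix from a VCF's GT field (count of non-reference alleles).

    Positions are 1-based per the VCF standard; missing calls become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage = np.array(
            [np.nan if t == 2 else {0: 0.0, 1: 1.0, 3: 2.0}[t] for t in variant.gt_types]
        )
        rows.append(dosage)
        ids.append(vid)
    if not rows:
        raise DataError(f"{path}: no variants")
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate variant ids")
    out = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    out.index.name = "snp_id"
    return out


def write_vcf_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Minimal single-chromosome VCF for a 0/1/2 dosage matrix.

    Dosage d is written as the unphased genotype with d alternate alleles;
    NaN becomes './.'.  SNPs get consecutive 1-based positions.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(genotypes.columns)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for pos, (snp, row) in enumerate(genotypes.iterrows(), start=1):
            calls = [
                "./." if not np.isfinite(v) else gt_map[float(v)] for v in row.to_numpy()
            ]
            fh.write(f"1\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_cohort(cohort: TwinCohort, individuals_path, genotypes_path, provenance=None, vcf: bool = False) -> None:
    write_table(cohort.individuals, individuals_path, provenance, index=False)
    if vcf:
        write_vcf_genotypes(cohort.genotypes, genotypes_path)
    else:
        geno = cohort.genotypes.copy()
        geno.index.name = "snp_id"
        write_table(geno, genotypes_path, provenance)


def read_cohort(individuals_path, genotypes_path) -> TwinCohort:
    ind = read_individuals(individuals_path)
    gpath = Path(genotypes_path)
    if gpath.suffix == ".vcf":
        geno = read_vcf_genotypes(gpath)
    else:
        geno = read_dosage_table(gpath)
    return TwinCohort(individuals=ind, genotypes=geno)
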