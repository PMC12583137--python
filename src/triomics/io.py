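"""File I/O: VCF genotypes, TSV tables, and scan/result serialization.

Genotypes are read with cyvcf2 (VCF 4.2, biallelic records; GT converted to
alt-allele dosage, DS used directly when present). All derived tables are
TSV for diffability: floats at 6 significant digits, p-values at 4
significant digits in scientific notation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .association import ScanTable
from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .exceptions import AlignmentError, ValidationError

log = logging.getLogger(__name__)

P_COLUMNS = {"p", "p_snp", "p_bmi", "p_meta", "p_snp_bmi", "p1", "p2", "p3", "p4",
             "p_omnibus"}


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into a dosage matrix; multi-allelic records are skipped
    with a warning; missing GT calls become NaN for that sample."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta = {}, []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("read_vcf: skipping multi-allelic record %s:%d", var.CHROM, var.POS)
            continue
        snp_id = var.ID or f"{var.CHROM}_{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())  # (n, ploidy+1); last col = phasing
            alleles = gt[:, :-1]
            missing = (alleles < 0).any(axis=1)
            dose = alleles.clip(min=0).sum(axis=1).astype(float)
            if missing.any():
                log.warning(
                    "read_vcf: %d missing call(s) at %s dropped per-SNP", missing.sum(), snp_id
                )
                dose[missing] = np.nan
        cols[snp_id] = dose
        alt = var.ALT[0]
        af = np.nanmean(dose) / 2.0
        meta.append((snp_id, str(var.CHROM), int(var.POS), var.REF, alt,
                     float(min(af, 1.0 - af))))
    if not samples:
        raise ValidationError("read_vcf: VCF has no samples")
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    snp_meta = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "ref", "alt", "maf"]
    ).set_index("snp_id")
    return GenotypeMatrix(dosages=dosages, snp_meta=snp_meta)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write unphased biallelic GT records, positions non-decreasing per
    chromosome."""
    meta = G.snp_meta.sort_values(["chrom", "pos"], kind="mergesort")
    samples = G.sample_ids
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp_id, row in meta.iterrows():
            doses = G.dosages[snp_id]
            gts = "\t".join(
                gt_map[int(d)] if d == d else "./." for d in doses
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_expression(expr_path, annotation_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t").set_index("sample_id")
    ann = pd.read_csv(annotation_path, sep="\t").set_index("transcript_id")
    if list(values.columns) != list(ann.index):
        ann = ann.reindex(values.columns)
        if ann["chrom"].isna().any():
            raise ValidationError("read_expression: annotation missing transcripts")
    return ExpressionMatrix(values=values, transcript_meta=ann)


def read_phenotypes(path) -> PhenotypeTable:
    table = pd.read_csv(path, sep="\t").set_index("sample_id")
    if table.index.duplicated().any():
        raise ValidationError("read_phenotypes: duplicated sample id")
    return PhenotypeTable(table=table)


def read_index_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValidationError(f"read_index_snps: missing columns {sorted(missing)}")
    return df


def read_tables(
    vcf_path, expression_path, annotation_path, phenotype_path, index_snps_path
):
    """Read all inputs and restrict every table to the common samples.

    Sample alignment is enforced by intersecting sample ids (keeping the
    genotype file's order); the final analysis set size is logged. Zero
    overlap is fatal.
    """
    G = read_vcf(vcf_path)
    E = read_expression(expression_path, annotation_path)
    P = read_phenotypes(phenotype_path)
    idx = read_index_snps(index_snps_path)

    common = [s for s in G.sample_ids if s in set(E.sample_ids) & set(P.sample_ids)]
    if not common:
        raise AlignmentError("read_tables: no overlapping samples across sources")
    dropped = (len(G.sample_ids) - len(common), len(E.sample_ids) - len(common),
               len(P.sample_ids) - len(common))
    if any(dropped):
        log.info("read_tables: dropped samples (genotypes=%d, expression=%d, "
                 "phenotypes=%d); analysis restricted to %d subjects",
                 *dropped, len(common))
    else:
        log.info("read_tables: %d subjects in the analysis set", len(common))
    G = GenotypeMatrix(dosages=G.dosages.loc[common], snp_meta=G.snp_meta)
    E = ExpressionMatrix(values=E.values.loc[common], transcript_meta=E.transcript_meta)
    P = PhenotypeTable(table=P.table.loc[common])
    return G, E, P, idx


def _formatted(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            fmt = "%.4e" if col in P_COLUMNS else "%.6g"
            out[col] = out[col].map(lambda v, f=fmt: f % v if v == v else "NA")
    return out


def write_table(df: pd.DataFrame, path) -> None:
    _formatted(df).to_csv(path, sep="\t", index=False)


def write_scan(scan: ScanTable, path) -> None:
    write_table(scan.results, path)


def read_scan(path, role: str, covariates=("age", "sex", "cohort")) -> ScanTable:
    df = pd.read_csv(path, sep="\t")
    return ScanTable(results=df, role=role, covariates=tuple(covariates))
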