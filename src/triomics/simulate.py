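"""Synthetic cohort generation.

Emulates the statistical structure the downstream analysis assumes: biallelic
SNPs in LD blocks around index variants, linear cis-eQTL effects on
transcripts within 1 Mb, covariate effects (age, sex, cohort), and a
BMI-like trait generated under a causal-mediation, reverse-causation,
pleiotropic, or null scenario. Samples are unrelated and genotypes are in
Hardy-Weinberg equilibrium, so ordinary least squares is the correct
downstream model.

LD is produced at the haplotype level by probabilistic copying: each proxy
haplotype allele copies the index allele with probability ``s = sqrt(r2)``
and is otherwise an independent Bernoulli(maf) draw, giving an allele
correlation of exactly ``s`` and hence an expected dosage r-squared equal to
the target.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    LocusSpec,
    PhenotypeTable,
    ScenarioSpec,
    TruthRecord,
    check_sample_alignment,
    truth_frame,
)
from .exceptions import AlignmentError, ValidationError

log = logging.getLogger(__name__)

TRAIT_INTERCEPT = 27.0  # kg/m^2-like baseline
TRAIT_SCALE = 4.5  # multiplies the latent (SD-unit) trait; cosmetic, inference-invariant


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(
    n_samples: int, loci: Sequence[LocusSpec], seed: int
) -> GenotypeMatrix:
    """Draw unphased dosages for index SNPs and their LD proxies.

    Index haplotype alleles are Bernoulli(maf) per haplotype (two per
    sample); each proxy haplotype copies the index allele with probability
    ``sqrt(target r2)``. Dosage is the sum of the two haplotypes.
    """
    if n_samples < 2:
        raise ValidationError(f"n_samples must be >= 2, got {n_samples}")
    rng = np.random.default_rng(seed)
    cols, meta = {}, []
    for locus in loci:
        maf = locus.index_maf
        hap = rng.random((n_samples, 2)) < maf  # index haplotypes
        idx_id = f"{locus.locus_id}_idx"
        cols[idx_id] = hap.sum(axis=1).astype(np.int64)
        meta.append((idx_id, locus.chrom, locus.index_pos, "A", "G", maf))
        for j, (r2, off) in enumerate(zip(locus.proxy_r2_targets, locus.proxy_offsets)):
            s = np.sqrt(r2)
            copy = rng.random((n_samples, 2)) < s
            fresh = rng.random((n_samples, 2)) < maf
            proxy = np.where(copy, hap, fresh)
            pid = f"{locus.locus_id}_px{j + 1}"
            cols[pid] = proxy.sum(axis=1).astype(np.int64)
            meta.append((pid, locus.chrom, locus.index_pos + off, "A", "G", maf))
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    dosages = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    snp_meta = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "ref", "alt", "maf"]
    ).set_index("snp_id")
    return GenotypeMatrix(dosages=dosages, snp_meta=snp_meta)


def simulate_covariates(n_samples: int, seed: int) -> pd.DataFrame:
    """age ~ Normal(55, 10), sex ~ Bernoulli(0.55), cohort ~ Bernoulli(0.5)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(55.0, 10.0, n_samples),
            "sex": (rng.random(n_samples) < 0.55).astype(int),
            "cohort": (rng.random(n_samples) < 0.5).astype(int),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample_id"),
    )


def _covariate_term(covars: pd.DataFrame, effects) -> np.ndarray:
    out = np.zeros(len(covars))
    for name, eff in effects.items():
        if name not in covars.columns:
            raise ValidationError(f"covariate effect on unknown covariate {name!r}")
        out += eff * covars[name].to_numpy(dtype=float)
    return out


def make_locus_truth(
    loci: Sequence[LocusSpec],
    scenario: ScenarioSpec,
    n_null_per_locus: int = 9,
) -> list[TruthRecord]:
    """One affected transcript plus ``n_null_per_locus`` null transcripts per
    locus, all assigned to the locus index SNP (null ones with zero effects)."""
    records = []
    for locus in loci:
        idx_id = f"{locus.locus_id}_idx"
        if scenario.kind != "null":
            records.append(
                TruthRecord(
                    snp_id=idx_id,
                    transcript_id=f"{locus.locus_id}_tx0",
                    kind=scenario.kind,
                    beta_lg=scenario.beta_lg,
                    beta_gt=scenario.beta_gt,
                    beta_lt_direct=scenario.beta_lt_direct,
                )
            )
            start = 1
        else:
            start = 0
        for j in range(start, start + n_null_per_locus + (1 - start)):
            records.append(
                TruthRecord(snp_id=idx_id, transcript_id=f"{locus.locus_id}_tx{j}", kind="null")
            )
    return records


def _transcript_meta(truth: Sequence[TruthRecord], G: GenotypeMatrix) -> pd.DataFrame:
    """Place each transcript near its SNP (alternating offsets within the cis
    window) so cis-window selection has structure to act on."""
    rows = []
    per_snp_count: dict[str, int] = {}
    for t in truth:
        k = per_snp_count.get(t.snp_id, 0)
        per_snp_count[t.snp_id] = k + 1
        snp = G.snp_meta.loc[t.snp_id]
        offset = (k // 2 + 1) * 60_000 * (1 if k % 2 == 0 else -1)
        rows.append(
            (
                t.transcript_id,
                f"GENE_{t.transcript_id.upper()}",
                snp["chrom"],
                max(1, int(snp["pos"]) + offset),
            )
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_symbol", "chrom", "start"]
    ).set_index("transcript_id")


def simulate_expression(
    G: GenotypeMatrix,
    truth: Sequence[TruthRecord],
    pheno_covars: pd.DataFrame,
    scenario: ScenarioSpec,
    seed: int,
) -> ExpressionMatrix:
    """Linear generative model for expression.

    causal / pleiotropic / null kinds:
        expr = beta_LG * dosage + covariate effects + Normal(0, noise_sd_expr)
    reverse kind:
        expr = beta_GT * standardized trait + covariate effects + noise
        (the trait must already be present in ``pheno_covars['bmi']``).
    """
    if list(pheno_covars.index) != G.sample_ids:
        raise AlignmentError("pheno_covars sample ids do not match genotypes")
    ids = [t.transcript_id for t in truth]
    if len(set(ids)) != len(ids):
        raise ValidationError("truth: transcript_ids must be unique (one record per transcript)")
    rng = np.random.default_rng(seed)
    n = len(pheno_covars)
    cov_term = _covariate_term(pheno_covars, scenario.covariate_effects)
    cols = {}
    for t in truth:
        noise = rng.normal(0.0, scenario.noise_sd_expr, n)
        if t.kind == "reverse" and t.beta_gt != 0.0:
            if "bmi" not in pheno_covars.columns or pheno_covars["bmi"].isna().any():
                raise ValidationError("reverse scenario requires the trait to be simulated first")
            bmi = pheno_covars["bmi"].to_numpy(dtype=float)
            latent = (bmi - TRAIT_INTERCEPT) / TRAIT_SCALE  # back to SD units
            cols[t.transcript_id] = t.beta_gt * latent + cov_term + noise
        else:
            dose = G.dosages[t.snp_id].to_numpy(dtype=float)
            cols[t.transcript_id] = t.beta_lg * dose + cov_term + noise
    values = pd.DataFrame(cols, index=pheno_covars.index)
    return ExpressionMatrix(values=values, transcript_meta=_transcript_meta(truth, G))


def simulate_trait(
    G: GenotypeMatrix,
    E: ExpressionMatrix | None,
    truth: Sequence[TruthRecord],
    scenario: ScenarioSpec,
    seed: int,
    covariates: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """Generate the trait (and, if not supplied, the covariates).

    causal:      trait = sum over mediators of beta_GT * expression + covars + noise
    pleiotropic: trait = sum of beta_LT_direct * dosage + covars + noise
    reverse:     trait = sum of beta_LT_direct * dosage + covars + noise
                 (expression is then derived from the trait downstream)
    null:        covars + noise only.
    The latent SD-unit trait is affinely mapped to a BMI-like scale
    (27 + 4.5 * latent), which leaves every downstream test statistic unchanged.
    """
    if scenario.kind not in ("causal", "reverse", "pleiotropic", "null"):
        raise ValidationError(f"unknown scenario kind {scenario.kind!r}")
    rng = np.random.default_rng(seed)
    n = len(G.dosages)
    if covariates is None:
        covariates = simulate_covariates(n, seed=int(rng.integers(2**31)))
    if list(covariates.index) != G.sample_ids:
        raise AlignmentError("covariate sample ids do not match genotypes")
    latent = _covariate_term(covariates, scenario.covariate_effects) + rng.normal(
        0.0, scenario.noise_sd_trait, n
    )
    if scenario.kind == "causal":
        if E is None:
            raise ValidationError("causal scenario requires expression to be simulated first")
        check_sample_alignment(G, E)
        for t in truth:
            if t.kind == "causal" and t.beta_gt != 0.0:
                latent += t.beta_gt * E.values[t.transcript_id].to_numpy(dtype=float)
    elif scenario.kind in ("pleiotropic", "reverse"):
        for t in truth:
            if t.kind == scenario.kind and t.beta_lt_direct != 0.0:
                latent += t.beta_lt_direct * G.dosages[t.snp_id].to_numpy(dtype=float)
    table = covariates.copy()
    table.insert(0, "bmi", TRAIT_INTERCEPT + TRAIT_SCALE * latent)
    return PhenotypeTable(table=table)


def simulate_cohort(
    n_samples: int,
    loci: Sequence[LocusSpec],
    scenario: ScenarioSpec,
    seed: int,
    truth: Sequence[TruthRecord] | None = None,
    n_null_per_locus: int = 9,
) -> Cohort:
    """Generate a full cohort under one scenario.

    Ordering follows the generative direction: genotypes and covariates
    first; for the reverse scenario the trait precedes expression, otherwise
    expression precedes the trait.
    """
    rngs = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rngs]
    G = simulate_genotypes(n_samples, loci, seeds[0])
    if truth is None:
        truth = make_locus_truth(loci, scenario, n_null_per_locus=n_null_per_locus)
    covars = simulate_covariates(n_samples, seeds[1])
    if scenario.kind == "reverse":
        P = simulate_trait(G, None, truth, scenario, seeds[3], covariates=covars)
        E = simulate_expression(G, truth, P.table, scenario, seeds[2])
    else:
        E = simulate_expression(G, truth, covars, scenario, seeds[2])
        P = simulate_trait(G, E, truth, scenario, seeds[3], covariates=covars)
    index_snps = (
        G.snp_meta.loc[[f"{loc.locus_id}_idx" for loc in loci], ["chrom", "pos"]]
        .reset_index()
        .rename(columns={"index": "snp_id"})
    )
    return Cohort(
        genotypes=G,
        expression=E,
        phenotypes=P,
        truth=truth_frame(truth),
        index_snps=index_snps,
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write VCF + TSVs + truth table; round-trips exactly through the readers."""
    from .io import write_vcf  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "annotation": out / "annotation.tsv",
        "index_snps": out / "index_snps.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    expr = cohort.expression.values.copy()
    expr.insert(0, "sample_id", expr.index)
    expr.to_csv(paths["expression"], sep="\t", index=False, float_format="%.15g")
    pheno = cohort.phenotypes.table.copy()
    pheno.insert(0, "sample_id", pheno.index)
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.15g")
    ann = cohort.expression.transcript_meta.reset_index()
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    cohort.index_snps.to_csv(paths["index_snps"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.15g")
    log.info("wrote cohort (%d samples, %d SNPs, %d transcripts) to %s",
             len(cohort.genotypes.dosages), len(cohort.genotypes.snp_ids),
             len(cohort.expression.transcript_ids), out)
    return paths
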