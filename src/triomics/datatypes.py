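"""Core data containers.

Genotypes, expression, and phenotypes are thin dataclass wrappers around
pandas objects so that sample alignment, identifier uniqueness, and value
domains can be validated once at construction and relied on downstream.
Simulation scenario descriptors (:class:`LocusSpec`, :class:`ScenarioSpec`,
:class:`TruthRecord`) carry the generative parameters of a synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError

SCENARIO_KINDS = ("causal", "reverse", "pleiotropic", "null")

#: default covariate effect sizes (per year of age / per unit indicator)
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {"age": 0.01, "sex": 0.2, "cohort": 0.1}


@dataclass
class LocusSpec:
    """One index variant and its LD proxies.

    ``proxy_r2_targets`` are the intended squared dosage correlations between
    each proxy and the index SNP; proxies are placed at ``index_pos + offset``.
    """

    locus_id: str
    chrom: str
    index_pos: int
    index_maf: float
    n_proxies: int = 0
    proxy_r2_targets: tuple = ()
    proxy_offsets: tuple = ()

    def __post_init__(self):
        if self.index_pos <= 0:
            raise ValidationError(f"LocusSpec.index_pos must be positive, got {self.index_pos}")
        if not (0.0 <= self.index_maf <= 0.5):
            raise ValidationError(
                f"LocusSpec.index_maf must lie in [0, 0.5], got {self.index_maf}"
            )
        if self.n_proxies < 0:
            raise ValidationError(f"LocusSpec.n_proxies must be >= 0, got {self.n_proxies}")
        self.proxy_r2_targets = tuple(self.proxy_r2_targets)
        self.proxy_offsets = tuple(self.proxy_offsets)
        if len(self.proxy_r2_targets) != self.n_proxies or len(self.proxy_offsets) != self.n_proxies:
            raise ValidationError(
                "LocusSpec: proxy_r2_targets and proxy_offsets must each have n_proxies entries"
            )
        for r2 in self.proxy_r2_targets:
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"LocusSpec.proxy_r2_targets entries must be in [0,1], got {r2}")
        for off in self.proxy_offsets:
            if self.index_pos + off <= 0:
                raise ValidationError("LocusSpec.proxy_offsets: proxy position must be positive")


@dataclass
class ScenarioSpec:
    """Generative scenario for a synthetic cohort.

    kind
        "causal": SNP -> expression -> trait (linear mediation);
        "reverse": SNP -> trait -> expression;
        "pleiotropic": SNP affects expression and trait through separate paths;
        "null": no genetic effects, covariates and noise only.
    beta_lg
        cis-eQTL effect, expression SD per alt allele.
    beta_gt
        expression -> trait effect (trait SD per expression SD); in the
        reverse scenario this is reused as the trait -> expression coefficient.
    beta_lt_direct
        direct SNP -> trait effect (pleiotropic path); in the reverse scenario
        this is the SNP -> trait coefficient that seeds the chain.
    """

    kind: str = "causal"
    beta_lg: float = 0.3
    beta_gt: float = 0.3
    beta_lt_direct: float = 0.0
    noise_sd_expr: float = 0.5
    noise_sd_trait: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValidationError(
                f"ScenarioSpec.kind must be one of {SCENARIO_KINDS}, got {self.kind!r}"
            )
        if self.noise_sd_expr <= 0:
            raise ValidationError("ScenarioSpec.noise_sd_expr must be > 0")
        if self.noise_sd_trait <= 0:
            raise ValidationError("ScenarioSpec.noise_sd_trait must be > 0")
        if self.kind == "null" and any(
            v != 0 for v in (self.beta_lg, self.beta_gt, self.beta_lt_direct)
        ):
            raise ValidationError("ScenarioSpec: kind='null' requires all effect sizes to be 0")


@dataclass
class TruthRecord:
    """Realized generative link for one transcript (exactly one per transcript)."""

    snp_id: str
    transcript_id: str
    kind: str
    beta_lg: float = 0.0
    beta_gt: float = 0.0
    beta_lt_direct: float = 0.0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValidationError(f"TruthRecord.kind must be one of {SCENARIO_KINDS}")


def truth_frame(records) -> pd.DataFrame:
    rows = [
        (t.snp_id, t.transcript_id, t.kind, t.beta_lg, t.beta_gt, t.beta_lt_direct)
        for t in records
    ]
    return pd.DataFrame(
        rows,
        columns=["snp_id", "transcript_id", "scenario", "beta_LG", "beta_GT", "beta_LT_direct"],
    )


@dataclass
class GenotypeMatrix:
    """samples x SNPs dosage table with per-SNP metadata.

    ``dosages``: DataFrame indexed by sample id, one column per SNP, values in
    {0, 1, 2} (NaN allowed only for missing calls read from external VCFs).
    ``snp_meta``: DataFrame indexed by snp_id with columns chrom, pos, ref,
    alt, maf.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self):
        if self.dosages.columns.duplicated().any():
            raise ValidationError("GenotypeMatrix: snp_ids must be unique")
        if not self.dosages.columns.equals(self.snp_meta.index):
            raise ValidationError("GenotypeMatrix: snp_meta index must match dosage columns")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("GenotypeMatrix: dosages must be in {0, 1, 2} (or NaN if missing)")

    @property
    def sample_ids(self):
        return list(self.dosages.index)

    @property
    def snp_ids(self):
        return list(self.dosages.columns)


@dataclass
class ExpressionMatrix:
    """samples x transcripts expression values plus transcript annotation.

    ``transcript_meta`` is indexed by transcript_id with columns gene_symbol,
    chrom, start. Sample order must match the cohort's GenotypeMatrix.
    """

    values: pd.DataFrame
    transcript_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValidationError("ExpressionMatrix: transcript_ids must be unique")
        if not self.values.columns.equals(self.transcript_meta.index):
            raise ValidationError(
                "ExpressionMatrix: transcript_meta index must match value columns"
            )

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def transcript_ids(self):
        return list(self.values.columns)


@dataclass
class PhenotypeTable:
    """Per-sample trait and covariates: bmi, age, sex (0/1), cohort (0/1)."""

    table: pd.DataFrame

    REQUIRED = ("bmi", "age", "sex", "cohort")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"PhenotypeTable missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValidationError("PhenotypeTable: one row per sample required")

    @property
    def sample_ids(self):
        return list(self.table.index)


def check_sample_alignment(*objs) -> None:
    """Raise AlignmentError unless all containers share identical sample order."""
    ids = None
    for o in objs:
        cur = o.sample_ids if hasattr(o, "sample_ids") else list(o.index)
        if ids is None:
            ids = cur
        elif cur != ids:
            raise AlignmentError("sample ids differ (or differ in order) across data sources")


@dataclass
class Cohort:
    """A complete synthetic cohort bundle."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    truth: pd.DataFrame
    index_snps: pd.DataFrame  # snp_id, chrom, pos

    def __post_init__(self):
        check_sample_alignment(self.genotypes, self.expression, self.phenotypes)
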