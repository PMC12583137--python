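"""End-to-end orchestration of the discovery and generalization pipeline.

Stages: (optionally) simulate a cohort -> select LD proxies and cis
transcripts -> three association scans -> correlated meta-analysis ->
five-criterion screen -> CIT (forward + reverse) -> Fisher generalization
(when tissue tables are provided). Every stage writes a TSV and the run
emits a manifest (config hash, version, per-stage row counts, seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import DEFAULT_COVARIATES, run_scan
from .cit import cit_for_prioritized, cit_results_frame
from .corrmeta import run_cma
from .datatypes import Cohort, LocusSpec, ScenarioSpec
from .exceptions import ValidationError
from .generalize import run_generalization
from .io import read_tables, write_table
from .prioritize import CriteriaConfig, apply_criteria, build_pairs, summarize_genes
from .simulate import simulate_cohort, write_cohort

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    n_samples: int = 1000
    loci: list = field(default_factory=list)  # list of LocusSpec
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    n_null_per_locus: int = 9


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    paths: dict | None = None  # vcf, expression, annotation, phenotypes, index_snps
    synthetic: SyntheticConfig | None = None
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    # None -> Bonferroni denominator tracks the number of transcripts actually scanned
    n_transcripts_tested: int | None = None
    cma_mode: str = "one_sided"
    cma_threshold_rule: str = "median"
    cma_method: str = "ml"
    cit_n_perm: int = 1000
    cit_n_bins: int = 10
    cit_scheme: str = "residual"
    covariate_names: tuple = DEFAULT_COVARIATES
    tissue_tables: dict = field(default_factory=dict)  # label -> tsv path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("config: a seed is mandatory for any stochastic step")
        syn = None
        if "synthetic" in raw:
            s = raw["synthetic"]
            sc = dict(s.get("scenario", {}))
            if sc.get("kind", "causal") is None:  # YAML reads bare `null` as None
                sc["kind"] = "null"
            syn = SyntheticConfig(
                n_samples=s.get("n_samples", 1000),
                loci=[LocusSpec(**d) for d in s.get("loci", [])],
                scenario=ScenarioSpec(**sc),
                n_null_per_locus=s.get("n_null_per_locus", 9),
            )
        crit = CriteriaConfig(**raw.get("criteria", {}))
        cma = raw.get("corrmeta", {})
        cit = raw.get("cit", {})
        return cls(
            seed=int(raw["seed"]),
            out_dir=raw.get("out_dir", "triomics_out"),
            paths=raw.get("paths"),
            synthetic=syn,
            criteria=crit,
            n_transcripts_tested=raw.get("n_transcripts_tested"),
            cma_mode=cma.get("mode", "one_sided"),
            cma_threshold_rule=cma.get("threshold_rule", "median"),
            cma_method=cma.get("method", "ml"),
            cit_n_perm=cit.get("n_perm", 1000),
            cit_n_bins=cit.get("n_bins", 10),
            cit_scheme=cit.get("scheme", "residual"),
            tissue_tables=raw.get("tissues", {}),
        )

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(config: PipelineConfig):
    if config.synthetic is not None:
        syn = config.synthetic
        cohort = simulate_cohort(
            syn.n_samples, syn.loci, syn.scenario, config.seed,
            n_null_per_locus=syn.n_null_per_locus,
        )
        return cohort
    if not config.paths:
        raise ValidationError("config: either a synthetic block or input paths are required")
    p = config.paths
    G, E, P, idx = read_tables(
        p["vcf"], p["expression"], p["annotation"], p["phenotypes"], p["index_snps"]
    )
    return Cohort(genotypes=G, expression=E, phenotypes=P,
                  truth=pd.DataFrame(), index_snps=idx)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    stage = "cohort"
    try:
        cohort = _load_cohort(config)
        if config.synthetic is not None:
            write_cohort(cohort, out / "cohort")
        counts["samples"] = len(cohort.phenotypes.table)

        stage = "pairs"
        pairs = build_pairs(
            cohort.genotypes, cohort.index_snps,
            cohort.expression.transcript_meta, config.criteria,
        )
        if not pairs:
            raise ValidationError("no candidate SNP-transcript pairs in the cis windows")
        counts["pairs"] = len(pairs)
        transcripts = sorted({t for _, t in pairs})
        snps = sorted({s for s, _ in pairs})

        stage = "association"
        snp_scan = run_scan("snp_transcript", cohort.genotypes, cohort.expression,
                            cohort.phenotypes, pairs, config.covariate_names)
        bmi_scan = run_scan("transcript_bmi", None, cohort.expression,
                            cohort.phenotypes, transcripts, config.covariate_names)
        snp_bmi_scan = run_scan("snp_bmi", cohort.genotypes, None,
                                cohort.phenotypes, snps, config.covariate_names)
        write_table(snp_scan.results, out / "scan_snp_transcript.tsv")
        write_table(bmi_scan.results, out / "scan_transcript_bmi.tsv")
        write_table(snp_bmi_scan.results, out / "scan_snp_bmi.tsv")
        counts["snp_transcript_results"] = len(snp_scan.results)

        stage = "corrmeta"
        meta = run_cma(snp_scan, bmi_scan, mode=config.cma_mode,
                       threshold_rule=config.cma_threshold_rule, method=config.cma_method)
        # row-count conservation: every joinable pair yields exactly one meta row
        assert len(meta) == len(snp_scan.results), "meta row count != joinable pair count"
        counts["meta_rows"] = len(meta)
        write_table(meta, out / "meta.tsv")

        stage = "prioritize"
        crit = config.criteria
        if config.n_transcripts_tested is not None:
            crit = dataclasses.replace(crit, n_transcripts_tested=config.n_transcripts_tested)
        elif config.synthetic is not None:
            crit = dataclasses.replace(crit, n_transcripts_tested=len(transcripts))
        triplets = apply_criteria(meta, snp_scan, bmi_scan, snp_bmi_scan, crit)
        counts["triplets"] = len(triplets)
        counts["passing_triplets"] = int(triplets["passed"].sum())
        write_table(triplets, out / "triplets.tsv")
        genes = summarize_genes(triplets, cohort.expression.transcript_meta)
        write_table(genes, out / "prioritized_genes.tsv")

        stage = "cit"
        if triplets["passed"].any():
            cit_res = cit_for_prioritized(
                triplets, snp_scan, cohort.genotypes, cohort.expression,
                cohort.phenotypes, config.covariate_names,
                n_perm=config.cit_n_perm, seed=config.seed, scheme=config.cit_scheme,
            )
            cit_df = cit_results_frame(cit_res)
        else:
            cit_df = cit_results_frame([])
        counts["cit_results"] = len(cit_df)
        write_table(cit_df, out / "cit.tsv")

        stage = "generalization"
        if config.tissue_tables:
            tables = {label: pd.read_csv(path, sep="\t")
                      for label, path in config.tissue_tables.items()}
            gen = run_generalization(triplets, tables)
            counts["generalization_records"] = len(gen)
            write_table(gen, out / "generalization.tsv")
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "row_counts": counts,
        "timestamp": pd.Timestamp.utcnow().isoformat(),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", counts)
    return out
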