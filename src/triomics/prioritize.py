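"""Pair construction and the five-criterion prioritization screen.

Candidate pairs are built from LD proxies of each index variant (squared
dosage correlation strictly greater than 0.8 by default, same chromosome)
and transcripts whose annotated start lies within 1 Mb of the index position
(inclusive boundary). A SNP-transcript-BMI triplet is prioritized when all
five strict inequalities hold:

    c1: P_meta < P_SNP          c2: P_meta < P_BMI
    c3: P_SNP < alpha / n_transcripts_tested
    c4: P_BMI < alpha / n_transcripts_tested
    c5: the SNP's own BMI association is nominally significant (p < 0.05)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import ScanTable
from .datatypes import GenotypeMatrix
from .exceptions import DegenerateInputError, IdLookupError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CriteriaConfig:
    alpha: float = 0.05
    n_transcripts_tested: int = 1408
    nominal_alpha: float = 0.05
    r2_threshold: float = 0.8
    cis_window_bp: int = 1_000_000

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.nominal_alpha < 1):
            raise ValidationError("CriteriaConfig: alpha and nominal_alpha must be in (0,1)")
        if self.n_transcripts_tested < 1:
            raise ValidationError("CriteriaConfig: n_transcripts_tested must be >= 1")
        if self.r2_threshold <= 0 or self.cis_window_bp <= 0:
            raise ValidationError("CriteriaConfig: thresholds must be positive")


def bonferroni_threshold(alpha: float, n: int) -> float:
    """alpha / n, exactly (not the rounded display value)."""
    if not (0 < alpha < 1):
        raise ValidationError(f"bonferroni_threshold: alpha must be in (0,1), got {alpha}")
    if n < 1:
        raise ValidationError(f"bonferroni_threshold: n must be >= 1, got {n}")
    return alpha / n


def select_proxies(G: GenotypeMatrix, index_snp_id: str, r2_threshold: float = 0.8):
    """SNPs on the index chromosome with squared dosage correlation strictly
    above ``r2_threshold`` with the index SNP (index always included; r^2 is
    sign-free, so negatively correlated proxies qualify)."""
    if index_snp_id not in G.dosages.columns:
        raise IdLookupError("snp", [index_snp_id])
    idx = G.dosages[index_snp_id].to_numpy(dtype=float)
    if np.nanstd(idx) == 0.0:
        raise DegenerateInputError(f"select_proxies: index SNP {index_snp_id!r} is constant")
    chrom = G.snp_meta.loc[index_snp_id, "chrom"]
    same_chrom = G.snp_meta.index[G.snp_meta["chrom"] == chrom]
    out = []
    for snp_id in same_chrom:
        if snp_id == index_snp_id:
            out.append(snp_id)
            continue
        other = G.dosages[snp_id].to_numpy(dtype=float)
        if np.nanstd(other) == 0.0:
            continue
        mask = np.isfinite(idx) & np.isfinite(other)
        r = np.corrcoef(idx[mask], other[mask])[0, 1]
        if r * r > r2_threshold:
            out.append(snp_id)
    return out


def select_cis_transcripts(
    index_chrom: str, index_pos: int, transcript_meta: pd.DataFrame,
    cis_window_bp: int = 1_000_000,
):
    """Transcripts on the index chromosome with |start - index_pos| <= window
    (inclusive boundary; the transcript start, not midpoint, defines distance)."""
    tm = transcript_meta
    mask = (tm["chrom"].astype(str) == str(index_chrom)) & (
        (tm["start"] - index_pos).abs() <= cis_window_bp
    )
    return list(tm.index[mask])


def build_pairs(
    G: GenotypeMatrix,
    index_snps: pd.DataFrame,
    transcript_meta: pd.DataFrame,
    config: CriteriaConfig,
):
    """(snp_id, transcript_id) candidates: LD proxies x cis transcripts per
    index variant, deduplicated in first-seen order."""
    seen, pairs = set(), []
    for _, row in index_snps.iterrows():
        proxies = select_proxies(G, row["snp_id"], config.r2_threshold)
        cis_tx = select_cis_transcripts(
            row["chrom"], int(row["pos"]), transcript_meta, config.cis_window_bp
        )
        for s in proxies:
            for t in cis_tx:
                if (s, t) not in seen:
                    seen.add((s, t))
                    pairs.append((s, t))
    return pairs


def apply_criteria(
    meta: pd.DataFrame,
    snp_scan: ScanTable,
    bmi_scan: ScanTable,
    snp_bmi_scan: ScanTable,
    config: CriteriaConfig,
) -> pd.DataFrame:
    """Evaluate the five criteria for every meta-analysis row.

    Returns one record per (snp_id, transcript_id) with boolean flags c1..c5
    and ``passed`` = their conjunction, sorted by p_meta ascending with ties
    broken by (snp_id, transcript_id). Rows whose SNP lacks a SNP-BMI result
    are unevaluable: they are excluded with a logged warning.
    """
    snp_p = snp_scan.results.rename(
        columns={"outcome_id": "transcript_id", "predictor_id": "snp_id", "p": "p_snp"}
    )[["snp_id", "transcript_id", "p_snp"]]
    bmi_p = bmi_scan.results.rename(
        columns={"outcome_id": "transcript_id", "p": "p_bmi"}
    )[["transcript_id", "p_bmi"]]
    sb_p = snp_bmi_scan.results.rename(
        columns={"predictor_id": "snp_id", "p": "p_snp_bmi"}
    )[["snp_id", "p_snp_bmi"]]

    df = (
        meta[["snp_id", "transcript_id", "p_meta"]]
        .merge(snp_p, on=["snp_id", "transcript_id"], how="left")
        .merge(bmi_p, on="transcript_id", how="left")
        .merge(sb_p, on="snp_id", how="left")
    )
    if df[["p_snp", "p_bmi"]].isna().any().any():
        raise ValidationError("apply_criteria: meta rows not joinable to both scans")
    n_missing = int(df["p_snp_bmi"].isna().sum())
    if n_missing:
        log.warning("apply_criteria: excluding %d record(s) with no SNP-BMI result", n_missing)
        df = df.dropna(subset=["p_snp_bmi"])

    bonf = bonferroni_threshold(config.alpha, config.n_transcripts_tested)
    df = df.assign(
        c1=df["p_meta"] < df["p_snp"],
        c2=df["p_meta"] < df["p_bmi"],
        c3=df["p_snp"] < bonf,
        c4=df["p_bmi"] < bonf,
        c5=df["p_snp_bmi"] < config.nominal_alpha,
    )
    df["passed"] = df[["c1", "c2", "c3", "c4", "c5"]].all(axis=1)
    df = df.sort_values(
        ["p_meta", "snp_id", "transcript_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df[
        ["snp_id", "transcript_id", "p_snp", "p_bmi", "p_meta", "p_snp_bmi",
         "c1", "c2", "c3", "c4", "c5", "passed"]
    ]


def pick_top_snp(
    transcript_id: str, snp_scan: ScanTable, snp_meta: pd.DataFrame | None = None
) -> str:
    """The transcript's most significant SNP (smallest p); exact-p ties break
    by smaller genomic position, then lexicographic id."""
    rows = snp_scan.results[snp_scan.results["outcome_id"] == transcript_id]
    if rows.empty:
        raise IdLookupError("transcript (no SNP associations)", [transcript_id])
    best_p = rows["p"].min()
    cand = rows[rows["p"] == best_p].copy()
    cand = cand.rename(columns={"predictor_id": "snp_id"})
    if snp_meta is not None:
        cand["pos"] = cand["snp_id"].map(snp_meta["pos"])
        cand = cand.sort_values(["pos", "snp_id"], kind="mergesort")
    else:
        cand = cand.sort_values("snp_id", kind="mergesort")
    return str(cand.iloc[0]["snp_id"])


def summarize_genes(triplets: pd.DataFrame, transcript_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary of passing triplets: gene, n_triplets, best p_meta."""
    passed = triplets[triplets["passed"]].copy()
    if passed.empty:
        return pd.DataFrame(columns=["gene_symbol", "n_triplets", "best_p_meta"])
    passed["gene_symbol"] = passed["transcript_id"].map(transcript_meta["gene_symbol"])
    out = (
        passed.groupby("gene_symbol")
        .agg(n_triplets=("p_meta", "size"), best_p_meta=("p_meta", "min"))
        .reset_index()
        .sort_values("best_p_meta", kind="mergesort")
        .reset_index(drop=True)
    )
    return out
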