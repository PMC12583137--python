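"""Pair construction and the five-criterion screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triomics.association import ScanTable
from triomics.datatypes import GenotypeMatrix
from triomics.exceptions import DegenerateInputError, IdLookupError, ValidationError
from triomics.prioritize import (
    CriteriaConfig,
    apply_criteria,
    bonferroni_threshold,
    pick_top_snp,
    select_cis_transcripts,
    select_proxies,
    summarize_genes,
)


def make_scan(role, rows):
    cols = ["role", "outcome_id", "predictor_id", "beta", "se", "t", "p", "n"]
    return ScanTable(results=pd.DataFrame(rows, columns=cols), role=role,
                     covariates=("age",))


class TestBonferroni:
    def test_published_denominator_displays_as_3_6e_minus_5(self):
        thr = bonferroni_threshold(0.05, 1408)
        assert thr == pytest.approx(3.5511e-5, rel=1e-4)
        assert f"{thr:.1e}" == "3.6e-05"

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.05, 5000, 1e-5)])
    def test_simple_arithmetic(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_threshold(1.5, 10)


def toy_genotypes():
    dosages = pd.DataFrame(
        {
            "idx": [0, 1, 2, 1],
            "dup": [0, 1, 2, 1],
            "neg": [2, 1, 0, 1],
            "far": [0, 0, 1, 2],
            "otherchrom": [0, 1, 2, 1],
        },
        index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
    )
    meta = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "1", "2"],
            "pos": [100, 200, 300, 400, 100],
            "ref": ["A"] * 5,
            "alt": ["G"] * 5,
            "maf": [0.3] * 5,
        },
        index=pd.Index(dosages.columns, name="snp_id"),
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=meta)


class TestProxySelection:
    def test_index_duplicate_and_sign_free_r2(self):
        got = select_proxies(toy_genotypes(), "idx", 0.8)
        # the exact duplicate and the perfectly anti-correlated SNP both pass;
        # r^2 is sign-free; the same-valued SNP on another chromosome does not
        assert got == ["idx", "dup", "neg"]

    def test_constant_index_rejected(self):
        G = toy_genotypes()
        G.dosages["idx"] = 1
        with pytest.raises(DegenerateInputError):
            select_proxies(G, "idx", 0.8)

    def test_unknown_index_listed(self):
        with pytest.raises(IdLookupError):
            select_proxies(toy_genotypes(), "missing", 0.8)


class TestCisWindow:
    meta = pd.DataFrame(
        {
            "gene_symbol": ["g0", "g1", "g2", "g3"],
            "chrom": ["1", "1", "1", "2"],
            "start": [5_000_000, 6_000_000, 6_000_001, 5_000_000],
        },
        index=pd.Index(["t0", "t1", "t2", "t3"], name="transcript_id"),
    )

    def test_boundary_is_inclusive_at_exactly_one_megabase(self):
        got = select_cis_transcripts("1", 5_000_000, self.meta, 1_000_000)
        assert got == ["t0", "t1"]  # distance 0 and exactly 1 Mb in; 1 Mb + 1 bp out

    def test_other_chromosome_never_cis(self):
        assert "t3" not in select_cis_transcripts("1", 5_000_000, self.meta)


def triplet_inputs(records):
    """records: (snp, tx, p_snp, p_bmi, p_meta, p_snp_bmi)"""
    meta = pd.DataFrame(
        [(r[0], r[1], r[4]) for r in records],
        columns=["snp_id", "transcript_id", "p_meta"],
    )
    snp = make_scan("snp_transcript",
                    [["snp_transcript", r[1], r[0], 0.1, 0.01, 5, r[2], 99]
                     for r in records])
    seen = {}
    bmi_rows, sb_rows = [], []
    for r in records:
        if r[1] not in seen:
            seen[r[1]] = True
            bmi_rows.append(["transcript_bmi", r[1], "BMI", 0.1, 0.01, 5, r[3], 99])
    seen = {}
    for r in records:
        if r[0] not in seen and r[5] is not None:
            seen[r[0]] = True
            sb_rows.append(["snp_bmi", "BMI", r[0], 0.1, 0.01, 5, r[5], 99])
    return meta, snp, make_scan("transcript_bmi", bmi_rows), make_scan("snp_bmi", sb_rows)


class TestApplyCriteria:
    config = CriteriaConfig(n_transcripts_tested=1408)

    def test_all_criteria_hold(self):
        meta, s, b, sb = triplet_inputs([("rs1", "t1", 1e-20, 1e-10, 1e-40, 0.01)])
        out = apply_criteria(meta, s, b, sb, self.config)
        assert bool(out["passed"].iloc[0])

    def test_fails_when_meta_not_stronger_than_snp(self):
        meta, s, b, sb = triplet_inputs([("rs1", "t1", 1e-30, 1e-10, 1e-20, 0.01)])
        out = apply_criteria(meta, s, b, sb, self.config)
        assert not bool(out["c1"].iloc[0]) and not bool(out["passed"].iloc[0])

    def test_survivors_match_brute_force_enumeration(self):
        records = [
            ("rs1", "t1", 1e-20, 1e-10, 1e-40, 0.01),
            ("rs2", "t2", 1e-6, 1e-10, 1e-12, 0.01),
            ("rs3", "t3", 1e-20, 1e-3, 1e-40, 0.01),
            ("rs4", "t4", 1e-20, 1e-10, 1e-40, 0.2),
            ("rs5", "t5", 1e-20, 1e-10, 1e-15, 0.01),
            ("rs6", "t6", 1e-8, 1e-9, 1e-20, 0.049),
        ]
        meta, s, b, sb = triplet_inputs(records)
        out = apply_criteria(meta, s, b, sb, self.config)
        bonf = 0.05 / 1408
        expected = {
            (r[0], r[1])
            for r in records
            if r[4] < r[2] and r[4] < r[3] and r[2] < bonf and r[3] < bonf and r[5] < 0.05
        }
        got = set(map(tuple, out.loc[out["passed"], ["snp_id", "transcript_id"]].values))
        assert got == expected

    def test_order_independent_and_sorted_by_p_meta(self, rng):
        records = [(f"rs{i}", f"t{i}", 1e-10, 1e-10, 10.0 ** -rng.integers(11, 40), 0.01)
                   for i in range(8)]
        meta, s, b, sb = triplet_inputs(records)
        out1 = apply_criteria(meta, s, b, sb, self.config)
        shuffled = meta.sample(frac=1, random_state=1).reset_index(drop=True)
        out2 = apply_criteria(shuffled, s, b, sb, self.config)
        pd.testing.assert_frame_equal(out1, out2)
        assert (np.diff(out1["p_meta"]) >= 0).all()

    def test_weakening_alpha_never_shrinks_pass_set(self):
        records = [("rs1", "t1", 1e-5, 1e-6, 1e-12, 0.04),
                   ("rs2", "t2", 1e-20, 1e-10, 1e-40, 0.01)]
        meta, s, b, sb = triplet_inputs(records)
        tight = apply_criteria(meta, s, b, sb, CriteriaConfig(alpha=0.05,
                                                              n_transcripts_tested=1408))
        loose = apply_criteria(meta, s, b, sb, CriteriaConfig(alpha=0.5,
                                                              n_transcripts_tested=1408))
        passed_tight = set(tight.loc[tight["passed"], "snp_id"])
        passed_loose = set(loose.loc[loose["passed"], "snp_id"])
        assert passed_tight <= passed_loose

    def test_missing_snp_bmi_record_excluded_with_warning(self, caplog):
        meta, s, b, sb = triplet_inputs([("rs1", "t1", 1e-20, 1e-10, 1e-40, 0.01),
                                         ("rs2", "t2", 1e-20, 1e-10, 1e-40, None)])
        with caplog.at_level("WARNING"):
            out = apply_criteria(meta, s, b, sb, self.config)
        assert len(out) == 1 and out["snp_id"].iloc[0] == "rs1"
        assert any("SNP-BMI" in m for m in caplog.messages)


class TestPickTopSnp:
    snp_meta = pd.DataFrame({"pos": [300, 100, 200]},
                            index=pd.Index(["a", "b", "c"], name="snp_id"))

    def test_minimum_p_wins(self):
        scan = make_scan("snp_transcript",
                         [["snp_transcript", "t1", "a", 0, 1, 0, 1e-8, 9],
                          ["snp_transcript", "t1", "b", 0, 1, 0, 1e-6, 9]])
        assert pick_top_snp("t1", scan, self.snp_meta) == "a"

    def test_exact_tie_breaks_by_position_then_id(self):
        scan = make_scan("snp_transcript",
                         [["snp_transcript", "t1", "a", 0, 1, 0, 1e-8, 9],
                          ["snp_transcript", "t1", "b", 0, 1, 0, 1e-8, 9]])
        assert pick_top_snp("t1", scan, self.snp_meta) == "b"  # pos 100 < 300
        assert pick_top_snp("t1", scan, None) == "a"  # lexicographic fallback

    def test_no_associations_is_an_error(self):
        scan = make_scan("snp_transcript",
                         [["snp_transcript", "t1", "a", 0, 1, 0, 1e-8, 9]])
        with pytest.raises(IdLookupError):
            pick_top_snp("t2", scan)


def test_summarize_genes_counts_and_best_p():
    trip = pd.DataFrame({
        "snp_id": ["a", "b", "c"], "transcript_id": ["t1", "t1", "t2"],
        "p_meta": [1e-10, 1e-8, 1e-5], "passed": [True, True, False],
    })
    meta = pd.DataFrame({"gene_symbol": ["G1", "G2"]},
                        index=pd.Index(["t1", "t2"], name="transcript_id"))
    out = summarize_genes(trip, meta)
    assert len(out) == 1
    assert out.iloc[0]["gene_symbol"] == "G1"
    assert out.iloc[0]["n_triplets"] == 2
    assert out.iloc[0]["best_p_meta"] == pytest.approx(1e-10)
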