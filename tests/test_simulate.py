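"""Synthetic-cohort generator: LD structure, generative paths, determinism."""

import numpy as np
import pandas as pd
import pytest

from triomics.datatypes import LocusSpec, ScenarioSpec, TruthRecord
from triomics.exceptions import AlignmentError, ValidationError
from triomics.simulate import (
    TRAIT_INTERCEPT,
    TRAIT_SCALE,
    make_locus_truth,
    simulate_cohort,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_trait,
    write_cohort,
)


def locus(maf=0.5, r2=(), offsets=None, locus_id="L1"):
    offsets = offsets if offsets is not None else tuple(10_000 * (i + 1) for i in range(len(r2)))
    return LocusSpec(
        locus_id=locus_id, chrom="1", index_pos=1_000_000, index_maf=maf,
        n_proxies=len(r2), proxy_r2_targets=tuple(r2), proxy_offsets=offsets,
    )


class TestGenotypes:
    def test_monomorphic_locus_gives_all_zero_dosage(self):
        G = simulate_genotypes(50, [locus(maf=0.0)], seed=1)
        assert (G.dosages["L1_idx"] == 0).all()

    def test_perfect_proxy_copies_index_column(self):
        G = simulate_genotypes(200, [locus(maf=0.3, r2=(1.0,))], seed=2)
        assert (G.dosages["L1_px1"] == G.dosages["L1_idx"]).all()

    def test_realized_r2_and_mean_dosage_match_targets(self):
        G = simulate_genotypes(5000, [locus(maf=0.5, r2=(0.81,))], seed=3)
        x = G.dosages["L1_idx"].to_numpy(float)
        y = G.dosages["L1_px1"].to_numpy(float)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert abs(r2 - 0.81) < 0.04
        assert abs(x.mean() - 1.0) < 0.05

    @pytest.mark.parametrize("maf", [0.1, 0.3, 0.5])
    def test_realized_maf_converges(self, maf):
        n = 2000
        G = simulate_genotypes(n, [locus(maf=maf)], seed=4)
        realized = G.dosages["L1_idx"].mean() / 2.0
        assert abs(realized - maf) < 3 * np.sqrt(maf * (1 - maf) / (2 * n))

    def test_same_seed_reproduces_dosages_bitwise(self):
        loci = [locus(maf=0.2, r2=(0.9, 0.85))]
        a = simulate_genotypes(300, loci, seed=5)
        b = simulate_genotypes(300, loci, seed=5)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)

    def test_invalid_parameters_raise_named_errors(self):
        with pytest.raises(ValidationError, match="index_maf"):
            LocusSpec("L", "1", 100, index_maf=0.7)
        with pytest.raises(ValidationError, match="n_samples"):
            simulate_genotypes(1, [locus()], seed=1)
        with pytest.raises(ValidationError, match="proxy"):
            LocusSpec("L", "1", 100, 0.3, n_proxies=2, proxy_r2_targets=(0.9,),
                      proxy_offsets=(10, 20))


class TestExpressionAndTrait:
    def test_noiseless_expression_is_affine_in_dosage(self):
        G = simulate_genotypes(100, [locus(maf=0.4)], seed=6)
        truth = [TruthRecord("L1_idx", "tx", "causal", beta_lg=1.0)]
        covars = simulate_covariates(100, seed=7)
        sc = ScenarioSpec(kind="causal", beta_lg=1.0, noise_sd_expr=1e-10,
                          covariate_effects={})
        E = simulate_expression(G, truth, covars, sc, seed=8)
        np.testing.assert_allclose(
            E.values["tx"].to_numpy(), G.dosages["L1_idx"].to_numpy(float), atol=1e-8
        )

    def test_null_effect_gives_no_dosage_correlation(self):
        G = simulate_genotypes(5000, [locus(maf=0.4)], seed=9)
        truth = [TruthRecord("L1_idx", "tx", "null")]
        covars = simulate_covariates(5000, seed=10)
        sc = ScenarioSpec(kind="null", beta_lg=0, beta_gt=0, covariate_effects={})
        E = simulate_expression(G, truth, covars, sc, seed=11)
        r = np.corrcoef(E.values["tx"], G.dosages["L1_idx"].astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_eqtl_effect_recovered_by_ols_within_3se(self):
        n, beta = 2000, 0.3
        G = simulate_genotypes(n, [locus(maf=0.3)], seed=12)
        truth = [TruthRecord("L1_idx", "tx", "causal", beta_lg=beta)]
        covars = simulate_covariates(n, seed=13)
        sc = ScenarioSpec(kind="causal", beta_lg=beta, noise_sd_expr=1.0,
                          covariate_effects={})
        E = simulate_expression(G, truth, covars, sc, seed=14)
        x = G.dosages["L1_idx"].to_numpy(float)
        y = E.values["tx"].to_numpy()
        X = np.column_stack([np.ones(n), x])
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ bhat
        se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(bhat[1] - beta) < 3 * se

    def test_causal_chain_implies_product_snp_trait_effect(self):
        n, b1, b2 = 1000, 0.3, 0.3
        sc = ScenarioSpec(kind="causal", beta_lg=b1, beta_gt=b2, noise_sd_expr=1.0,
                          noise_sd_trait=1.0, covariate_effects={})
        cohort = simulate_cohort(n, [locus(maf=0.3)], sc, seed=15, n_null_per_locus=0)
        x = cohort.genotypes.dosages["L1_idx"].to_numpy(float)
        # undo the cosmetic BMI scaling to work in latent SD units
        y = (cohort.phenotypes.table["bmi"].to_numpy() - TRAIT_INTERCEPT) / TRAIT_SCALE
        X = np.column_stack([np.ones(n), x])
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ bhat
        se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(bhat[1] - b1 * b2) < 3 * se

    def test_null_scenario_trait_independent_of_transcripts(self, null_cohort):
        bmi = null_cohort.phenotypes.table["bmi"].to_numpy()
        covars = null_cohort.phenotypes.table[["age", "sex", "cohort"]].to_numpy(float)
        X = np.column_stack([np.ones(len(bmi)), covars])
        bmi_r = bmi - X @ np.linalg.lstsq(X, bmi, rcond=None)[0]
        for tx in null_cohort.expression.transcript_ids[:5]:
            e = null_cohort.expression.values[tx].to_numpy()
            e_r = e - X @ np.linalg.lstsq(X, e, rcond=None)[0]
            r = np.corrcoef(bmi_r, e_r)[0, 1]
            assert abs(r) < 4 / np.sqrt(len(bmi))

    def test_noiseless_trait_is_deterministic_given_mediator(self):
        G = simulate_genotypes(60, [locus(maf=0.4)], seed=16)
        truth = [TruthRecord("L1_idx", "tx", "causal", beta_lg=0.5, beta_gt=1.0)]
        covars = simulate_covariates(60, seed=17)
        sc = ScenarioSpec(kind="causal", beta_lg=0.5, beta_gt=1.0,
                          noise_sd_trait=1e-12, covariate_effects={})
        E = simulate_expression(G, truth, covars, sc, seed=18)
        P = simulate_trait(G, E, truth, sc, seed=19, covariates=covars)
        expected = TRAIT_INTERCEPT + TRAIT_SCALE * E.values["tx"].to_numpy()
        np.testing.assert_allclose(P.table["bmi"].to_numpy(), expected, atol=1e-6)

    def test_unknown_scenario_and_misalignment_rejected(self):
        G = simulate_genotypes(50, [locus()], seed=20)
        covars = simulate_covariates(40, seed=21)  # wrong length
        sc = ScenarioSpec(kind="causal")
        with pytest.raises(AlignmentError):
            simulate_expression(G, [TruthRecord("L1_idx", "tx", "causal")], covars, sc, 22)
        with pytest.raises(ValidationError):
            ScenarioSpec(kind="sideways")


class TestCohortRoundTrip:
    def test_write_read_round_trip_exact(self, tmp_path):
        sc = ScenarioSpec(kind="causal")
        cohort = simulate_cohort(10, [locus(maf=0.3, r2=(0.9, 0.85))], sc, seed=23,
                                 n_null_per_locus=1)
        paths = write_cohort(cohort, tmp_path / "cohort")
        from triomics.io import read_tables

        G, E, P, idx = read_tables(paths["vcf"], paths["expression"],
                                   paths["annotation"], paths["phenotypes"],
                                   paths["index_snps"])
        pd.testing.assert_frame_equal(
            G.dosages.astype(float), cohort.genotypes.dosages.astype(float),
            check_names=False,
        )
        np.testing.assert_allclose(E.values.to_numpy(),
                                   cohort.expression.values.to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(P.table["bmi"].to_numpy(),
                                   cohort.phenotypes.table["bmi"].to_numpy(), rtol=1e-12)

    def test_fixed_seed_writes_byte_identical_files(self, tmp_path):
        sc = ScenarioSpec(kind="causal")
        for d in ("a", "b"):
            cohort = simulate_cohort(15, [locus(maf=0.25, r2=(0.9,))], sc, seed=24)
            write_cohort(cohort, tmp_path / d)
        for name in ("genotypes.vcf", "expression.tsv", "phenotypes.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_empty_cohort_yields_valid_header_only_vcf(self, tmp_path):
        from triomics.datatypes import GenotypeMatrix
        from triomics.io import write_vcf

        G = GenotypeMatrix(
            dosages=pd.DataFrame(index=pd.Index(["S1", "S2"], name="sample_id")),
            snp_meta=pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "maf"]),
        )
        write_vcf(G, tmp_path / "empty.vcf")
        lines = (tmp_path / "empty.vcf").read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert lines[-1].startswith("#CHROM")

    def test_truth_table_covers_every_transcript_once(self, causal_cohort):
        assert causal_cohort.truth["transcript_id"].is_unique
        assert set(causal_cohort.truth["transcript_id"]) == set(
            causal_cohort.expression.transcript_ids
        )


def test_make_locus_truth_counts():
    loci = [locus(locus_id="A"), locus(locus_id="B")]
    records = make_locus_truth(loci, ScenarioSpec(kind="causal"), n_null_per_locus=9)
    assert len(records) == 20
    assert sum(r.kind == "causal" for r in records) == 2
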