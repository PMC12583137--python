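# Methods

## Scope and statistical surface

The package integrates two per-transcript association scans computed on the
same cohort — SNP → transcript (cis-eQTL) and transcript → trait — into a
single dependence-corrected evidence stream, screens the resulting
SNP–transcript–trait triplets, and probes mediation. All inference is
ordinary least squares on unrelated individuals: the synthetic cohorts are
generated without family structure (Hardy–Weinberg, independent samples),
so no mixed-model relatedness adjustment is needed or provided. A hook for
other adjustments exists implicitly: any pre-residualized outcome can be
passed to the scan functions in place of the raw one.

Both scans use the transcript as the outcome — dosage (0–2 alt-allele
count) or BMI is the predictor — with covariates age, sex, and cohort
indicator, classical homoskedastic variance, and two-sided p from the
Student-t with n − k degrees of freedom (at n > 200 the difference from the
normal is negligible, but small-n behavior is exact). Complete cases per
pair; n is recorded per result. A predictor whose residual variance after
projection on the covariates falls below 1e-12 is an error, not a NaN.

## Correlated meta-analysis

Evidence is mapped to the upper tail, z = Φ⁻¹(1 − p), so small p gives
large positive z and the combined P_meta = 1 − Φ(z_meta) is small for
strong joint evidence. (The alternative convention z = Φ⁻¹(p) would invert
the direction of every result; the signed mode z = sign·Φ⁻¹(1 − p/2) is
available when effect directions should be allowed to cancel, off by
default because the default treats each stream's significance as
one-directional evidence.) Quantiles are computed via the complementary
functions and are accurate for p down to ~1e-300.

The two streams share samples and the transcript, so their Z-scores are
dependent. One pooled ρ per scan pair is estimated from all (z_SNP, z_BMI)
pairs — a per-pair 2×2 table from a single observation is impossible, and a
pooled empirical-null estimate is the coherent reading of the framework.
Each stream is dichotomized at its own empirical median (default; a zero
threshold is available). The median rule makes the margins exactly
balanced, which stabilizes the thresholds when a minority of pairs carry
true signal; the tetrachoric correlation itself uses only quadrant
membership and is therefore much less sensitive to contamination from the
alternative than a Pearson correlation on the raw Z values (extreme
signal pairs shift a Pearson estimate arbitrarily; they move at most a few
counts between quadrants here).

Tetrachoric estimation: zero cells receive a +0.5 continuity correction;
thresholds are fixed from the corrected margins; ρ maximizes the quadrant
multinomial likelihood over [−0.999, 0.999] by bounded Brent search
(xatol 1e-8). Quadrant probabilities use the bivariate normal CDF evaluated
with the single-integral arcsin identity and adaptive quadrature (absolute
accuracy ~1e-12); the cosine-π closed form cos(π/(1 + √(ad/bc))) is
available as a fast alternative. On symmetric zero-threshold tables the
MLE has the closed form sin(2π(P₁₁ − ¼)), which the estimator reproduces to
<1e-6; on arbitrary tables it matches a brute-force grid search (step 1e-4,
independent fixed-order Gauss–Legendre evaluation of the same CDF identity)
to <2e-4.

Combination: z_meta = (z_SNP + z_BMI)/√(2 + 2ρ). P_meta is monotonically
increasing in ρ for positive evidence (dependence always costs), equals the
equal-weight Stouffer combination exactly at ρ = 0, and ρ = −1 (degenerate
variance) is an error. Under a dependent null with ρ = 0.3 the naive ρ = 0
combination rejects at 1 − Φ(1.6449·√2/√2.6) ≈ 0.0745; the corrected
combination restores the nominal 5% — this calibration is recomputed by
the acceptance study.

## Prioritization

Candidate pairs: for each index variant, all same-chromosome SNPs with
squared dosage correlation strictly greater than 0.8 (r² is sign-free, so
perfectly anti-correlated proxies qualify), crossed with transcripts whose
annotated start lies within 1 Mb of the index position. The cis boundary is
inclusive at exactly 1 Mb; distance is measured to the transcript start as
annotated, strand ignored. Five strict inequalities define a pass (see
README); the Bonferroni denominator is configurable — 1408 is the shipped
default for reproducing the published threshold display (0.05/1408 shows
as 3.6 × 10⁻⁵ at two significant figures), while pipeline runs on synthetic
cohorts default to the number of transcripts actually scanned. The screen
is idempotent and order-independent; output is sorted by P_meta with
deterministic (snp, transcript) tie-breaks.

## Causal inference test

For each prioritized transcript, the most significant SNP from its
SNP-transcript associations is used (LD proxies are near-duplicates;
including several would only add multicollinearity). Exact-p ties break by
genomic position, then id.

Covariates are projected out of L (dosage), G (mediator), T (outcome) once
up front. By Frisch–Waugh this is exact for the three F-test components
when the lost degrees of freedom are carried over (they are); it is an
approximation only inside the permutation component, where refitting
covariates in every permutation would multiply the cost for no measurable
change at the default covariate count.

Components (forward direction; reverse swaps G and T):

1. L associated with T (F-test of L in T ~ L);
2. L associated with G given T (F for L in G ~ L + T);
3. G associated with T given L (F for G in T ~ G + L);
4. equivalence-style conditional-independence component: observed F for L
   in T ~ L + G, compared against a permutation null constructed by
   reconstructing the mediator as G* = fitted(G ~ L) + permuted residuals.
   G* preserves the L–G relation but severs G–T, so under true mediation
   the permuted F is large (the L–T path is no longer explained away)
   while the observed F is small; p₄ = (1 + #{F_perm ≤ F_obs})/(n_perm + 1)
   is then small. p₄ has resolution 1/(n_perm + 1) and never equals 0.

The omnibus p is exactly max(p₁…p₄): an intersection-union test, which
rejects only when every component rejects and is conservative under the
composite null. A within-stratum permutation of L (quantile bins of G,
`scheme="strata"`, bin count configurable) is retained for comparison, but
note that under true mediation its permutation null coincides with the
observed distribution — both F's are central — so p₄ is uniform and the
scheme has essentially no power; the mediator-reconstruction scheme is the
default for that reason. Measured operating characteristics at β = 0.4,
n = 1000, 500 permutations (recomputed by the acceptance study): forward
power ≈ 0.9 on causal chains, ≈ 0 rejections under full independence, and
on reverse-causation data the forward test stays near 0 while the
reverse-direction test rejects in ≈ 0.9 of replicates.

Determinism: each (SNP, transcript, direction) test derives its seed from
the master seed and the pair key via a stable hash, so results are
reproducible and independent of evaluation order.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

* **Genotypes.** Index-SNP haplotype alleles are Bernoulli(maf), two per
  sample; each proxy haplotype copies the index allele with probability
  s = √(target r²), else draws fresh — allele correlation is exactly s, so
  expected dosage r² equals the target. No recombination maps, one LD block
  per locus. maf = 0 is allowed as a degenerate monomorphic case.
* **Covariates.** age ~ N(55, 10), sex ~ Bernoulli(0.55),
  cohort ~ Bernoulli(0.5); linear effects on expression and trait,
  configurable.
* **Expression and trait.** Linear generative paths per scenario: causal
  (L → G → T), pleiotropic (L → G and L → T separately), reverse
  (L → T → G; the trait is generated first and the transcript derives from
  it), null. The latent SD-unit trait is affinely mapped to a BMI-like
  scale (27 + 4.5·latent), which changes no test statistic. Every
  transcript has exactly one truth record; one affected plus nine null
  transcripts per locus by default.

Default calibration (chosen by power analysis when the generative scales
were otherwise open, and then fixed): maf 0.3, effect sizes 0.3 SD
(β_LG per allele, β_GT per expression SD), noise SDs 0.5 for both
expression and trait. At n = 1000 this places a single locus in the same
detectability regime that the original cohort-scale analyses occupy at
n ≈ 5600: the cis-eQTL explains ~13% of expression variance (strong but
realistic for a top cis signal), the mediated path explains ~1% of trait
variance, and — the binding constraints — the implied SNP→trait effect
(β_LG·β_GT ≈ 0.09) is detectable at nominal 0.05 (criterion 5), while the
two streams' Z-scores stay comparable in magnitude so the combined
statistic can beat both inputs (criteria 1–2). The CIT benchmark scenario
uses maf 0.5 with unit noise, matching the generator's own worked-example
convention for that component.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: family structure and cryptic relatedness,
population stratification, imputation uncertainty, RNA count distributions
(expression is Gaussian, not negative binomial), batch effects, missing
data, probe-level multiplicity, and trans effects. Results on synthetic
cohorts certify the statistical machinery, not robustness to those
artifacts.

## Numerical choices and degenerate inputs

* p-values are floored at the smallest positive double and capped at 1;
  a perfect fit reports the floor rather than 0.
* Fisher's method: X² = −2(ln p₁ + ln p₂) against χ²₄ (two studies → 4 df);
  p = 1 accepted, p = 0 a domain error. Symmetric and monotone by
  construction; combining with an uninformative partner (p₂ = 1) always
  yields a larger p than the informative input (4-df penalty).
* Tetrachoric ρ clipped at ±0.999; degenerate margins and constant streams
  are errors, as are constant predictors/mediators everywhere.
* TSV output: floats at 6 significant digits, p-values at 4 significant
  digits in scientific notation; the VCF writer emits sorted, unphased
  biallelic GT records.
* Problem sizes in the shipped studies (5000 null pairs; 50 random tables;
  100 CIT replicates at n = 1000 with 500 permutations; 20 end-to-end
  cohorts of n = 1000) were chosen so every study completes in seconds on
  one CPU while keeping Monte-Carlo error well inside the margins being
  asserted.

## Known limitations

* The pooled-ρ design assumes one common dependence level across pairs; a
  locus-specific dependence structure would be absorbed into the pooled
  estimate.
* The permutation component of the CIT inherits the usual caveats of
  residual-based permutation under heteroskedasticity.
* The generalization layer treats tissue-level inputs as independent of
  discovery (Fisher, not correlated meta-analysis), mirroring the sparse
  real-data setting it models; no effect-direction concordance is tested.
* Real-data ingestion supports uncompressed VCF with GT or DS; BGEN/PLINK
  binary formats are out of scope.
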