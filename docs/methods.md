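# Methods

This note documents the statistical model, the numerical choices and the
limits of what the packaged tests demonstrate.

## Model and estimators

All computation is on summary statistics. For variant j, the exposure
sample provides (β̂ₓⱼ, σₓⱼ) — the per-effect-allele association with the
exposure (here: genetically predicted serum testosterone) — and the
outcome sample provides (β̂ᵧⱼ, σᵧⱼ) on the log-odds scale. Under the
instrumental-variable assumptions (relevance, independence from
confounders, no pathway to the outcome other than the exposure), each
valid variant satisfies E[β̂ᵧⱼ] = θ·E[β̂ₓⱼ], with θ the causal log odds
ratio per exposure unit.

**Wald ratio.** θ̂ = β̂ᵧ/β̂ₓ. The default SE is the first-order delta
method σᵧ/|β̂ₓ| (treats β̂ₓ as fixed, standard in two-sample MR where the
samples are independent); the second-order option adds the
exposure-uncertainty term √(σᵧ²/β̂ₓ² + β̂ᵧ²σₓ²/β̂ₓ⁴) and is never
smaller. β̂ₓ = 0 is an error (undefined ratio), not a silent NaN.

**IVW.** Ratios pooled with first-order weights wⱼ = β̂ₓⱼ²/σᵧⱼ², which is
algebraically identical to weighted least squares of β̂ᵧ on β̂ₓ through
the origin with weights 1/σᵧⱼ² — the test suite asserts the two routes
agree to 1e−10 against an independently coded regression. Fixed-effects
SE (Σwⱼ)^−1/2 is the default; the multiplicative random-effects option
scales it by max(1, √(Q/(J−1))) with Q Cochran's statistic, so it never
deflates. With J = 1 IVW reduces exactly to the ratio.

**Correlated-variant IVW.** When instrument variants are in LD, the GLS
form uses Ω = R ∘ σᵧσᵧᵀ (R the signed LD correlation matrix):
θ̂ = (βₓᵀΩ⁻¹βᵧ)/(βₓᵀΩ⁻¹βₓ), SE = (βₓᵀΩ⁻¹βₓ)^−1/2, solved by Cholesky
factorization. A singular Ω (duplicate variants) raises an error
suggesting a ridge term, which is added as ridge·diag(Ω). This estimator
is strictly opt-in: the headline analysis prunes to low-LD variants and
treats them as independent, so correlation modelling is never applied
silently.

**Weighted median.** Ratios sorted ascending with normalized weights wⱼ;
the estimate interpolates θ at cumulative midpoint weight
sⱼ = Σₖ≤ⱼwₖ − wⱼ/2 = 0.5, clamping outside [s₁, s_J]. This estimator is
consistent when valid instruments carry at least half the total weight.
The SE is the standard deviation over n_boot (default 1000) parametric
bootstrap replicates drawing β̂ₓⱼ ~ N(β̂ₓⱼ, σₓⱼ) and β̂ᵧⱼ ~ N(β̂ᵧⱼ, σᵧⱼ);
the seed is a required argument — there is no silent nondeterminism
anywhere in the package. Fewer than 3 variants is an error.

**MR-Egger.** Pairs are first oriented so β̂ₓⱼ ≥ 0 (both signs flipped
together; the regression is not invariant to per-variant reorientation,
and this is the conventional choice), then β̂ᵧ is regressed on β̂ₓ with a
free intercept and weights 1/σᵧⱼ². The slope estimates θ under the
InSIDE assumption; the intercept estimates mean directional pleiotropy
per variant. SEs carry the multiplicative overdispersion factor
max(1, √(RSS_w/(J−2))). p-values use the standard normal by default, with
a t(J−2) reference available by flag; under the simulation's correctly
specified weights the floored scale makes the normal-reference intercept
test mildly conservative, which the type-I-error study below confirms
(observed level slightly under 5%, within [0.03, 0.07]).

**Reporting.** 95% CIs use the exact 0.975 normal quantile
(1.959963984…), not 1.96. Odds-scale columns are exact exponentials of
the log-scale values. Display formatting renders ORs/estimates/SEs to 3
decimals and floors p-values at "<0.001"; significance is flagged at raw
two-sided p < 0.05 with no multiple-testing correction (the report's
`n_tests` column lets readers apply their own), matching the analysis
design the package reproduces.

## Harmonization

Matching is by rsid (positions are metadata only — the outcome sources
are rsid-keyed and no genome build is asserted). Outcome records are
aligned to the exposure effect allele: identical allele pairs are kept,
swapped pairs flip the outcome beta, strand-complement pairs are
complemented first. Palindromic variants (A/T, C/G) are dropped by
default since strand cannot be inferred from alleles, and no allele
frequencies are available in the packaged instruments to resolve them;
`palindromic_policy="keep"` assumes both tables report the same strand.
Unmatched or irreconcilable records are dropped with per-rsid reason
codes; an instrument that loses every variant raises rather than
returning an empty object. Harmonization is idempotent and invariant to
wholesale reorientation of the outcome table, and both properties are
asserted as tests.

## Instrument selection

Greedy p-value-ranked stepwise pruning: select the remaining candidate
with the smallest p-value, remove every remaining candidate with
r² strictly greater than the threshold (default 0.40) against it, repeat.
"Strictly greater" follows the procedure's definition of LD as r² above
the threshold; pairs at exactly the threshold are retained. Ties on
p-value break by lexicographic rsid so results are deterministic and
input-order invariant. The implementation is verified against a
brute-force oracle on random instances. Single-variant instruments bypass
selection (the *JMJD1C* instrument is pre-specified). The pipeline prunes
once on the exposure side; per-outcome re-pruning after harmonization
losses is available behind `reprune_per_outcome` but off by default.

## Synthetic data generator

`simulate_two_sample` draws summary statistics directly at the summary
level: MAF pⱼ ~ U(0.05, 0.5), true exposure effect γⱼ (default magnitude
U(0.03, 0.18), matching the packaged instruments' effect sizes),
σₓⱼ = (2pⱼ(1−pⱼ)·n_exposure)^−1/2, σᵧⱼ analogous, β̂ₓⱼ ~ N(γⱼ, σₓⱼ),
β̂ᵧⱼ ~ N(θγⱼ + αⱼ, σᵧⱼ). Pleiotropy αⱼ is zero for valid variants and
normal with mean 0 (balanced) or mean `pleiotropy_mean` (directional) for
a configured fraction of variants, chosen at random. Default sample sizes
are n_exposure = 3225 (the size of the cohort behind the packaged
instruments) and n_outcome = 100 000 (the order of the disease GWAS
emulated). Optional LD blocks correlate the sampling noise within blocks.
Alleles are assigned non-palindromic and orientation-consistent, so the
generator also exercises harmonization trivially; `simulate_ld_candidates`
builds block-structured candidate sets whose correct pruning outcome is
known by construction.

What the generator does **not** emulate: individual-level genotypes,
case/control ascertainment and the binary-trait scale of the outcome
betas (effects are interpreted as log-odds directly; the estimator
algebra is identical), winner's curse in instrument discovery, sample
overlap between the two samples, and allele-frequency mismatch between
studies. Passing recovery tests therefore demonstrates the estimators'
correctness and calibration under clean two-sample sampling, not
robustness to those real-data pathologies.

## Validation studies and problem sizes

The simulation studies in the acceptance tests use a 20-variant
instrument with θ = 0.2, n_outcome = 10⁵, and n_exposure = 2×10⁵ — a
strong-instrument regime chosen so that weak-instrument bias does not
confound what each study measures. Problem sizes (500 replicates for
recovery, 1000 for the type-I-error study, bootstrap 200 within
replicates) keep each study's Monte-Carlo SE small relative to its
assertion band while the whole suite runs in seconds.

* With valid instruments, IVW and weighted-median replicate means recover
  θ and the Egger intercept mean recovers 0, each within 3 Monte-Carlo
  SEs.
* With 40% of variants carrying directional pleiotropy (mean 0.05), the
  weighted median's mean stays within 0.05 — the injected pleiotropy
  magnitude, fixed in advance as the tolerance — of θ while fixed-effects
  IVW is biased well beyond it. The weighted median's guarantee is
  conditional on valid variants holding > 50% of the weight; with only 20
  variants that precondition fails by chance in a minority of replicates,
  so the assertion conditions on it (both estimators compared on the same
  replicates). Unconditionally the contrast still holds qualitatively
  (median bias ≈ 0.06 versus IVW ≈ 0.17).
* With every variant pleiotropic (mean 0.05), the Egger intercept mean
  recovers 0.05 within 3 Monte-Carlo SEs.
* Under the null, the Egger intercept test's rejection rate at the 5%
  level lies in [0.03, 0.07] over 1000 replicates.

## Packaged data and its provenance

`data/jmjd1c_exposure.tsv` and `data/shbg_exposure.tsv` are the published
exposure instruments (beta, SE, p, alleles, positions as printed; 1-based
coordinates, no liftover). The per-outcome tables under
`data/synthetic_outcomes/` are **synthetic stand-ins**: the real outcome
GWAS are external consortium data without packaged accessions, so these
single-variant fixtures are derived by inverting the ratio formula on the
published per-outcome results. Running the estimator forward on them
reproduces the published single-variant rows at printed precision — a
round-trip consistency check on this package's arithmetic, **not** an
independent replication of the epidemiological findings.
`data/reported_results.tsv` records the published per-outcome numbers for
those consistency checks. Two of the published CIs (SHBG rheumatoid
arthritis and type 2 diabetes) are internally inconsistent with their own
tabulated SEs (the intervals imply SEs of ≈ 0.074 and ≈ 0.043 versus
tabulated 0.060 and 0.030); the consistency tests cover the four
self-consistent CIs and note the exclusion. Similarly, a few published
p-values are not derivable from the tabulated (estimate, SE) pairs —
tests assert estimate/SE/OR at printed precision and do not re-derive
those p-values.

## Known limitations

* No MR-PRESSO outlier removal, multivariable MR, Steiger filtering or
  bidirectional analysis.
* No proxy-variant lookup: a variant missing from the outcome table is
  dropped, and the per-outcome instrument is the post-harmonization
  intersection.
* No VCF input or remote GWAS-catalogue queries; tabular I/O is TSV only.
* LD is always an input (square labelled TSV or long triples); the
  package never estimates LD from genotypes.
* Palindromic variants cannot be rescued by allele frequency (EAF-based
  resolution is deliberately not implemented; the packaged instruments
  print no frequencies).
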