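# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument construction by greedy LD pruning, exposure/outcome allele
harmonization, causal estimation by the Wald ratio and inverse-variance
weighting, weighted-median and MR-Egger sensitivity analyses, and
odds-scale reporting — plus a seeded synthetic summary-statistic generator
so the whole pipeline is testable without downloading consortium data.

The package was built around a concrete application: estimating the causal
effect of serum testosterone on seven common diseases (type 2 diabetes,
gout, rheumatoid arthritis, depression, schizophrenia, bipolar disorder,
Alzheimer's disease) using two genetic instruments — a single variant at
the *JMJD1C* locus and a 20-variant instrument at the *SHBG* locus — and it
ships those published instruments as packaged data. Everything is, however,
generic: any rsid-keyed exposure and outcome association tables work.

## The method

MR uses genetic variants as instrumental variables. Because alleles are
randomized at conception, a variant associated with an exposure X provides
a confounding-free handle on X's causal effect θ on an outcome Y. In the
two-sample design, the variant–exposure associations (β̂ₓⱼ, σₓⱼ) and
variant–outcome associations (β̂ᵧⱼ, σᵧⱼ) come from different studies'
summary statistics.

* **Wald ratio** (single variant): θ̂ = β̂ᵧ/β̂ₓ, with first-order
  delta-method SE σᵧ/|β̂ₓ| (second-order available).
* **IVW** (J variants): pool the ratios θ̂ⱼ with weights
  wⱼ = β̂ₓⱼ²/σᵧⱼ²; θ̂ = Σwⱼθ̂ⱼ/Σwⱼ, SE = (Σwⱼ)^−1/2 — equivalently the
  weighted regression of β̂ᵧ on β̂ₓ through the origin. Fixed effects by
  default; a multiplicative random-effects SE inflation
  max(1, √(Q/(J−1))) is available, as is a GLS variant for correlated
  variants using a signed LD matrix.
* **Weighted median**: the weighted 50th percentile of the θ̂ⱼ, consistent
  when valid instruments carry ≥ 50% of the weight; SE by seeded
  parametric bootstrap.
* **MR-Egger**: weighted regression of β̂ᵧ on β̂ₓ with a free intercept
  (after orienting β̂ₓ ≥ 0); the slope is a pleiotropy-robust causal
  estimate and a nonzero intercept indicates directional pleiotropy.

Estimates against disease outcomes are log odds ratios; every result is
reported with the exact-quantile 95% CI, a two-sided normal p-value and
the exponentiated odds-scale equivalents.

Instruments are built by greedy p-value-ranked stepwise LD pruning: pick
the remaining candidate with the smallest p-value, discard everything with
r² > 0.40 against it (threshold configurable, strict inequality), repeat.

## Worked example

The packaged single-variant *JMJD1C* instrument (rs10822184,
β̂ₓ = −0.058, σₓ = 0.01) against the packaged gout outcome stand-in
(β̂ᵧ = 0.0439, σᵧ = 0.0128 — a synthetic fixture derived from the
published result, see `mrkit.datasets`):

```python
import mrkit
from mrkit import datasets

exposure = datasets.load_exposure_instrument("jmjd1c")
outcome = datasets.load_synthetic_outcome("gout")
instrument = mrkit.harmonize(exposure, outcome)        # allele alignment
v = instrument.variants[0]
est = mrkit.ratio_estimate(v.beta_x, v.se_x, v.beta_y, v.se_y)
row = mrkit.to_report_row(est, "gout", "JMJD1C")
print(f"{row['locus']} -> {row['outcome']}: OR {row['odds_ratio']} "
      f"{row['or_95ci']}, estimate (se) {row['estimate_se']}, p {row['pvalue']}")
```

prints

```
JMJD1C -> gout: OR 0.469 (0.304, 0.723), estimate (se) -0.757 (0.221), p 0.001
```

i.e. each unit of genetically predicted testosterone multiplies the odds
of gout by 0.469 (95% CI 0.304–0.723): higher testosterone is protective
for gout, p = 0.001 — the published single-variant result.

### Pipeline from the shell

A YAML config drives the full analysis (`mrkit run`), and `mrkit simulate`
generates synthetic data with known truth:

```yaml
# analysis.yaml
seed: 7
n_boot: 1000
methods: [ivw, weighted_median, egger]
loci:
  - label: SIM
    exposure: exposure.tsv
    ld: ld.tsv            # omit to skip pruning (pre-pruned instrument)
    r2_threshold: 0.4
outcomes:
  - label: disease
    path: outcome.tsv
output:
  report: report.tsv
  run_summary: summary.tsv
```

```sh
mrkit run --config analysis.yaml
mrkit report --report report.tsv
```

On a simulated 20-variant locus (true θ = 0.2, 10 LD blocks pruned to 10
independent variants) this prints:

```
locus  outcome  method           n_variants  odds_ratio  or_95ci         estimate_se     ci_95           pvalue  significant ...
SIM    disease  ivw              10          1.195       (1.169, 1.222)  0.178 (0.011)   (0.156, 0.201)  <0.001  True
SIM    disease  weighted_median  10          1.172       (1.124, 1.222)  0.159 (0.021)   (0.117, 0.201)  <0.001  True
SIM    disease  egger_slope      10          1.111       (1.020, 1.211)  0.105 (0.044)   (0.020, 0.191)  0.016   True
```

All three estimators bracket the true log-odds effect 0.2; the Egger
intercept (0.011, p = 0.081) correctly finds no directional pleiotropy.
Single-variant loci get the ratio estimate only — the sensitivity analyses
need at least three variants and are skipped with a logged note.

Other subcommands: `mrkit prune` (stepwise LD selection of an association
table) and `mrkit simulate` (synthetic two-sample summary statistics; see
`mrkit.simulate.SimulationConfig` for the generative model).

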