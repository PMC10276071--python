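# Methods

## Model and assumptions

The package estimates the effect of pharmacologically lowering blood
glucose — proxied by cis variants in the gene encoding a drug's target
protein — on a binary disease outcome, from two independent GWAS
summary-statistic sets (two-sample design, no sample overlap).  The
instrumental-variable assumptions are the usual three: the instruments are
associated with the exposure (relevance, checked via per-variant
F = (β̂/σ)² and a mean-F ≤ 10 weak-instrument flag), independent of
confounders, and affect the outcome only through the exposure (exclusion
restriction; relaxed by the Egger/median/mode estimators).  Restricting
instruments to a narrow cis window around the target gene is itself the
main pleiotropy defence: variants there plausibly act through the encoded
protein.

The causal parameter θ is the log-odds of the outcome per 1 mmol/L higher
glucose; reports rescale it to an odds ratio per 0.1 mmol/L *lower*
glucose (factor −0.1), the direction of pharmacological action.  The
factor is configurable because other exposures use other conventions — a
fasting-insulin exposure on a log scale is reported per 1 log-unit
decrement (factor −1).

## Instrument selection

Per drug class, in order:

1. **Window extraction** — gene span ± `window_bp` (default 2,500 bp),
   closed 1-based GRCh37 intervals; multi-gene targets (sulfonylureas:
   KCNJ11 + ABCC8) take the union of windows.
2. **FDR filter** — Benjamini–Hochberg within the extracted window, keep
   q < 0.05.  The adjustment set is per-window because that is the only
   set computable from a cis extract; a genome-wide adjustment would be
   more conservative.  A threshold of 1 disables the filter (q is capped
   at 1, so a strict comparison would otherwise drop q = 1 variants).
3. **Palindrome screen** — A/T and C/G variants are strand-ambiguous;
   admitted only when MAF < 0.3.  Missing frequency fails the screen.
4. **Greedy LD clumping** at r² < 0.001, ascending p, ties broken by
   position then rsid; clumping runs jointly across a multi-gene target's
   windows so correlated duplicates cannot enter via two genes.  The
   relaxed sensitivity run (r² < 0.1) is *nested*: its greedy scan is
   seeded with the strict run's retained set, which guarantees the
   sensitivity instruments are a superset of the primary ones.  Two
   independent greedy runs do not nest — a variant discarded only at the
   relaxed threshold can shelter a later variant that the strict run
   discards.
5. **Proxy lookup** — instruments absent from the outcome dataset are
   replaced by the best panel variant with r² > 0.8 that is present in
   the outcome (search restricted to the window plus 500 kb flanks; ties
   by distance then rsid).  The proxy substitutes fully: its own exposure
   association is used, so harmonization is a same-variant alignment; the
   panel's signed r decides the allele mapping when the index exposure
   effect is paired with a proxy outcome record directly.
6. **F statistics** and the weak-set flag.

Functional variants of known biological relevance (e.g. a PPARG missense
variant) are run as forced single-variant instrument sets that bypass the
FDR ranking but still face the palindrome and proxy checks.

Every excluded variant is logged exactly once with a stage and reason
code.

## Harmonization

The outcome record is re-expressed on the exposure's effect allele:
swapped alleles negate β_Y and complement the frequency; strand
complements (A/G vs T/C) are resolved before declaring incompatibility.
Palindromic pairs carry no allele information about strand, so alignment
minimizes |eaf_X − eaf_Y|; if both frequencies fall in (0.42, 0.58) the
orientation is unresolvable and the pair is dropped.  The MAF < 0.3
admission rule makes that band rarely binding; its width is a
conventional safety margin, not a fitted quantity.

## Estimators

Wald ratio, fixed-effect IVW, MR-Egger, weighted median and weighted mode
as summarized in the README.  Numerical choices:

- The Wald/IVW standard error is first-order (exposure-side uncertainty
  ignored), the standard two-sample convention; weights are
  w_j = β̂²_Xj/σ²_Yj.
- Egger requires k ≥ 3 and orients all instruments to β̂_X ≥ 0 first (the
  fit is not orientation-invariant otherwise); its standard errors carry a
  multiplicative overdispersion factor floored at 1.
- The weighted median interpolates the weighted empirical quantile at 0.5
  with cumulative weight s_j = Σ_{i≤j} w_i − w_j/2 on normalized weights.
- The weighted mode maximizes a weighted normal-kernel density over the
  ratio estimates on a 512-point grid spanning the ratio range ± 3h, with
  bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·k^(−1/5), φ = 1; identical
  ratios short-circuit to the common value.
- Median/mode standard errors come from a parametric bootstrap (resample
  β̂_X, β̂_Y from their normal sampling distributions; 10,000 replicates by
  default, mandatory seed).  Method dispatch by instrument count: k = 1
  Wald; k = 2 IVW; k ≥ 3 all of IVW/Egger/median/mode.
- Bonferroni gating is strict (p < α/m, default 0.05/6); the threshold is
  reported to 3 decimals.

## Positive-control gate

Before the primary analysis, each drug class's instruments must reproduce
the drug's established effects on control outcomes: T2DM risk reduction
for every class; weight gain for insulin, thiazolidinediones and
sulfonylureas, weight loss for GLP-1 receptor agonists and SGLT2
inhibitors, neutrality for DPP-4 inhibitors; insulin-sensitivity
improvement for thiazolidinediones; increased secretion (proinsulin
readout) for the secretagogue classes.  Concordance is judged on the sign
of the scaled point estimate only — passing controls in practice include
CI-crossing estimates, so demanding significance would gate on power, not
direction.  A strict mode requiring nominal p < 0.05 is available.
Neutral expectations and untested outcomes never fail the gate.

## Colocalization

Wakefield ABFs with prior effect variance W = (0.15·sd_Y)² for
quantitative traits (sd_Y supplied, or estimated from the median of
se²·n·2p(1−p) across variants) and W = 0.2² on the log-odds scale for
case-control traits — the established defaults for this framework.
Priors p1 = p2 = 1e−4, p12 = 1e−5.  All sums run in log space with
log-sum-exp; the distinct-variants term S3 uses the product-minus-diagonal
identity ΣA·ΣB − ΣAB rather than the O(M²) double sum, with the rare
negative floating-point cancellation clamped to zero.  The colocalized
region is the drug-target window plus a 200 kb flank so the regional
signal, not just the instruments, is evaluated.  One causal variant per
trait is assumed; multi-causal fine-mapping is out of scope.

## Synthetic data

Summary statistics are drawn directly from their asymptotic sampling
distributions — the exact structure two-sample MR assumes — rather than
from individual-level genotypes: on the standardized-genotype scale,
b_X ~ MVN(Rβ, R·σ²_X/n_X) and b_Y ~ MVN(R(θβ + α), R·c/n_Y) with
c = 1/(φ(1−φ)) the logistic-score variance factor for case fraction φ.
Standard errors are the theoretical values, conversion to the allelic
scale divides by √(2·maf·(1−maf)), and p-values are two-sided normal.
Defaults emulate the motivating study's conditions: a continuous glucose
GWAS of N = 309,895 with phenotype sd 0.8 mmol/L (a typical random-glucose
spread in a non-diabetic biobank population), an RA GWAS of 22,350 cases /
74,823 controls, MAF ~ U(0.05, 0.5), and an AR(1) LD panel with ρ = 0.5
over a drug-target window.  Direct (pleiotropic) effects can be injected
on the standardized or the allelic scale; the pleiotropy presets use the
allelic scale so the injected offset is constant after MAF conversion and
the Egger intercept has a well-defined target.

What the generator does **not** emulate: genotype-level noise, imputation
quality, population stratification, sample overlap, MAF-dependent LD
structure, and genome-wide polygenicity.  Passing tests therefore show
the estimators and pipeline behave correctly *under the model's own
assumptions*; they do not certify robustness to real-data violations of
those assumptions.

Scenario presets (all deterministic given a seed): `null-region` (no
effects), `one-causal`/`multi-causal` (1 or 3 causal variants at β = 0.04
per genotype sd, θ = 0.2 — strong instruments so recovery checks measure
estimator bias rather than sampling noise), `directional-pleiotropy`
(20 spaced instruments, constant allelic-scale direct effect 0.05),
`balanced-pleiotropy` (10 instruments, 4 carrying a large direct effect —
IVW breaks, the weighted median should not), `weak-instrument` (expected
F ≈ 8), `shared-causal` and `distinct-causal` (colocalization behavior).

## Verification sizes

The acceptance script and test suite use 200 seeded replicates for IVW
bias/coverage (at n_X = 300,000, n_Y = 100,000), 1,000 for null
calibration, 100 per colocalization scenario, and brute-force oracles at
M ≤ 10 variants / k ≤ 12 instruments — sizes at which the Monte-Carlo
error of each check is comfortably below the bound it asserts.

## Known limitations

- Single best proxy per missing instrument; no LD-based imputation of
  outcome associations.
- Per-window FDR (see above) — the genome-wide alternative is not
  computable from a cis extract.
- The binary-trait sampling variance uses the logistic-score
  approximation; its adequacy is covered by the type-I-error calibration
  band rather than by exactness claims.
- Colocalization assumes at most one causal variant per trait in the
  region.
- The positive-control gate is a sign test by design; it cannot detect
  instruments that are directionally right for the wrong reason.
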