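# Methods

## Model

Let γ̂ᵢ be the standardized effect of variant *i* on the outcome from a
GWAS of *n_l* samples: γ̂ᵢ = zᵢ/√n_l with sampling variance σ₀² = 1/n_l
(genotype and phenotype standardized to unit variance). For *T*
intermediate traits with summary statistics from non-overlapping studies
of nₜ samples each, b̂ᵢₜ = zᵢₜ/√nₜ with Var(b̂ᵢₜ) = 1/nₜ.

**Causal effects.** With individual-level data, two-stage least squares
would estimate the joint causal effects of the traits on the outcome. At
the summary level the same estimator reduces, for a set *S* of mutually
independent instruments, to a zero-intercept regression of outcome
effects on trait effects:

    α̂ = (B᾿B)⁻¹ B᾿ b_y
    Cov(α̂) = (σ̂²/n_l) (B᾿B)⁻¹,   σ̂² = RSS·n_l / (|S| − k)

B is the |S|×T matrix of *truncated* standardized trait effects — entries
with trait P > 10⁻⁵ set to exactly zero, so only strong instruments carry
weight — and b_y the outcome effects of the same variants. Instruments
are chosen greedily: the smallest trait P value first, removing every
remaining candidate with panel r² > 0.2 against each pick; the
instrument correlation matrix is then approximated by the identity. σ̂²
is the residual variance of the outcome on the standardized-effect
scale; when the traits explain a small share of per-variant effect
variance it sits near 1 (the test suite asserts it lands in (0.5, 1.5)
on calibrated simulations).

**Trait selection.** Bidirectional stepwise search over traits minimizing
AIC = |S|·ln(RSS/|S|) + 2k of the zero-intercept fit, followed by
backward elimination (refitting after each drop) of traits with
multivariate P > 0.05. Minimizing AIC is deliberate: selecting to
*maximize* it would always prefer the saturated model.

**Priors.** For each variant, μᵢ = Σₜ b̃ᵢₜ·α̂ₜ. Because b̂ and α̂ come from
independent data, the exact variance of this sum of products is

    Var(μᵢ) = b̃ᵢ᾿ Cov(α̂) b̃ᵢ + Σₜ (α̂ₜ² + Cov(α̂)ₜₜ) / nₜ

where the second term keeps Var(b̂ᵢₜ) = 1/nₜ for *every* selected trait,
truncated or not: a variant with all-zero b̃ still has a proper, weakly
informative prior N(0, Var μᵢ) rather than a point mass. The full
off-diagonal Cov(α̂) enters the quadratic form. The α̂ used for a variant
always comes from the fit that masked the variant's own chromosome
(leave-one-chromosome-out), so the prior is independent of the variant's
observed outcome statistic.

**Bayes factor.** The marginal likelihood of γ̂ under the alternative
(true effect δ ~ N(μ, Var μ), observation γ̂ | δ ~ N(δ, σ₀²)) divided by
the null likelihood N(0, σ₀²) has the conjugate closed form

    log BF = ½ ln(σ₀²/(σ₀²+Var μ)) + γ̂²/(2σ₀²) − (γ̂−μ)²/(2(σ₀²+Var μ))

verified against trapezoid numerical integration of the marginal to
< 10⁻⁶ over the parameter ranges the pipeline produces.

**Calibration.** K null replicates of the full Z vector (default 1,000;
simulation studies use 100–500) are generated either by regressing fresh
standard-normal phenotypes on the standardized panel dosages
(`phenotype-permutation`, the faithful construction) or by drawing
Z ~ MVN(0, C) per LD block (`mvn`, equivalent in distribution and much
faster; the default). Null Bayes factors use each variant's own prior.
Empirical P values pool all K·m null values with an add-one correction,
p = (1 + #{null ≥ observed})/(1 + K·m), so p > 0 always and ranking by
log BF and by empirical P agree. Benjamini–Hochberg is applied to these
P values; additionally the pooled exceedance rate (per-comparison error
rate) and the implied FDR estimate at any log-BF threshold are reported,
since "weak-control error" admits both readings.

## Synthetic data

The generator emulates the features the scan exploits and nothing more:

* **Panel**: variants in independent blocks (default 10 variants/block),
  latent Gaussian haplotypes with AR1(ρ=0.5) correlation thresholded at
  MAFs drawn uniformly from (0.05, 0.5), two haplotypes summed to
  Hardy–Weinberg dosages; 500 reference individuals. Thresholding
  attenuates the latent correlation (the tests compare against the exact
  bivariate-normal attenuation). Blocks are separated by 400 kb so
  windowed operations also see them as unlinked.
* **Compendium**: per trait, 50 causal variants with Gaussian effects
  scaled to 10% SNP heritability; outcome effects are Σₜ αₜβₜ with
  α = (0.2, −0.1, 0, 0.05, 0), plus direct (pleiotropic) effects on 1% of
  variants carrying h²_direct = 0.001 — a deliberate minor contaminant,
  about a fifth of the trait-mediated outcome-effect variance Σαₜ²h²ₜ,
  matching the model's premise that outcome effects act predominantly
  through the traits. Observed Z = √n·(C@β) + MVN(0, C) blockwise, with C
  the panel's empirical block correlation; studies are mutually
  non-overlapping, so no cross-study noise correlation. Sample sizes
  default to 100,000 per study.

What this does **not** emulate: realistic demography or coalescent LD,
imputation error, sample overlap between trait studies, non-linear
trait–outcome relationships, and case–control liability-scale effects.
Passing tests therefore show the machinery is correct and calibrated
under its own assumptions, not that real-data discoveries would have any
particular count.

## Numerical choices

* Ridge on LD solves: λ defaults to 2/√n_ref on the diagonal, which keeps
  windows wider than the panel invertible; λ=0 preserves the exact
  self-imputation identity. Imputation window ±250 kb, quality floor
  r²pred ≥ 0.3 (both exposed as flags).
* Ties in greedy instrument pruning broken by (chromosome, position);
  duplicated variant ids are a hard error, never silently deduplicated.
* Strand-ambiguous (A/T, C/G) variants are dropped at harmonization;
  swapped-allele records flip the sign of z and b; irreconcilable allele
  pairs are dropped with a warning.
* Cholesky factors of empirical block correlations get a 10⁻⁹ jitter
  (escalated only if needed); monomorphic panel columns are excluded from
  correlation queries.
* `sigma2 = 0` (an exact fit) gives all-zero standardized MR residuals
  rather than 0/0.

## Validation studies and problem sizes

The acceptance suite (`tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) runs:

* closed-form vs integrated log BF on 1,000 random parameter draws;
* null calibration at m = 20,000 variants, K = 500 pooled null
  replicates, 100 null observed scans: mean per-scan KS statistic below
  1.63/√m and mean BH-5% false-discovery proportion in [0.03, 0.07];
* MR recovery at T = 5, |S| = 500, n = 10⁵, 200 replicates, instrument
  effect SD 0.045 (the strong-instrument scale √(h²ₜ/n_causal) of the
  default compendium): ≥ 99% of the 1,000 trait-replicate estimates
  within 3 estimated s.e., 95% CI coverage within 95% ± 3%;
* exact sample-size invariance: scaling any one trait's n by 4 end to end
  moves no prior mean by more than 10⁻¹⁰ (observed shifts are ~10⁻¹⁷);
* paired power at the default compendium, 100 replicates, K = 100: the
  prior-informed scan's true-positive count at matched empirical FDR is
  at least the flat |Z| scan's in ≥ 90 replicates.

These sizes were chosen as the smallest at which the asymptotic
guarantees are clearly expressed; all studies are seeded and
reproducible.

## Known limitations

* The depletion test implements the stated binomial construction —
  count-based tail Pr(X ≥ k; n, 0.05) and sign-based tail
  Pr(X ≥ k; n, 0.5) with exact sums. External write-ups of analogous
  analyses sometimes print P values that do not follow from this
  construction; this implementation does not attempt to reverse-engineer
  such numbers.
* Zero-prior variants are effectively undiscoverable by the Bayes-factor
  scan (their BF is nearly flat in γ̂). That is the method's designed
  trade-off: power is reallocated toward variants with informative
  priors, and a genome whose signal is mostly prior-independent will
  favor the flat scan.
* The MR estimator inherits a small weak-instrument attenuation when
  instrument effects are noisy; at the default strong-instrument scale
  the bias is ≲ 0.3 estimated s.e.
* Multivariate MR here assumes non-overlapping trait and outcome studies,
  homoscedastic errors, and identity instrument correlation after
  pruning; no Egger/median robust variants are provided.
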