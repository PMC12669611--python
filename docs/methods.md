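# Methods

## The problem

A GWAS of disease *progression* is run in people who already have the
disease. Selecting on incident disease conditions on a collider: incident
disease is caused both by genotype and by confounders `U` of the
incidence–progression relationship, so within cases genotype and `U`
become negatively correlated and variants that only affect incidence
acquire spurious progression associations. Existing slope-based
corrections (instrument-effect regression; Slope-Hunter) assume the
direct genetic effects on incidence (`β_GX`) and progression (`β_GY`) are
uncorrelated, or that the modal incidence-associated cluster has no direct
progression effect — assumptions likely violated when both phenotypes
derive from the same biomarker (e.g. creatinine-based eGFR level and eGFR
slope in kidney disease).

## The model

For each variant `i`, with observed incidence estimate `bhat_GX,i` (SE
`σ_GX,i`) from the full-cohort GWAS and observed progression estimate
`bhat*_GY,i` (SE `σ_GY,i`) from the cases-only GWAS:

    bhat*_GY,i ~ N(β_GY,i + b·β_GX,i, σ²_GY,i)
    bhat_GX,i  ~ N(β_GX,i, σ²_GX,i)

    (β_GX,i, β_GY,i) ~ N( (μ, 0),  [ s_x²,            ρ_i·s_x·φ_i·τ ]
                                    [ ρ_i·s_x·φ_i·τ,  φ_i²·τ²       ] )

`b` is a single global coefficient capturing the collider path (and any
residual direct incidence→progression effect); the estimand of interest
is the direct effect `β_GY,i`. The `β_GY` margin carries a horseshoe
prior — local scales `φ_i ~ Cauchy⁺(0,1)`, global scale `τ ~ Cauchy⁺(0,1)`
— which shrinks null progression effects hard while letting genuinely
non-null effects escape. The per-variant correlation is `ρ_i = 2·r_i − 1`
with `r_i ~ Beta(3,1)`, placing most prior mass on strong positive
correlation (the expected direction for kidney phenotypes) while allowing
negative values. Remaining priors: `b ~ Uniform(−10,10)`, `μ ~ N(0,1)`,
`s_x² ~ N⁺(0,1)`. SEs are treated as known. A variant is called
significant when the equal-tailed 95% credible interval for `β_GY,i`
excludes zero.

A sensitivity mode replaces the horseshoe with a fixed-scale normal prior
on `β_GY` (`prior_family_gy="normal"`); it reproduces the known failure
mode of inflated type-1 error and is not recommended for inference.

## Posterior computation

The sampler is a collapsed Metropolis-within-Gibbs scheme written in
numpy, vectorized over variants and chains:

* Because the likelihood and the effect-pair prior are jointly Gaussian,
  `(β_GX,i, β_GY,i)` is integrated out analytically: marginally
  `(bhat_GX,i, bhat*_GY,i)` is bivariate normal with mean `(μ, b·μ)` and
  covariance `A Σ_i Aᵀ + diag(σ²_GX,i, σ²_GY,i)`, `A = [[1,0],[b,1]]`.
  All scale/correlation/global updates target this collapsed posterior,
  which removes the funnel coupling between `β_GY,i` and `φ_i τ` that
  makes horseshoe posteriors slow for uncollapsed one-at-a-time samplers.
* `log φ_i` and `logit r_i` receive element-wise adaptive random-walk
  Metropolis updates (one vectorized proposal per sweep across all
  variants and chains); `log τ`, `log s_x`, `b`, `μ` receive per-chain
  scalar random-walk updates. Proposal scales adapt by Robbins–Monro
  toward 0.44 acceptance during burn-in and are frozen afterwards, so the
  retained draws come from a fixed-kernel chain.
* After each sweep past burn-in, `β_GY,i` is drawn exactly from its
  Gaussian full conditional (at stored iterations only). Draws are
  conditionally independent given the scale chain, so the effective
  sample size of `β_GY` reflects the mixing of the scales and globals.
* Transformed parameters are bounded (`|log scale| ≤ 20`,
  `|logit r| ≤ 12`); the prior mass excluded is below 1e−8 and the bound
  keeps the collapsed covariance numerically positive definite.
* Defaults follow the published MCMC settings: 4 chains × 15,000
  iterations, 20% burn-in. Stored draws per chain are capped (default
  2,000, thinned evenly) to bound memory; global parameters are stored at
  every kept iteration.
* Chains never interact, so independent replicate datasets of equal size
  are fitted in a single vectorized run (`fit_mr_horse_many`) by stacking
  them as additional chain rows. This is an implementation detail; each
  replicate's posterior is identical to a solo fit up to RNG stream.

The sampler was validated two ways: against JAGS 4.3.2 running the same
model (posterior mean/SD of `b`, `τ`, `μ`, `s_x` agree within Monte-Carlo
error on shared data; one such check ships in the test suite), and
against a brute-force importance-sampling integrator on a 5-variant
instance (`tests/oracles.py`), which evaluates the marginal likelihood
through generic matrix algebra and samples all parameters from their
priors.

### Convergence diagnostics

Rank-normalized split-`R̂` (maximum of the bulk and folded statistics) and
Geyer initial-positive-sequence bulk ESS are implemented vectorized over
variants; both are cross-checked against ArviZ in the test suite.
Zero-variance chains return `R̂ = 1.0` by convention with a warning
(rank-normalizing a constant sequence would inject spurious variation).

### Which variants enter the fit

Joint fitting at genome scale is impractical, so three modes are exposed:
(i) fit on variants selected at `p_inc < 1e−3` (the published
application's approach; CLI default); (ii) two-pass (`--score-all`): fit
globals on the selected set, then sample per-variant parameters for every
remaining variant with `b, τ, μ, s_x` fixed at their posterior means, so
all variants get estimates; (iii) all-variant joint fitting
(`--all-variants`), used by the simulation harness where 2,000 variants
are affordable. Mean instrument strength `F = mean((bhat*_GY/σ_GY)²)` over
the selected set above ~15 indicates adequate power.

## The simulator

One replicate generates, for `n` individuals and `m` independent SNPs in
HWE (MAF ~ U(0.01, 0.49)):

    Inc_j  = Σ_i β_GX,i G_ij + U_j + ε_I,j          (liability)
    CKD_j  = 1[Inc_j ≥ empirical (1 − prevalence) quantile]
    Prog_j = Σ_i β_GY,i G_ij + λ·Inc_j + γ·U_j + ε_P,j

with `U ~ N(0,1)`, `λ = 0.1`, `γ = 1.5`, prevalence 40%. The incidence
GWAS is per-SNP logistic regression on the binary indicator in the whole
population; the progression GWAS is per-SNP linear regression in cases
only. `λ` multiplies the continuous liability (the progression equation
references the liability variable, not the thresholded indicator).

Variants fall into four clusters — null (95%), incidence-only GI (1%),
progression-only GP (1%), pleiotropic GIP (3%). Per-variant variance
contributions `r²_i` are half-normal with scale `R²·√π/(n_c·√2)` (cluster
mean `R²/n_c`), and per-allele effects are `±√(r²_i/(2·maf(1−maf)))`.
Each cluster's drawn effects are rescaled so the cluster's realized
variance contribution equals its target exactly; the half-normal shape is
preserved and the expectation is unchanged, but small clusters no longer
fluctuate into infeasible variance budgets. GIP effect pairs are coupled
by a Gaussian copula: a bivariate standard normal with correlation `ρ` is
mapped through each margin's signed quantile function, preserving rank
correlation ≈ `ρ` (the realized Pearson correlation of the heavy-tailed
margins is somewhat lower and is recorded in `TrueEffects.params`).

### Variance budgets

`Var(U) = 1` is fixed (the liability equation gives `U` a unit
coefficient), so with liability SNP heritability `h² = 0.40` the noise
variance solves `σ²_ε,I = V_g(1 − h²)/h² − 1`, which requires a total
incidence-cluster budget `≥ h²/(1 − h²) = 2/3`. For progression, `U`
reaches the phenotype through both `γ` and `λ·Inc` (total coefficient
`γ + λ`); the direct effects `β_GY` are rescaled by a common factor and
`σ²_ε,P` solved so that, in the full population, SNP heritability and the
`U`-variance fraction hit the midpoints (0.35) of their 30–40% target
ranges exactly.

### Per-cluster variance targets (defaults)

The per-cluster `R²` values are free parameters of the design. Defaults,
chosen once against the published description of the architecture:
incidence `R²` = 0.5 (GI) + 0.5 (GIP) in liability-variance units —
equal cluster totals, making incidence-only variants individually ~3×
stronger than pleiotropic ones, consistent with the motivating kidney
example where the strongest cross-sectional loci (creatinine-metabolism
genes) are exactly the ones without progression effects; progression
relative targets 0.5 (GP) and 2.0 (GIP), so the pleiotropic cluster
explains 80% of progression genetic variance (the architecture is built
to violate the comparators' assumptions). Under these defaults the mean
pleiotropic variant explains ≈ 0.47% of progression variance, so the
0.4–0.6% variance-explained bin — the effect size of interest for kidney
phenotypes — is well populated.

### GWAS internals

Genotypes take only values {0,1,2}, so each per-SNP logistic regression
depends on the data through six counts; Newton–Raphson on those
sufficient statistics is exact (matches `statsmodels.Logit` to ~1e−15 in
the tests) and orders of magnitude faster than iterating over
individuals. Monomorphic and non-converged SNPs return missing estimates
and are dropped from the replicate (with their truth rows). Linear GWAS
uses closed-form simple regression with t-based two-sided p-values.

## Comparator methods

* **Instrument-effect regression (Dudbridge)** — OLS of `bhat*_GY` on
  `bhat_GX` through the origin (the structural equation has no constant;
  an intercept is available by flag) over variants with `p_inc < 1e−3`,
  divided by the Hedges–Olkin reliability `1 − mean(σ²_GX)/var(bhat_GX)`.
  Non-positive reliability is an error. SIMEX-style corrections are out
  of scope.
* **Slope-Hunter style mixture** — two-component zero-mean Gaussian
  mixture fitted by EM on `(bhat_GX, bhat*_GY)` pairs: a "hunted"
  component constrained to a line through the origin (covariance
  `[[v₁, b v₁],[b v₁, b² v₁ + e₁]]`) and a free-covariance component.
  Initialization: k-means on the ratio `bhat*_GY/bhat_GX` plus 5 random
  restarts, best log-likelihood wins; because the labeling is
  exchangeable, the hunted cluster is identified post hoc as the more
  collinear component and its through-origin slope is reported.
  Percentile bootstrap (default 200 resamples) gives the CI. This is a
  re-implementation from the algorithmic description; property-level
  agreement (slope recovery when the hunted-cluster assumption holds),
  not numerical identity with the published R package, is the contract.
* Adjustment applies `β̂_adj = bhat*_GY − b̂·bhat_GX` with SE
  `√(σ²_GY + b̂²σ²_GX + bhat²_GX·se²_b̂)` (the last term dropped when no
  slope SE is available) and two-sided normal p-values.

## Evaluation definitions

* **Type-1 error**: fraction of truly-null progression variants (G0 ∪ GI)
  flagged significant (p < 0.05 for slope methods; 95% CrI excluding 0
  for the Bayesian method).
* **Power**: detection fraction among truly non-null variants, binned by
  variance explained `2β²·maf(1−maf)` as a fraction of progression
  phenotype variance; deciles by default, with a fixed 0.4–0.6% bin
  (centred on 0.5%) for the headline number.
* **Bias**: mean `|β̂_GY,i − β_GY,i|` over GI ∪ GIP variants, where the
  collider distortion concentrates.
* Metrics are computed per replicate and averaged; SEMs across replicates
  accompany the means.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) uses the full published
per-replicate scale (10,000 individuals × 2,000 SNPs) with 20 replicates
per correlation at 4 × 2,000 iterations, and 3 replicates at the full
4 × 15,000 iterations for the convergence rate; the test suite asserts
the same properties at 1,000 SNPs with 5–8 replicates per correlation.
The published study used 1,000 replicates; at the replicate counts used
here the pooled type-1 error rate is estimated from ≥ 3,000 null-variant
decisions per correlation and the 0.5%-bin power from ≥ 60 detection
decisions.

## Known limitations

* Independent SNPs only: no LD, no clumping, no relatedness or
  covariates. Real applications must supply an externally clumped variant
  list.
* Binary progression outcomes (logistic progression GWAS) are not
  supported.
* In the no/negative-correlation regime the bias reduction relative to
  unadjusted analysis is small while the power cost is marked — matching
  the published characterization — so unadjusted or instrument-effect
  estimates may be preferable when strong negative correlation is
  plausible.
* When the pleiotropic cluster dominates the incidence-associated set,
  the posterior for `b` partially attributes the pleiotropic trend to the
  bias coefficient and recovers only part of the generative bias slope;
  per-variant `β_GY` estimates remain well calibrated (type-1 error
  controlled) but some residual bias persists for escaped effects.
* The horseshoe's type-1-error control is a shrinkage phenomenon, not a
  frequentist guarantee; heavily shrunk true effects appear in the bias
  metric of the pleiotropic cluster.
* Simulated SEs are treated as known in the model, as in the published
  formulation; very small studies with noisy SEs are outside the model's
  assumptions.
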