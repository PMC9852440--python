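# Methods

## The twin design and its generative model

The package's inferential core is the classical twin design: monozygotic
(MZ) co-twins share essentially all segregating genetic variation, dizygotic
(DZ) co-twins half of it on average. Writing a standardized phenotype as

    P = a·A + c·C + e·E,     a² + c² + e² = 1,

with A the additive-genetic factor (correlated 1 between MZ co-twins, 0.5
between DZ co-twins), C the pair-shared environment and E the
individual-specific environment plus measurement error, the implied co-twin
correlations are rMZ = a² + c² and rDZ = a²/2 + c². All twin estimators in
the package are functions of this contrast.

The synthetic-data generator (`simulate`) draws exactly this model: a
pair-shared (MZ) or half-shared (DZ) Gaussian A factor, a fully shared C, an
independent E, optional age/sex fixed effects added on the raw scale, and —
in bivariate mode — cross-trait factor correlations rA, rC, rE so that the
within-twin cross-trait covariance is √(a²ₓa²ᵧ)·rA + √(c²ₓc²ᵧ)·rC +
√(e²ₓe²ᵧ)·rE, with the rE term absent across twins and the rA term halved in
DZ pairs. Because all factors are Gaussian and the mixing is linear, the
ACE truth is *exact* on the latent scale; skewness for exercising the
rank-based normalisation is produced by a separate monotone warp
(`skew_warp`) applied after generation. DZ twin sexes are drawn
independently, so same-sex and opposite-sex DZ pairs arise naturally and are
pooled in all fits — no sex-limitation model is simulated (sex and zygosity
jointly explain a trivial share of variance in the motivating data, and the
ANOVA helper exists to verify exactly that on any input).

Default group sizes (2,890 MZ / 4,879 DZ pairs) and the age distribution
(mean 22.14, SD 0.85 years) mirror a large UK twin register in emerging
adulthood; polygenic-score cohorts default to n = 6,000 unrelated
individuals with scores explaining under 1% of outcome variance, the current
effect-size regime for psychiatric polygenic scores.

What the generator does **not** emulate: non-Gaussian measurement scales
(Likert items), missingness patterns, assortative mating, dominance,
gene–environment interaction, sibling contrast effects, or real
linkage-disequilibrium structure behind the scores. Passing recovery tests
therefore shows the estimators are correct *under the model's own
assumptions*, not that those assumptions hold in any particular cohort.

## Phenotype preparation

Phenotypes are age/sex-residualised by OLS and re-standardized before
model fitting (members of a pair share age, and MZ pairs share sex, so
unremoved age/sex effects would masquerade as shared environment). The van
der Waerden transform maps value ranks to standard-normal quantiles
Φ⁻¹(rank/(n+1)) with average ranks for ties; it is applied after
residualisation. Intraclass correlations are computed by double entry
(each pair contributes both orderings), which makes them exactly symmetric
in twin labelling and consistent with the model likelihood; confidence
intervals use the Fisher z approximation with the *pair* count as effective
sample size. Multiple testing across a correlation family uses the
Benjamini–Hochberg step-up rule with the full left×right family as the
adjustment set.

## Univariate ACE estimation

Three estimators, in increasing order of fidelity:

1. **Falconer arithmetic**: a² = 2(rMZ − rDZ), c² = rMZ − a², e² = 1 − a² −
   c². Unconstrained by design; out-of-range components are flagged, not
   clipped, because their pattern is diagnostic (c² < 0 signals rMZ > 2·rDZ,
   possible non-additive variance).
2. **Summary-level ML**: treats z(r_g) as Normal(z(ρ_g), 1/(n_g − 3)) per
   zygosity group (Fisher z approximation) and maximizes over a², c² ≥ 0,
   a² + c² ≤ 1. This is the natural fit when only printed correlations are
   available and is asymptotically equivalent to the raw-data fit.
3. **Raw-pair ML**: full bivariate-normal likelihood of co-twin pairs with
   unit variances fixed (phenotypes are standardized by construction) and
   correlation ρ_g determined by (a², c²). Computed from symmetric
   sufficient statistics, so estimates are exactly invariant to swapping
   twin 1 and twin 2.

Variance proportions are parameterized directly as (a², c²) with simplex
constraints rather than as path coefficients: this avoids sign
indeterminacy and makes boundary reporting explicit (squared-path optima are
equivalent). Optimization is SLSQP with objective tolerance 1e-12 and 8
starting points (3 fixed, 5 seeded random); boundary flags are set below
1e-6. Confidence intervals are likelihood-ratio profiles: the bound solves
2·(ℓ_max − ℓ_profile(v)) = χ²₁(0.95) = 3.84, with the inner nuisance
dimension minimized by bounded scalar search and the crossing bracketed by
Brent's method; components at a boundary take the boundary as their limit.
The naive χ²₁ reference is used even at boundaries (where the true
distribution is a mixture); measured coverage for a² at the default group
sizes is ≈0.95, inside the 0.92–0.98 band the test suite enforces.
Submodel comparison (ACE/AE/CE/E) reports −2lnL, AIC with k = number of
free variance parameters, and likelihood-ratio p-values against ACE.

## Bivariate Cholesky decomposition

Two traits per twin give a 4-variate observation (X₁, Y₁, X₂, Y₂) whose
model-implied covariance is assembled from lower-triangular paths per
component (a11, a21, a22; likewise c, e), with within-twin cross-trait
covariance a11·a21 + c11·c21 + e11·e21, the e-term dropped across twins and
the a-term halved for DZ. The likelihood uses the double-entered
(swap-symmetrized) sample covariance per zygosity group and is maximized by
SLSQP over the 9 paths under two unit-variance equality constraints, with
first-element paths constrained non-negative to fix reflections. Primary
outputs are the proportions of the phenotypic correlation, prop_k =
cov_k/r_ph, and the component correlations, e.g. rA = a11·a21/(|a11|·√(a21²
+ a22²)).

Numerical guards: |r_ph| < 0.05 triggers a low-precision warning rather
than returning unstable ratios; a (near-)duplicate trait pair (|within-twin
cross-trait r| > 0.999) makes the 4-variate likelihood singular, so the fit
short-circuits to its analytic limit — the univariate ACE split of the
shared trait. Confidence intervals on the proportions use a seeded
nonparametric pair-resampling bootstrap (percentile, 200 replicates by
default); profiling a ratio of paths through the constrained 9-parameter
space proved numerically fragile, and the bootstrap is the robust,
deterministic-under-seed choice.

Monte Carlo note: at 20,000 + 20,000 pairs the sampling SD of prop_a is
≈0.06 when the truth splits a moderate r_ph ≈ 0.2–0.25, because the
identifying statistic 2·(MZ − DZ cross-twin cross-trait r) amplifies
correlation noise. Recovery checks that demand ±0.05 accuracy therefore
average the estimate over 5 independent replicates.

## Polygenic-score association

Scores are standardized on construction; per-score Pearson correlations
carry BH-FDR-adjusted p-values over the score×phenotype family, and the
joint OLS fit reports signed betas, R² (with adjusted R², since in-sample R²
never decreases when noise columns are added), multiple R = √R², and the
overall F-test. Rank-deficient score sets drop offending columns with a
warning. Ancestry covariates are accepted but default off — the synthetic
cohorts are ancestrally homogeneous by construction.

## Gsens: genetic-confounding sensitivity analysis

For standardized (G, X, Y) with correlations (r_GX, r_GY, r_XY), the
exposure effect adjusted for the genetic variable is the partial regression
coefficient b_adj = (r_XY − r_GX·r_GY)/(1 − r_GX²); confounding is reported
as 1 − b_adj/r_XY (×100 as attenuation; negative values — suppression — are
reported, not clipped). Standard errors come from the delta method with the
Olkin–Siotani asymptotic covariance of the three correlations; a seeded
parametric bootstrap (resampling trivariate-normal cohorts of size n) is
available for percentile intervals.

Scenario scaling anchors on the outcome's heritability: r_GY' =
sign(r_GY)·√h² and r_GX' = r_GX·√h²/|r_GY|, preserving the score's
exposure/outcome association ratio, with r_XY untouched and positive
definiteness re-checked (a failure means the requested confounding exceeds
what the observed association structure permits, and is reported as such).
The analysis runs three scenarios: observed, SNP heritability, twin
heritability.

Two properties of this single-score, outcome-anchored variant worth knowing:

- With a *pure confounding* truth, twin-scenario attenuation is exactly 100%
  in population moments, but the scaling factor √h²/|r_GY| is noisy when the
  observed score is weak (R² ≈ 0.01): at n = 50,000 the twin-scenario
  attenuation has a sampling SD near 10 points. Qualitative-pattern checks
  therefore use n = 2,000,000 cohorts, where the SD is ≈1.4 points.
- With a mixed causal+confounded truth, cor(G, Y) = √h² + b_xy·b_gx exceeds
  the anchor √h², so the twin-scenario b_adj carries an O(b_xy·b_gx) upward
  bias relative to the true causal effect (≈0.007 at b_gx = 0.15,
  b_xy = 0.15). It recovers the causal effect exactly only when either path
  is the sole nonzero one.

## Pipeline and determinism

`run_pipeline` executes simulate → preprocess → univariate (→ GPS → Gsens)
from one config dict, writing per-stage JSON/CSV, a Table-style summary
(trait rows; A/C/E, rMZ/rDZ with CIs), and a run log with versions, seed and
timings. One global integer seed drives everything; per-stage streams are
derived deterministically from it, so identical configs produce
byte-identical JSON (floats rounded to 4 decimals).

## Problem sizes used in the test suite

Recovery tests use 20,000 + 20,000 pairs (univariate ±0.02, bivariate
prop_a ±0.05 on the 5-replicate mean); coverage simulation uses 500
replicates at 2,890/4,879 pairs; the FDR null simulation uses 200 replicates
of a 3×3 family at n = 5,000; Gsens qualitative patterns use n = 2,000,000
cohorts as explained above. The full suite runs in about a minute on one
CPU.
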