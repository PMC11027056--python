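# Methods

This note documents the statistical model behind `kpsae`, the decisions
taken where the design was genuinely open, the synthetic data the tests
rely on, and the limits of what those tests demonstrate.

## Consensus triangulation

**Model.** Competing direct size estimates for one region are combined on
the natural-log scale. Input *i* with point xᵢ and 95% CI (Lᵢ, Uᵢ)
contributes a Gaussian likelihood factor for the true log size μ with
mean ln xᵢ and SD σᵢ = (ln Uᵢ − ln Lᵢ)/(2·1.96). Its precision 1/σᵢ² is
multiplied by a confidence weight wᵢ ∈ (0, 1] reflecting methodological
rigor. An optional log-normal prior contributes mean μ₀ and precision
1/σ₀². Because every factor is Gaussian in μ, the posterior is Gaussian
with precision equal to the sum of contributions and mean equal to the
precision-weighted average; the package asserts this closed form against
a brute-force grid posterior (10⁵-point log-size grid) in its tests.

**Decisions.**

- The input mean is ln(point), *not* the CI log-midpoint. Published
  intervals are often asymmetric around their point (e.g. 100 with CI
  50–1700); keeping the published point as the headline value and using
  the CI only for spread preserves what the original investigators
  reported.
- Confidence weights default to linear decay (8 − rank)/7 over the fixed
  method ranking (SS-PSE, unique object multiplier, mapping, stakeholder
  consensus, literature review, key informant, wisdom of the crowds).
  Only the *order* is substantive; the numeric values are a
  parameterization, and the rank-sensitivity harness quantifies how little
  the consensus moves across order-preserving alternatives (linear,
  geometric, equal) versus order-reversing permutations.
- A missing CI ("no bounds") falls back to a symmetric multiplicative
  factor-4 interval, σ = ln 4/1.96 ≈ 0.707, configurable and flagged in
  output. Factor 4 matches the spread of comparable published rows.
- A point-mass prior (σ₀ = 0) is refused with an instruction to widen:
  it would make the data irrelevant, which is never the analyst's intent
  for a prior summarizing noisy program counts.
- Intervals use the normal 1.96 quantile on the log scale throughout.
- Missing methods are simply absent inputs; nothing is imputed for them.
- With weights below 1 the posterior precision understates the true
  information content, so credible intervals are mildly conservative;
  the empirical coverage check (~0.95–0.97 across seeds) reflects this.

## Program-data priors

Quarterly counts of individuals reached by services are pooled across
reporting systems after a two-tailed two-sample t test checks that the
systems' distributions are compatible. The Welch (unequal-variance)
variant is used since nothing justifies assuming equal variances; the
test can optionally run on log counts. The pooled counts are reduced to
minimum, maximum, median, and sample SD (n−1). The prior is moment-matched
as μ₀ = ln(median) and σ₀² = ln(1 + (sd/median)²) — the simplest use of
the four summaries consistent with a log-normal size distribution. The
min/max are carried as plausibility bounds that trigger warnings, not
truncation. Matching the spread through sd/median rather than sd/mean
slightly inflates σ₀ for very skewed samples; this is deliberate
conservatism and is documented in the prior-recovery test. A single
pooled count yields sd = 0 with a warning so single-quarter pilots run.
Priors may be pooled nationally per population (default, matching how
such data are usually reported) or per region when records carry a
region identifier.

## Imputation and extrapolation

Proportions are formed by dividing region-level sizes by survey-year
census denominators of the matching sex, ages 18–49, and are applied to
projected target-year denominators, ages 15–49. The age-band mismatch is
intentional and preserved: the survey-year denominators match the age
composition of the surveyed populations, while programs plan against the
wider 15–49 projection.

- **Simple imputation** assigns the unweighted mean of on-sample
  proportions to *every* region — including on-sample ones — so final
  regional estimates are exactly proportional to the projections. This is
  required to reproduce the published regional tables, whose surveyed-region
  entries differ from their own consensus-derived values.
- **Stratified imputation** first median-splits regions on HIV prevalence
  or population density (strictly greater than the median → high; ties
  low, matching the reporting label "less than or equal to median"), then
  assigns per-stratum means. Any stratum containing a region to predict
  must contain at least one on-sample donor; otherwise the run aborts
  naming the empty stratum. With a single stratum this reduces exactly to
  simple imputation (tested).
- **Pre-program mode** uses all method-level estimates: proportions are
  averaged per region first, then across regions, so each region counts
  equally however many methods it fielded. **Post-program mode** uses the
  prior-informed consensus estimates.
- Rounding to whole persons happens once, at the final extrapolation
  step, half-up.

## Offset-Poisson regression

The supplemental small-area model treats each method-level estimate
(rounded to an integer) as a Poisson count with offset ln(denominator),
so the linear predictor is a log proportion. Estimating equations are
solved with region clusters (statsmodels GEE; independence or
exchangeable working correlation, robust variance). Decisions:

- AIC/BIC for model selection are computed from the independence-
  likelihood GLM fit of the same design, because a GEE has no likelihood;
  QIC is reported as an auxiliary column but is not the selector.
- Covariates are z-scored across *regions* (not observations) before
  fitting; coefficients are reported on both scales, and the
  standardization is exactly undone for prediction (tested against the
  unstandardized fit).
- Predictions are capped at the projection (proportion < 1) with a
  warning.
- The saturated zero-residual toy case cannot identify an exchangeable
  correlation parameter (division by zero inside the moment estimator);
  it is reported as non-convergence rather than silently returning NaNs.

## Synthetic data

The generator draws, from a single seeded PCG64 stream in a fixed
documented order: regional covariates (HIV prevalence ~ U(5, 30)%,
density ~ LogUniform(1, 100) persons/km², literacy ~ U(60, 95)%,
employment ~ U(30, 70)%, growth ~ U(0.5, 3)%/yr — percentage scales
chosen to sit in realistic ranges for the schema's validation), survey
denominators ~ U(20k, 120k) with projection growth ~ U(1.05, 1.35); true
proportions from a log-linear model in covariate z-scores (default
intercept ln 0.02) or a two-level stratum model; method-level estimates
point ~ LogNormal(ln(bias·size), σ²) with CIs point·exp(±1.96σ); and
quarterly program counts as truncated-normal coverage (mean 0.35, SD
0.10, in (0, 1]) of the true size, so counts never exceed it. Default
method profiles encode the confidence ranking: σ rises from 0.10 (SS-PSE)
to 0.80 (wisdom of the crowds) and |ln bias| from 0 to 0.22 — biases kept
small relative to each method's own noise so that they order the methods
without dominating them. When a stratum model is configured, on-sample
selection is stratified so both strata have donor regions, mirroring the
imputation precondition.

What the generator does *not* emulate: spatial correlation between
regions, time trends or seasonality in program counts, differential
reporting quality between source systems, and correlated errors between
methods fielded in the same survey. Passing recovery tests therefore
demonstrate internal consistency of the estimators under the assumed
error structure, not robustness to those real-world features.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates of the default 13-region,
4-on-sample configuration (recovery tolerance ±0.005 on proportions of
0.01–0.04; coverage band 0.90–0.99), 100 replicates for model-selection
consistency, and a 10⁵-point grid for the posterior oracle — sizes at
which Monte-Carlo error is far below the tolerances while the whole suite
runs in seconds. Tie-breaks: AIC then BIC in model selection; median ties
to the low stratum; warnings are ordered deterministically. Degenerate
inputs (zero-variance t test, zero-width CI, point-mass prior, single
cluster, empty donor stratum) raise explicit errors rather than returning
arbitrary numbers.

## Known limitations

- The published consensus values cannot be reproduced numerically: the
  pooled program-count summaries that parameterized their priors were
  never published. Consensus correctness is therefore established by the
  closed-form/grid-oracle equivalence and invariance properties instead.
- National totals recomputed from the published regional tables differ
  from the printed national endpoints by up to 6 persons (≤ 0.13%)
  because the printed regional entries are rounded; one column (post-
  program stratified-by-HIV FSW) reproduces its endpoint exactly.
- The precision proxy (CI width) and the numeric weight values are
  decisions of this package; the original tool's internals are not
  public. Sensitivity to the weights is quantified rather than assumed
  away.
- No uncertainty intervals accompany imputed regional estimates, matching
  the published tables.
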