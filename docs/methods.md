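# Methods

## Stability partition

For a site with populations `i = 1..S` observed over `T ≥ 2` years, let
`μ_i`, `σ_i` be the temporal mean and standard deviation of population
abundance, `μ`, `σ²` those of the community total. The package computes

- community CV: `CV = σ / μ`,
- weighted mean population CV: `CV_w = Σ_i (μ_i/μ)(σ_i/μ_i) = Σ_i σ_i / μ`,
- synchrony: `φ = σ² / (Σ_i σ_i)²` (0 = perfectly compensatory
  dynamics, 1 = perfectly parallel dynamics),

which satisfy `CV = CV_w √φ` identically, and on the negative
natural-log scale `−log CV = ½(−log φ) + (−log CV_w)` — community
stability decomposes additively into population asynchrony and weighted
mean population stability. Both identities are verified to 1e-10 on
random matrices in the test suite.

Conventions: all variances, covariances and standard deviations use the
sample (n−1) denominator; both identities hold under either convention
as long as it is consistent, and the choice is recorded in every run's
metadata. Logs are natural throughout (the base cancels in standardized
SEM coefficients). A year missing from a site's records is dropped for
all species of that site (complete-column analysis, no zero
imputation); species never observed at a site are removed before
computing `CV_w`, while species observed at least once contribute their
zero years. Degenerate communities (CV = 0 or φ = 0, where a log
diverges) are excluded from downstream regressions with a logged
reason, never clamped.

Taylor's law `σ_i² = c μ_i^b` is fit as a log-log regression of the
population sample variances on sample means across all (site × species)
populations with positive mean and variance — either plain OLS
(`variant="fixed"`) or with crossed random intercepts for species and
site (`variant="mixed"`, ML via `MixedLM` with variance components).
The slope `b` is the mean-variance scaling exponent; `b < 2` means CV
falls as abundance rises, so habitat change that shrinks populations
also destabilizes them.

## Diversity

Species diversity is `exp(−Σ p_i ln p_i)` over per-species abundances
summed across all surveyed years (Hill number of order 1; natural log,
the exponential makes the result base-free). Richness counts species
seen at least once; Chao1 uses the bias-corrected form
`S_obs + F₁(F₁−1)/(2(F₂+1))` — defined even without doubletons — and is
only computed on integer counts.

Phylogenetic diversity is the abundance-weighted mean pairwise distance:
`MPD_w = Σ_{i≠j} p_i p_j d(i,j) / Σ_{i≠j} p_i p_j` with `d` the
patristic distance on an ultrametric tree and self-pairs excluded;
ordered and unordered pair weighting coincide because `d` is symmetric.
With the `weighted=False` flag every present species gets equal weight
(the plain mean over unordered pairs). Because weighted MPD correlates
with species diversity, analyses use residual MPD — the residuals of an
OLS fit of MPD on diversity — computed within one dataset (one taxon) at
a time, never pooled across datasets whose correlation structure may
differ.

## Landscape gradients

The eight per-site variables (urban %, cropland %, heterogeneous
agriculture %, woodland %, seminatural open %, sealed soil,
agricultural inputs in k€ per agricultural-area unit per year, and a
Shannon complexity index over land-use category areas) are standardized
and decomposed by correlation-matrix PCA. Exactly two components are
always retained and varimax-rotated with Kaiser normalization
(row-communality weights; tolerance 1e-8, iteration cap 1000, rotation
via `statsmodels`). Axis identity is assigned deterministically — the
rotated axis with the larger summed |loading| on urban + sealed soil is
the urban gradient — and each axis is sign-oriented so urban
(respectively cropland) loads positively, so no PCA sign indeterminacy
reaches the SEM. Urban scores are then log-transformed as
`ln(score − min + 1)` (rotated scores can be negative; the shift is the
minimal one and is recorded in the output metadata). The log transform
is applied after rotation.

An orthogonal rotation preserves each variable's communality and the
total variance of the retained pair exactly — these are the invariants
tested. It does *not* in general keep the rotated loading columns
orthogonal (that would require equal eigenvalues), so no such property
is asserted.

## Piecewise SEM

The causal structure is a DAG over per-site summaries: urban and
agricultural gradients (exogenous) → species diversity and residual-MPD
phylogenetic diversity (models 1–2); gradients + both diversities →
population stability and population asynchrony (models 3–4); the two
components → community stability (model 5). Each endogenous variable is
fit by its own regression with all variables z-scored, so slopes are
standardized. Error structures per regression: iid OLS; GLS with
`ρ(d) = exp(−d/r)` or `exp(−(d/r)²)` spatial correlation, the range `r`
profiled by maximum likelihood on a log grid and refined by bounded
scalar minimization (no nugget); or a one-factor random intercept
(e.g. region), fit by ML. AIC for a multi-model SEM is the sum of the
component-model AICs (piecewise SEM has no joint likelihood); buffer
variants of the landscape table are compared by this summed AIC, and
only within one error-structure family.

**d-separation.** Global fit is tested on the basis set of independence
claims the DAG implies: all non-adjacent pairs, conditioned on the
union of the parents of both variables, with the topologically later
variable as the regression response. Pairs whose members have an
*identical* parent set are excluded — this covers exogenous–exogenous
pairs, whose association the model leaves free, and sibling responses
of the same saturated regression, for which the causal ordering implies
no testable direction. For the five-model structure this leaves four
claims (each gradient and each diversity versus community stability).
Claim p-values combine into Fisher's `C = −2 Σ ln p_i`, compared to
χ² on `2k` degrees of freedom; p-values are clamped below at 1e-16 so
underflow cannot produce an infinite C, and an empty basis set returns
`(0, 0, 1)` exactly.

One numerical subtlety is intrinsic to the analysis: community
stability is an exact linear function of its two parents (the additive
partition identity), so any claim regression conditioning on both
components has residual variance at rounding level and its test
statistic would be noise. When the conditioning set explains the
response to within 1e-9 relative residual variance, the claim is
treated as trivially satisfied (p = 1, logged): conditional on its
parents the response is constant, so no conditional association is
possible. Calibration of the d-sep test is checked on noisy
linear-Gaussian data, where this branch never triggers and the
rejection rate under the true DAG is nominal (5% ± 2% over 500
replicates in the acceptance suite).

**Path effects.** The strength of a directed path is the product of its
standardized coefficients, with any coefficient at `p ≥ α` (default
α = 0.05) set to zero; marginally significant edges are not special-
cased. Effects "via" a variable group the paths by their first
mediating node, so each total is exactly the sum of its "via" rows and
also exactly the sum of its per-source rows. A group in which every
path contains a zeroed edge is reported `NS`.

## Synthetic data generator

The generator defines the study conditions for all simulation-based
tests. Per dataset:

- **Landscape.** Two independent standard-normal latent gradients per
  site. Each of the eight observed variables is an affine transform of
  a fixed linear combination of the latents plus independent normal
  noise (sd 0.3 by default): urban and sealed soil load on the urban
  latent (1.0, 0.9), cropland and agricultural inputs on the
  agricultural latent (1.0, 0.9), woodland mostly opposes the urban
  axis (−0.45, −0.2), heterogeneous agriculture and seminatural open
  mostly oppose the agricultural axis (−0.2/−0.15, −0.45), complexity
  opposes both (−0.3, −0.3). The magnitudes were chosen by analysing
  the noiseless varimax optimum so that the rotated axes coincide with
  the planted latents (recovery |r| > 0.99 at low noise); percentage
  variables are centered at 30 with scale 5, keeping them inside
  [0, 100] with overwhelming probability (clipped defensively).
  Coordinates are uniform on a 10 × 10 square; the landscape has no
  spatial autocorrelation by design.
- **Occupancy and abundance.** Species presence at a site is Bernoulli
  with logit `b₀ + β_ud·u + β_ad·a + δ_s` (`b₀ = 1`, species effect
  δ_s ~ N(0, 0.5²)); per-species base log mean abundances are uniform
  on `[ln 5, ln 200]`, shifted by the gradient effects on mean
  abundance. Default causal slopes: −0.4 (each gradient → diversity),
  −0.25 (→ mean abundance), +0.15 (→ population CV, implemented as a
  site-level multiplier on the Taylor intercept `c`). Signs encode
  habitat degradation lowering diversity and abundance and raising
  population variability.
- **Dynamics.** `N_it = μ_i exp(s_i(a e_t + √(1−a²) η_it) − s_i²/2)`
  with `e_t` a shared site-year factor, `a ∈ [0, 1]` the synchrony
  loading, `η_it` independent noise, and `s_i² = ln(1 + c μ_i^{b−2})`,
  which gives `E[N] = μ` and `Var(N) = c μ^b` exactly (defaults
  b = 1.61 — the steepest of the three empirically motivated exponents —
  and c = 1). The log-scale correlation between any two species is
  `a²`, giving continuous synchrony control; the implied closed-form
  synchrony `φ = [Σ c μ_i^b + Σ_{i≠j} μ_i μ_j(e^{a² s_i s_j}−1)] /
  (Σ √(c μ_i^b))²` is exported per site as ground truth. Abundances
  stay continuous by default so the Taylor exponent is exact; a Poisson
  observation switch produces integer counts (enabling Chao1) at the
  cost of extra variance. Note that perfect proportionality at `a = 1`
  additionally requires equal `s_i`, which holds for any abundance mix
  when b = 2; with b ≠ 2, φ at full loading approaches but does not
  reach 1.
- **Tree.** A pure-birth tree over the species pool (dendropy), tip
  edges extended past the final speciation event by an exponential
  increment, scaled to unit depth and made exactly ultrametric; tips
  are labeled `sp1..spN`. No trait evolution on the tree.
- **Seeding.** One global seed feeds a hierarchical `SeedSequence`
  stream (tree / landscape / communities), so any sub-stage is
  reproducible in isolation and identical configs give byte-identical
  outputs.

Default sizes (200 sites, 30-species pool, 11-year series) sit in the
middle of the motivating monitoring schemes (130–269 sites, 7–75
species, 6–17 years). What the generator does *not* emulate: detection
error and other observation noise of citizen-science protocols,
temporal autocorrelation or trends in the environment, species
interactions, spatially autocorrelated landscapes, and gaps within a
site's series. Tests passing on these simulations therefore validate
the estimators and their composition under the stated factor model, not
robustness to those real-data features.

## Pipeline

Stages run in a fixed order: site filtering by minimum series length
(≥ 3 years required; thresholds of 4–8 years are typical for real
schemes), stability partition with degenerate-community exclusion,
diversity metrics, gradient PCA computed on the retained sites only (so
exclusions propagate into the ordination), merge, bivariate stability
regressions (stability on the two gradients; stability on the two
diversity measures), piecewise SEM, and the path decomposition. Every
stage writes a TSV/JSON artifact, so a run can be resumed from any
stage's table; reports contain no timestamps and a fixed seed yields a
byte-identical bundle. Duplicate (site, species, year) rows are summed
with a warning. The run metadata records every convention flag
(variance denominator, log bases, α, rotation flavor, MPD weighting).

## Problem sizes in the checked properties

The test and acceptance suites use: 1000 random matrices for the
partition identities; 100 replicate communities × 1000 years per
synchrony loading on the five-point grid; 500 populations × 200 years
for Taylor recovery; 500 replicate datasets of 269 sites for d-sep
calibration; 300 sites for gradient recovery; 60-site pipelines for
determinism. These sizes give Monte-Carlo error comfortably below the
stated tolerances (e.g. binomial SE ≈ 1% for the rejection rate).

## Known limitations

- No detrending or temporal-autocorrelation correction in the stability
  measures; variability estimates grow with series length, so short
  series understate long-run variability.
- No null-model standardized effect sizes for MPD; no phylogenetic
  inference (trees are inputs).
- The spatial GLS ignores uncertainty in the estimated range when
  computing coefficient p-values (as common in profile-ML practice) and
  fits no nugget.
- AIC sums across component models are a pragmatic aggregate for buffer
  selection, not a joint-likelihood criterion.
- Chao1 requires counts; on continuous simulated abundances it is
  reported as missing.
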