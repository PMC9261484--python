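# Methods

This note records the models, conventions and numerical choices behind
`trophicniche`, and what the synthetic-data tests do and do not
demonstrate about real survey data.

## Gut-content indices

Diet composition within a group of fish is summarized per prey taxon by
%N (share of prey individuals), %W (share of prey wet mass) and %FO
(share of guts containing the taxon). Two conventions are fixed here:

- **%FO denominator is the number of non-empty guts.** Occurrence is a
  statement about feeding fish; with 121 fish and 22.3% vacuity, a taxon
  found in 25 guts has %FO = 25/94 ≈ 26.6%, which is the convention that
  reproduces the packaged reference table. Groups consisting entirely of
  empty guts are reported as flagged `empty_groups`, never as rows of
  zeros.
- **IRI uses the parenthesized Pinkas form** `(%N + %W) × %FO`. The flat
  reading `%N + %W × %FO` is not a percentage-scale index and does not
  reproduce the reference table's normalized column; the package
  verifies the parenthesized form against that table to ±0.1 in the
  acceptance tests.

Censored numerals printed as `<0.01` are parsed to half the bound
(0.005, the midpoint convention), isolated in one function
(`data_model.parse_censored`). Blank cells in the packaged tables are
missing values (prey absent), which downstream compositional operations
treat as zero contribution.

The Schoener overlap α = 1 − ½ Σ|P_xi − P_yi| renormalizes its inputs to
proportions first, so printed percentage columns summing to 99.9 from
rounding are handled safely. α ≥ 0.6 is flagged as conventionally
"significant" overlap. The aggregation level (taxon vs category) is a
caller choice with taxon as default: published overlap matrices in this
literature are sometimes computed from unpublished per-station data and
cannot generally be reproduced from pooled tables, so pairwise published
values are not treated as test oracles. Habitat-origin roll-ups keep
terrestrial (T) prey as their own bin and put taxa without an assigned
origin in an explicit `unknown` bin so shares always total 100.

## Trophic position and screening

TP = TP_base + (δ¹⁵N − δ¹⁵N_base)/TDF with defaults TDF = 3.4‰ and
TP_base = 1 (baseline resources such as sediment organic matter are
assigned trophic level 1). Baseline matching precedence is
(estuary, station, season) → (estuary, season) mean → estuary mean, each
fallback logged: baselines are typically measured for only a subset of
systems, and averaging across stations is a disclosed approximation, not
a silent default. The C/N lipid screen excludes records **strictly
above** 4 (C/N = 4.0 is kept); records without a C/N value are kept with
a warning since the screen cannot be evaluated.

## Ellipse areas and the Bayesian model

SEA = π√(λ₁λ₂) with λ the eigenvalues of the 2×2 sample covariance
(n − 1 denominator); SEAc = SEA·(n−1)/(n−2). The correction matters:
E[√det S] ≈ √det Σ · (1 − 3/(2n)), and the (n−1)/(n−2) factor cancels
this bias almost exactly — the test suite confirms unbiasedness over 500
replicates at n = 50.

The posterior over SEA uses a conjugate Normal–inverse-Wishart model
with a deliberately vague prior: prior degrees of freedom ν₀ = 3 (just
proper in two dimensions), prior scale 0.01·I ‰², prior mean 0 with
prior precision κ₀ = 10⁻³ (so the data dominate for any realistic n).
Draws of Σ from the inverse-Wishart posterior map to areas π√det Σ.

## Probabilistic niche-region overlap

The α-level niche region of a group is the elliptical contour of its
bivariate normal containing probability mass α (Mahalanobis radius²
= χ²₂(α)); overlap of A onto B is the probability mass of A's
distribution inside B's region — a mass, not an area ratio, and
directional by construction. Per posterior draw of both groups'
(μ, Σ) (10,000 iterations by default), the mass is estimated with 200
Monte Carlo points; the reported value is the posterior mean with a 95%
percentile credible interval. Two groups drawn from the same
distribution therefore overlap at ≈ 95% for α = 0.95, which is the
calibration the acceptance tests check. 200 points per draw puts ≈ 0.1
percentage-point Monte-Carlo noise on the posterior mean at 10,000
iterations, negligible against posterior spread.

## Permutation statistics

- PERMANOVA pseudo-F comes from the sums-of-squared-distances identity
  (equivalent to the Gower-centred formulation); on Euclidean distances
  of univariate data it equals the classical one-way ANOVA F exactly.
  Degrees of freedom are (a − 1, N − a).
- p-values use the add-one convention p = (#{F* ≥ F} + 1)/(n_perm + 1),
  so p ≥ 1/(n_perm + 1) and is never 0. When the number of distinct
  label arrangements is small (≤ min(n_perm, 10,000)) the full group is
  enumerated instead and p is exact.
- Defaults: 9999 permutations for PERMANOVA/ANOSIM (exposed); 999 for
  SIMPROF and RDA forward selection. Pairwise PERMANOVAs are adjusted by
  Benjamini–Hochberg FDR over the pair family. Only one-way designs are
  supported; single-factor analyses are run per factor.
- ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2),
  M = n(n−1)/2, on average-ranked distances.
- SIMPER decomposes the average **between-group** Bray–Curtis
  dissimilarity into exact per-taxon terms |x_ik − x_jk|/Σ_m(x_im+x_jm)
  averaged over cross-group sample pairs; contributions sum to 100% and
  the cutoff set is the taxa reaching a cumulative 80% by default.
- SIMPROF tests a node's samples for multivariate structure: the ordered
  Bray–Curtis profile statistic π is compared against profiles obtained
  by permuting each variable independently across the node's samples —
  one batch estimates the expected profile, an independent batch gives
  the null distribution of π. The tree is pruned top-down: a
  non-significant node becomes one output group. Because the recursion
  tests several nodes, callers wanting the family-wise split rate
  controlled should lower the per-node alpha (the recovery tests use
  0.01); the per-node test is close to nominal but slightly liberal
  (≈ 7% at nominal 5% in the suite's calibration check), a known
  property of plugging in an estimated expected profile.
- RDA centres both response and covariates (the intercept is absorbed),
  selects covariates forward by permutation tests on reduced-model
  residuals at 0.05, reports Ezekiel-adjusted R² and the eigenvalues of
  the fitted-value decomposition, and partitions adjusted R² across
  named covariate sets into unique fractions (full minus
  others-only models) and the shared remainder. Collinear covariates are
  dropped with a warning before selection. A helper applies the
  customary log → centre → scale normalization for environmental
  covariates.

## Synthetic generator

The generator emulates the study design: 6 estuaries × 3 stations ×
4 seasons, ~5 fish per cell. Per fish the gut is empty with the
estuary's vacuity probability; otherwise the number of prey individuals
is 1 + Poisson(mean_items − 1) with mean_items = 20 (a feeding eel's
gut holds tens of small prey), taxon counts are multinomial with
Dirichlet-drawn per-fish probabilities (concentration 50: moderate
inter-fish diet heterogeneity — fish share the estuary composition but
individual guts are specialized), and individual prey masses are
lognormal (σ = 0.5) around per-taxon medians, making %W informative
beyond %N. Isotopes are bivariate normal per estuary × station;
baselines are emitted noiselessly at a fixed offset (8.5‰ ≈ 2.5 trophic
levels at TDF 3.4) below the consumer mean, so TP recovery is limited
only by isotope noise.

`paperlike_config()` anchors everything to the printed summary tables:
diet compositions are the per-estuary %IRI columns renormalized, vacuity
the printed rates, isotope means/SDs the per-station summaries (diagonal
covariances; SDs floored at 0.2‰ where a station had too few fish to
print one), per-cell sample sizes the design table's station counts
spread as evenly as possible over the four seasons, and per-taxon mass
medians proportional to the pooled %W/%N ratio (the relative mass scale
the printed composition implies) with the gammarid pinned at 0.1 g.
`default_config()` is a generic variant with strictly monotone
gradients: δ¹³C +1.5‰ and δ¹⁵N +0.8‰ per station step toward the sea —
seaward enrichment in carbon, and nitrogen highest at the seaward
station, as the study system shows. (The published per-station table is
itself not perfectly monotone in every estuary, so monotonicity is
asserted for the generic configuration, not the table-anchored one.)

`GroundTruth` carries what the configuration implies exactly: the
compositions, the niche parameters and π√det Σ per group, and — for the
diet — the large-sample %N/%W/%FO the Dirichlet-multinomial model
produces, with the absence probability computed in closed form from the
beta-binomial marginal averaged over the item-count distribution. The
recovery tests compare estimates against these implied values, which is
the honest oracle: at twenty-fold sample size the per-taxon %IRI error
stays within ±3 percentage points, and SEAc averaged over the 18
estuary × station groups of n = 100 is within 10% of the generating
ellipse area.

**What passing these tests shows — and does not.** The generator draws
clean parametric noise: no digestion-stage weight loss, no unidentifiable
prey, no tissue-turnover lag between diet and isotopes, no spatial
autocorrelation within stations, and empty guts independent of covariates.
Recovery under these conditions validates the estimators and their
implementation, not robustness to those field realities.

## Problem sizes and determinism

Simulation-based checks are sized to keep the full suite fast while
leaving comfortable statistical margins: 1000 null replicates (n = 20)
for PERMANOVA type-I error against binomial 95% bounds; 10,000 posterior
iterations for overlap calibration at n = 200 per group; ×20 scaling for
diet recovery. Every stochastic routine takes an explicit seed; the
pipeline derives per-stage seeds by hashing the stage name with the
user seed, so one seed yields byte-identical output bundles on rerun
while stages stay uncorrelated.

## Known limitations

- Overlap matrices computed from pooled composition tables need not
  match values computed from raw per-station data; only self-overlap and
  internally generated comparisons are exact.
- PERMANOVA/ANOSIM are one-way; no nested or factorial designs, no
  dispersion test (PERMDISP), no distLM/dbRDA.
- The niche model is bivariate normal; heavy-tailed or multimodal
  isotope clouds will inflate ellipse-based metrics relative to the hull
  metrics.
- No isotope mixing models, lipid-correction regressions or
  tissue-turnover modelling: samples are assumed lipid-extracted, with
  the C/N screen as the only chemical filter.
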