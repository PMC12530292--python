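# Methods

This note documents the statistical procedures implemented in `trophitv`,
the defaults and conventions chosen where the methodology is genuinely
open, and what the synthetic-data generator does and does not emulate.

## Diet quantification (MNI)

A validated detection table (one row per sample × sequence variant, each
variant assigned to a harmonised prey taxon) is reduced to an individual ×
taxon matrix by the Minimal Number of Individuals rule: the cell value is
the number of distinct variants of that taxon in that individual's faecal
sample.  The estimate is conservative — prey individuals sharing a genotype
collapse to one variant — and is biased only where taxa differ strongly in
genetic diversity; no correction is applied.  Upstream read filtering,
chimera/pseudogene removal and marker merging are out of scope: the input
contract is the post-validation variant table.  Duplicate (sample, variant)
rows are an input error unless deduplication is requested; more than one
sample per individual per campaign is always an error.  Young-of-the-year
individuals are removed by a metadata filter (`age_class`) before any trait
computation, because their diet differs systematically from older fish.

## Individual traits

* INW is Shannon diversity in natural log.  Natural log is the ecological
  convention and keeps typical values in the 0.8–1.7 range for diets of a
  handful of taxa.
* BIC is `V = 1 − Σ_j min(p_ij, q_j)`, the total-variation distance between
  the individual's proportions and the population diet.  The population
  unit is the sampling campaign.  The population diet `q` defaults to
  pooled MNI sums within the campaign (`sum` convention); the mean of
  individual proportions (`average`) is a config switch, because the two
  conventions differ when individuals vary in diet size and published
  work does not always state which was used.  Campaigns with one
  individual get `BIC = NaN` with a flag.
* Campaign summaries report sample SDs (n−1).
* Population size structure is the mean pairwise Euclidean distance between
  individuals in standardized (fork length, weight) space.  Standardisation
  uses the 1/n (population) SD — the scaling convention of ade4-style PCA,
  which the statistic is equivalent to: keeping all components of a PCA is
  a rotation, and Euclidean distances are rotation-invariant, so no
  explicit PCA is run.  With two individuals each variable contributes
  z = ±1 and the distance is 2√2.

## Ecological-opportunity estimators

Prey variables per campaign: mean per-point richness and Shannon diversity,
mean densities of Baetis and Heptageniidae (total and ≥ 5 mm, the cohort
split being inclusive) and Orthocladiinae, the CV (100·σ/μ, sample SD) of
each of those seven, and the mean pairwise Bray–Curtis dissimilarity
between points.  Habitat variables: mean and CV of substrate size-class
richness, maximum substrate size class (ordinal 0–10), water velocity,
depth, clogging (1–5) and vegetal development (1–5).  Notes:

* Densities are per Surber unit (0.05 m²); conversion to m² is
  presentational only.
* Bray–Curtis is computed on raw counts by default (`ln1p` switchable);
  the ln+1 transform is applied to the density estimators when they enter
  models (path analysis and seasonal models), not at summary time.
  Pairs of empty samples are excluded from Bray–Curtis: the dissimilarity
  of two empty communities is undefined, and coding it 0 or 1 would bias
  the campaign mean.
* Sampling effort differs between campaigns (45–90 points), so prey
  estimators are standardised to the minimum effort (n_sub = 45) by
  averaging the estimator over 1000 seeded without-replacement subsamples.
  Mean and CV estimators are each standardised independently under the
  same scheme.  When a campaign has exactly n_sub points the subsample is
  the full set and the plain estimator is returned.  Habitat estimators
  use all points (a config switch can extend standardisation to them).
* CV at zero mean is returned as NaN with a warning, never silently as a
  number; a single value is an error.

## Electivity null models

Taxa tested are those present in at least 5% of diet samples pooled across
campaigns (inclusive threshold); tests run per campaign.  Availability is
the permutation-standardised mean per-taxon density, normalised to
proportions — only relative abundance matters, and the classification is
invariant to rescaling.  Taxa consumed but absent from a campaign's surveys
get a pseudo-availability of half the smallest nonzero availability, with a
logged flag: dropping them silently would bias tests toward neutrality,
and a zero-probability resource would make observed consumption impossible
under the null.  Each of 1000 simulations redistributes every individual's
total MNI (over the tested taxa) as a multinomial draw proportional to
availability, conserving diet breadth while removing selectivity; draws are
made in canonical taxon order so results do not depend on column ordering.
The default aggregation statistic is the per-taxon total MNI across
individuals (mean per individual is switchable).  The envelope uses
empirical (linear-interpolation, type-7) quantiles at α/2 and 1−α/2;
observations equal to a boundary count as inside (conservative), so a
degenerate null classifies as neutral unless the observation actually
differs.  Under the null generative process the non-neutral rate is close
to, and slightly below, α because consumption totals are discrete.

## Path analysis

Variable pruning before modelling: (1) of each pair with |Pearson r| >
0.70, one member is dropped — processed from the highest |r|, preferring to
retain mean over CV variables, ties alphabetical; constant columns are
dropped first.  (2) VIFs are computed on the fixed-effects design
(OLS of each predictor on the others) and predictors with VIF > 5 are
dropped sequentially from the highest, same retention preference.

The structural hypothesis is a DAG with habitat variables pointing at prey
variables and at the trait, prey and size variables pointing at the trait,
and the trait sink-only.  Residual covariances are allowed among the
prey/size block and among habitat variables; they are estimated as
residual correlations (Pearson tests on parent-adjusted residuals) and
count as adjacency for d-separation.  Each endogenous variable gets a
linear mixed model with crossed random intercepts for site and year
(variance-component encoding; the factors are crossed, not nested, because
sites are sampled in multiple years).  Model-level conventions:

* Campaign-level regressions (all variables constant within campaign) are
  collapsed to one row per campaign before fitting; otherwise repeating
  campaign values across individuals would inflate the sample size of
  prey-on-habitat models.  Campaign-level predictors of individual-level
  responses are accepted as-is; the pseudo-replication caveat applies as
  in any design with shared covariates.
* Fixed-effect p-values use the large-sample normal approximation on
  t-ratios (no Kenward–Roger-style df correction); adequate at the
  design's sample sizes and implementation-independent.
* REML optimisation tries two quasi-Newton optimizers and keeps the better
  criterion (either can report convergence at a poor point), compares the
  criterion against the zero-variance boundary — where the GLS fit is
  exactly OLS — and takes the boundary solution when it is at least as
  good.  Fits with a variance component at zero are retained and flagged
  singular.
* Standardized estimates are `β·SD(x)/SD(y)` with sample SDs over the
  modelling frame; marginal/conditional R² are the fixed /
  fixed-plus-random shares of total variance (fixed + site + year +
  residual).

The union basis set contains one claim per non-adjacent pair: independence
conditional on the union of both variables' parents, with the
causally-downstream variable as response (the later in a deterministic
lexicographic topological order when neither descends from the other).
Claims are tested with the same random-effect structure as the structural
models; p-values combine into Fisher's C = −2 Σ ln p with df = 2k, and
p > 0.05 indicates the data are consistent with the DAG.  A saturated
model reports C = 0 with df = 0.

Backward selection refits after every single removal, in four steps:
(i) drop non-significant correlated-error links; (ii) sequentially drop
non-significant paths into the trait, highest p first (ties alphabetical);
(iii) drop prey and size variables left without a path to the trait, along
with their incoming edges and links; (iv) sequentially drop non-significant
habitat→prey paths, highest p first across all prey models.  Habitat
variables left with no edges are removed.  The procedure is deterministic
and idempotent.  Effects are decomposed per habitat variable as direct
(standardized path to the trait, 0 if absent), indirect (sum over prey
mediators of products of standardized estimates), and total = direct +
indirect; the decomposition does not depend on mediator ordering.  The BIC
model uses campaign size variability as the size variable; the INW model
uses individual fork length and weight.  Trait responses are modelled
untransformed.

## Seasonal contrasts

Campaign-level variables retained by the path models are tested with a
mixed model (season fixed effect; site and year random intercepts; prey
abundance variables ln+1 transformed first — in the pipeline this happens
once, when the campaign table is built).  Seasons are taken from an
explicit metadata column and never inferred from dates, because month-to-
season assignment near season boundaries is a judgement call that belongs
to the data owner.  All pairwise differences of estimated marginal means
are tested with a Tukey-style adjustment via the studentized-range
distribution (k groups, residual df); with two seasons this reduces exactly
to the unadjusted t-test, and adjusted p-values are never below raw ones.
Bonferroni is available as a fallback.  Residuals from a fixed-effects
`value ~ site + year` model are available as a display table.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with one root
seed split into named child streams so stage-level reruns reproduce
exactly.  Defaults echo the field design scale: 4 sites × 2 years × 3
seasons = 24 campaigns, 45–90 points per campaign, 30 faeces per campaign,
10 harmonised prey taxa.

1. Habitat: campaign means = site baseline + seasonal shift + noise;
   point values add a smooth sinusoidal gradient along the transect plus
   noise; ordinals are discretised onto the field scales.
2. Prey: expected density log-linear in point habitat; negative-binomial
   counts (dispersion 2) so spatial CVs vary realistically; Baetis and
   Heptageniidae get a seasonal large/small length mixture, with the large
   fraction dropping in autumn together with a seasonal density decline of
   the preferred mayflies.
3. Fish: site-specific size distributions; each fish forages over the
   points within a patch radius of its transect position, so its
   availability is the local prey mix.
4. Diet: items per faeces ~ 1 + Poisson(29) (a mean of 30 items keeps the
   finite-sample floor of BIC below 0.2, so heterogeneity effects are not
   swamped by multinomial noise); item taxa are multinomial with
   probability ∝ preference × local availability × a per-individual
   log-normal jitter whose scale is the heterogeneity parameter
   (default 1.0, giving campaign-mean BIC ≈ 0.35 and INW ≈ 1.5 —
   magnitudes typical of riverine fish diet studies).  A direct habitat
   channel into trait variation can be enabled by letting campaign habitat
   modulate the jitter scale.
5. Detections: each item draws a genotype uniformly from its taxon's pool
   (pool sizes 6–30); a sample's variants are the distinct genotypes, so
   recovered MNI ≤ items consumed, saturating exactly as the conservative
   estimator does.

Two monotone generator properties are verified by test: campaign-mean BIC
increases with the heterogeneity parameter, and with more local foraging
when prey are spatially heterogeneous.

A separate linear-Gaussian layer (`simulate_path_data`) plants *exact*
standardized path coefficients: campaign-level H, P (= bH + noise, unit
variance) and S, an individual-level trait with total variance 1
(direct·H + c·P + size·S + site + year + residual), so planted raw
coefficients are the planted standardized effects.  This layer is what the
d-separation calibration and the effect-recovery checks use, because the
mechanistic generator's implied standardized effects are not analytic.

### What the generator does not emulate

False positives/negatives of the metabarcoding pipeline, prey genetic
diversity varying between campaigns, river geometry beyond a 1-D transect,
fish movement between campaigns, and ontogenetic diet shifts (size affects
nothing in the mechanistic layer).  Passing tests therefore demonstrate
correctness of the estimators and inference machinery under a controlled
generative model, not robustness to every field artefact.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use sizes chosen to keep their error small relative to
the tolerance tested: 200 replicate campaigns (electivity calibration),
200 replicates of a 40-campaign × 10-individual study (d-separation
calibration), 30 (test) / 10 (script) replicates of 40 × 30 for effect
recovery, and 50 replicates per grid point for the generator monotonicity
checks on a reduced 6-campaign study.

## Known limitations

* Claim tests and path p-values share the normal approximation; at very
  small campaign counts the d-separation test is mildly liberal.
* The Tukey adjustment uses the large-sample residual df rather than a
  per-contrast Satterthwaite df.
* The occurrence filter and electivity statistic are the stated defaults;
  alternatives are exposed as switches but not jointly validated.
* The benchmark against the study's deposited diet dataset requires
  downloading the archive separately (see `tests/test_acceptance.py`);
  it cannot run offline.
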