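# Methods

## Niche metrics

A group's trophic niche at a site is summarized by the standard ellipse of
its (δ¹³C, δ¹⁵N) samples. With sample covariance Σ (n−1 denominator, fixed
and not configurable), the 1-SD ellipse has semi-axes √λ₁, √λ₂ (the square
roots of Σ's eigenvalues) and area SEA = π√det(Σ); for bivariate-normal data
it covers 1 − e^(−1/2) ≈ 39.35% of the distribution. No 95%-coverage scaling
is applied anywhere. SEA is biased low in small samples by a factor
(n−2)/(n−1); SEAc = SEA·(n−1)/(n−2) removes this bias exactly under
normality, which is why SEAc is used throughout and why requesting SEAc with
n ≤ 2 is an error rather than a silent fallback.

Ellipses are computed only for site × group (and site × taxon) cells with at
least 5 samples; the threshold is configurable but must be ≥ 3, where the
correction is defined. Distances and areas are computed in raw ‰ units on
unscaled axes — the two isotope axes are not standardized, so a ‰ of δ¹³C
and a ‰ of δ¹⁵N count equally. Rank-deficient covariances (collinear data)
give SEA = 0; such rows are excluded from log-scale analyses with a warning
rather than being offset by an arbitrary epsilon.

Trophic dissimilarity within a functional group is the arithmetic mean of
Euclidean distances between all unordered pairs of taxon centroids. Taxon
centroids require n ≥ 2 records (the minimum that makes the centroid a real
mean, deliberately weaker than the ellipse filter); with fewer than two taxa
the dissimilarity is undefined and propagates as missing, never as 0. The
group-level SEAc pools all individual records of the group at a site rather
than averaging taxon-level ellipses; the taxon level is captured separately
by the expansion indicator (the unweighted mean SEAc over the group's
qualifying taxa).

## Effect models

Responses are natural-log metrics (log SEAc, log dissimilarity). The main
model has functional group × land use × climate zone fixed effects and a
site random intercept, REML-fitted (statsmodels MixedLM). Factors that a
subset leaves with a single observed level are dropped from the fixed part
with a warning. The optional taxon-identity random effect is implemented as
a taxon-within-site variance component — statsmodels supports variance
components nested in the grouping factor, not fully crossed effects; at the
site counts this package targets the difference is immaterial for the
fixed-effect contrasts, and the component is off by default.

Contrasts are estimated-marginal-mean differences: model predictions on a
balanced grid of all factor combinations, averaged with equal weight per
cell (proportional weighting is not the default because the balanced grid is
what makes contrasts comparable across unbalanced strata). On a balanced
design these reduce exactly to simple factor means. Contrasts are formed on
the log scale, then back-transformed: percent = (e^est − 1)·100 with
delta-method SE = e^est·se·100. Confidence intervals use the normal
approximation throughout — reproducible and adequate at the design sizes
used here; Satterthwaite-type small-sample corrections are a possible
extension. Per-group contrasts are reported with individual CIs and no
multiple-testing correction; users comparing many groups should adjust
accordingly.

Moran's I on site-level residuals uses row-standardized k-nearest-neighbour
weights (k = 5) on great-circle distances and a seeded permutation null
(default 999 permutations, two-sided around E[I] = −1/(n−1)). A permutation
rather than analytic null keeps the test exact under the permutation
distribution at any n.

## Synthetic communities

The generator emulates the hierarchical structure the analysis assumes:
strata (climate zone × land use) contain sites; each site holds several taxa
per functional group; each taxon contributes bivariate-normal samples around
its centroid. Within-taxon covariance Σ_w controls niche expansion;
isotropic dispersion τ²I of taxon centroids around the group centroid
controls partitioning (isotropy keeps the partitioning knob one-dimensional
and the expected pooled covariance closed-form: τ²I + Σ_w). Treatment
effects are multiplicative factors α on Σ_w and/or τ²; because the area is
π√det(Σ) for a 2×2 covariance, scaling the full covariance by α scales the
area by exactly α, so an area multiplier α corresponds to a log-scale
contrast of ln α. The site random effect is a covariance multiplier
e^(b_site), b_site ~ N(0, site_sd²), i.e. additive on log areas — the
generator is correctly specified for the fitted model by construction, which
is a statement about the tests, not about nature.

Defaults: 4 taxa per group (3 for herbivores, 5 for microbivores, matching
the relative richness of the taxon pools), 10 samples per taxon, Σ_w =
[[1.5, 0.2], [0.2, 1.0]] ‰², τ = 1.5 ‰, site_sd = 0.3 — within-taxon spreads
of ~1–1.5 ‰ per axis and between-taxon centroid separations of ~2–3 ‰ are
typical of within-site soil fauna isotope data, and site_sd = 0.3 puts
~35% site-to-site multiplicative variation on areas. Taxon names are drawn
from the real high-rank taxon lists of each functional group so the
group-mapping layer is exercised end to end. All draws come from one seeded
generator in a fixed order (strata in config order; sites; groups sorted by
name; taxa), so output is reproducible bit-for-bit from (config, seed).

An optional `fixed_taxon_centroids` mode places taxon centroids
deterministically on a variance-matched circle (radius τ√2, so centroid
covariance is exactly τ²I). This exists because a *random*-centroid world
can never hold partitioning truly constant: with finitely many taxa the
realized centroid dispersion fluctuates between sites, which is genuine
partitioning variation. The fixed mode is what "expansion-only variation"
means precisely.

What the generator does not emulate: isotopic baselines and their spatial
variation, trophic fractionation chains, non-normal or skewed niche shapes,
unbalanced taxon detection, and covariance between taxa. Passing tests
therefore demonstrate that the estimators and models recover the effects
they target under the assumed hierarchical-normal structure, not that field
data meet that structure.

## Decomposition relations

Log group SEAc is regressed on each indicator (mean taxon SEAc;
dissimilarity) with a site random intercept; slopes are reported with
normal-approximation CIs and marginal/conditional variance explained
(fixed-effects-only vs fixed-plus-site, as fractions of total variance).
Because the *measured* dissimilarity carries centroid-estimation noise
proportional to Σ_w/n, a scenario that varies only expansion still perturbs
measured dissimilarity slightly; with a near-constant covariate the raw
slope is ill-posed (a ratio of two vanishing quantities). The discriminating
statistic in validation is therefore variance explained: the targeted
relation must carry the signal (positive slope, dominant marginal R²) and
the non-targeted relation must explain ~nothing.

## Validation problem sizes

The validation experiments (tests and `scripts/acceptance.py`) use: 10⁵
draws for the coverage check; 5,000 replicates of n = 5 samples for the
SEAc bias check; 100 replicates of a 100-sites-per-stratum,
two-functional-group design for recovery of a 1.35× land-use multiplier
(200 replicates for the α = 1 type-I check); 40 replicates per target of a
40-sites-per-stratum design at α = 1.6 for the expansion/partitioning
discrimination; and 1,000 (calibration) / 200 (power) replicates of n = 100
sites for Moran's I. These sizes make each Monte-Carlo check decisive (SEs
well below the asserted tolerances) while keeping a full run to a few
minutes on one core.

## Known limitations

- Crossed taxon random effects are approximated (see above).
- Degrees-of-freedom corrections beyond the normal approximation are not
  implemented.
- The dissimilarity estimator is positively contaminated by within-taxon
  variance through centroid noise (order tr(Σ_w)/n per centroid); at the
  default 10+ samples per taxon this is small relative to typical centroid
  separations but it is not corrected.
- Quadratic-in-isotope-SD model variants and information-criterion
  comparisons between them are not part of the default surface.
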