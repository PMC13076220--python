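# isoniche

Isotopic trophic-niche analysis for soil-animal communities: standard-ellipse
niche metrics, a niche-expansion vs niche-partitioning decomposition, and
mixed-model contrasts of land-use and climate effects — with a synthetic
community generator that provides analytic ground truth for every stage.

## The problem

Soil fauna (springtails, mites, earthworms, spiders, ...) drive decomposition
and nutrient cycling through their trophic activity. Paired stable-isotope
measurements place each animal in a two-dimensional trophic space: δ¹³C
tracks the basal resource it ultimately feeds on, δ¹⁵N its trophic level.
The *trophic diversity* of a functional group (herbivores, detritivores,
microbivores, predators, mixed feeders) at a site is the spread of its
members in that space, and ecologists want to know how it differs between
functional groups, land-use types and climates — and whether differences come
from individual taxa broadening their niches (*expansion*) or from taxa
spreading apart (*partitioning*).

`isoniche` is aimed at stable-isotope ecologists who have (or simulate)
sample-level δ¹³C/δ¹⁵N tables with site and taxonomic labels and want a
tested, scriptable pipeline from records to effect sizes.

## The statistics

For a group's points in the δ¹³C–δ¹⁵N plane with sample covariance Σ, the
**standard ellipse area** is

    SEA = π · √det(Σ)        (‰², the 1-SD ellipse, ≈40% coverage)

corrected for small samples as **SEAc = SEA · (n−1)/(n−2)** and computed only
for groups with n ≥ 5 samples per site. The expansion indicator is the
unweighted mean SEAc of the group's taxa; the partitioning indicator is the
mean pairwise Euclidean distance between taxon centroids. Effects of land use
and climate on log SEAc are estimated with linear mixed models (site random
intercept), summarized as estimated-marginal-mean contrasts on the log scale
and back-transformed to percent differences, (e^est − 1)·100. Residual
spatial autocorrelation is checked with Moran's I on k-nearest-neighbour
weights with a permutation null.

## Worked example

`examples/04_landuse_contrast.py` generates 100 woodland and 100 agricultural
sites whose agricultural group covariances are inflated by a factor 1.35
(a true +35% effect on ellipse area), then recovers the effect:

```
site SD (log scale): 0.338 (generator used 0.3)
agriculture - woodland: +0.3280 log units (SE 0.0568)
back-transformed: +38.8% +/- 7.9% (95% CI +24.2% to +55.1%)
true effect: +35.0%
```

The point estimate (+38.8%) is one Monte-Carlo draw around the true +35%,
and the 95% CI covers it. The other examples cover delta-notation
conversion and functional-group assignment (`01`), ellipse fitting (`02`),
the synthetic generator and per-site metrics table (`03`), and the
expansion/partitioning decomposition plus the Moran's I diagnostic (`05`).

A thin CLI wraps the same functions:

```sh
isoniche simulate --preset landuse_expansion --seed 1 --out records.csv
isoniche metrics --in records.csv --threshold 5 --out metrics.csv
isoniche effects --metrics metrics.csv --contrast landuse
```

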