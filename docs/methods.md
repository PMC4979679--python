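# Methods

## Partition of pairwise beta diversity

For binary occurrence data the package uses the Sørensen-family partition:
with `a` species shared by two assemblages and `b`, `c` unique to each,
`β_sor = (b+c)/(2a+b+c)` is total dissimilarity, `β_sim = min(b,c)/(a+min(b,c))`
is the turnover (Simpson) component, and `β_sne = β_sor − β_sim` the
nestedness-resultant component. β_sim is invariant to richness differences;
β_sne is the part of total dissimilarity attributable to one assemblage being
a poorer subset of the other. Additivity is exact by construction; empty
assemblages are rejected rather than mapped to a 0/NaN convention, because
the pipeline filters them upstream. Only presence/absence is supported;
abundance-based variants are out of scope.

The functional partition substitutes trait-space volumes for species counts:
`a` is the volume of the intersection of two assemblages' convex hulls, `b`
and `c` their volumes outside the intersection. The same formulas then
measure functional turnover (hull regions replaced between sites) and
functional nestedness (one hull largely inside the other).

## Trait space

Four per-species indices are computed from six raw measurements, averaged
across individuals (up to six per species) *before* the index formulas are
applied:

* `eye_position = (head width across eyes − interocular distance) / Weber's length`
* `relative_leg_length = (hind femur + hind tibia) / Weber's length`
* `relative_mandible_length = mandible length / head width across eyes`
* Weber's length passes through as the body-size index.

Eyeless species carry zeros for both eye measurements, so `eye_position = 0`.
Because the mandible index divides by head width across eyes, an eyeless
species must also have zero mandible length; its index is defined as 0. The
simulator enforces this; real data violating it are rejected with a clear
error rather than silently patched.

Indices are centred and scaled to unit *sample* SD (ddof = 1; stated so
frozen test values are exact), turned into a Euclidean distance matrix, and
embedded by classical scaling: double-centre `−½D²`, eigendecompose, retain
eigenvalues above `1e−8`, and scale eigenvector `k` by `√λ_k`. Axis signs are
fixed by forcing the largest-magnitude coordinate on each axis positive, so
results are deterministic. A trait constant across species contributes a zero
column with a warning. Inputs are Euclidean by construction, so any
eigenvalue below `−1e−6·λ_max` aborts with a diagnostic instead of applying a
Lingoes/Cailliez correction. Downstream analyses default to all four retained
axes for beta diversity and to the first two axes for trait-space region
maps.

## Convex hulls and intersection volumes

An assemblage's hull is built with qhull on the species' coordinates
(duplicates removed first; no jitter). An assemblage needs at least
`n_axes + 1` species — the geometric necessity for a full-dimensional hull —
otherwise it is excluded and logged; affinely flat point sets (volume below
`1e−12`) are likewise excluded as degenerate. This filter is what removes
species-poor assemblages from the study design (112 pooled assemblages → 111
when exactly one is too poor).

Intersection volume stacks both hulls' facet halfspaces and looks for the
Chebyshev centre (largest inscribed ball) by linear programming. An
infeasible LP, or an inscribed radius ≤ 1e−10, means the intersection is
empty or lower-dimensional and the shared volume is 0 — touching polytopes
correctly share nothing. Otherwise the intersection polytope's vertices are
enumerated by halfspace intersection about that interior point and its volume
taken from their hull. The Monte-Carlo rejection-sampling oracle in the test
suite checks this machinery on random 2–4-D pairs within 3 standard errors;
a 2-D cross-check against an independent polygon-clipping library is exact to
1e−9.

## Null models and SES

* **Independent swap** (species composition): repeated attempts pick two
  distinct rows and columns; a checkerboard 2×2 submatrix is flipped. Row and
  column sums are preserved exactly on every iteration. The mixing schedule
  is 10 × (number of presences) attempts per null matrix, each null matrix
  restarted independently from the observed matrix — independent restarts
  avoid serial autocorrelation between null matrices. Both the multiplier
  and the default of 1000 iterations are configurable.
* **Trait-label shuffle** (functional composition): a uniform random
  permutation of the species-to-coordinate assignment among all species
  present in the season-year matrix, with the occurrence matrix held fixed.
  The pooled point multiset — and hence the pooled hull — is exactly
  invariant. Null iterations in which a shuffled assemblage fails the hull
  filter are dropped and counted.

`SES = (observed − mean(null)) / SD(null)` with sample SD (n − 1). A zero-SD
null yields an undefined SES (NaN, flagged) with observed and null mean still
reported; |SES| > 1.96 is tagged significant at α = 0.05.

RNG streams are structured: one seeded generator per (composition, season,
year), derived from the master seed via `SeedSequence` spawn keys, so
per-stratum results do not depend on execution order and adding strata never
perturbs existing ones.

## Pipeline

Blocks pool to site-level assemblages by union. Pairs are formed within each
(season, year) stratum only — never across years — either against the lowest
*retained* elevation (`vs_base`) or all pairwise. If the hull filter removes
the lowest site, the next-lowest retained site becomes the base for both
compositions, keeping species and functional rows on common pairs. Output is
one tidy row per (year, season, composition, pair) with observed and SES
triplets, the number of valid null iterations, and flags; a failed stratum is
logged and does not abort the others. Trend modelling on the output table
(mixed models, information criteria) is deliberately out of scope — the tidy
table is the hand-off point.

## Synthetic data

The simulator emulates the survey design the package targets: 8 sites at
300-m steps from 900 to 3000 m a.s.l., wet and dry seasons over 7 years, 4
replicate blocks per site, 92 species, up to 6 measured individuals per
species. Its purpose is ground truth, not realism in every respect.

* **turnover** — each species gets an elevational optimum drawn uniformly on
  [min − σ, max + σ] and occupies sites with Gaussian probability
  (`niche_breadth` σ, default 400 m — wide enough for ~30 species per site
  from a 92-species pool, the simplest model producing distance-decay).
* **nestedness** — species are assigned elevational ceilings (every ceiling
  level guaranteed represented), so each higher site's pool is a strict
  subset of each lower site's; species turnover is exactly zero by
  construction.
* **neutral** — every site independently draws species at a fixed target
  richness (`neutral_occupancy` × pool, default 0.30), the calibration case
  for the null models.

The dry season multiplies occupancy probability by `dry_season_factor`
(default 0.7; the source design reports only a qualitative seasonal effect,
so this is a free simulator parameter, not an estimate). In the nestedness
scenario a multiplicative thinning would break exact nesting, so the seasonal
effect is instead a stochastic one-step ceiling reduction, which preserves
subset structure; one maximal-ceiling species is exempt so the top site is
never emptied. Site-level presences are distributed to blocks with
per-block probability 0.7 and at least one block forced, so pooling blocks
recovers the site assemblage exactly.

Morphology: species mean indices are drawn from pool distributions (Weber's
length log-normal around 1.3 mm; the dimensionless indices uniform on ranges
typical of epigaeic ants), then raw measurements are reconstructed (head
width = 0.35 × Weber's length) and individuals add multiplicative log-normal
noise with CV 5% — positive traits, small intraspecific spread. With
`trait_coupling = c`, a species with elevational optimum at relative height
`h` has its mean indices contracted toward the pool centroid by the factor
`1 − c·h`, so at `c = 1` the highest-elevation species collapse onto the
centroid: functional nestedness with a known cause. A configurable fraction
of species (default 5%) is eyeless.

What the simulator does **not** emulate: abundance structure (occurrence
only), spatially explicit dispersal, phylogenetic signal, detection error,
and trait correlations beyond the single filtering axis. Passing calibration
and recovery tests therefore shows the estimator and null models behave
correctly under controlled structure, not that any particular field system
matches these generating assumptions.

## Problem sizes and numerical choices

Test and acceptance runs scale the study conditions down where iteration
counts, not conditions, are at stake: null distributions use 99–199
iterations (default 1000), calibration uses 10–20 replicate surveys of one
year/one season, and the functional-recovery checks use two sites and two
axes. Degeneracy tolerances: hull volume 1e−12, eigenvalue retention 1e−8,
inscribed-ball radius 1e−10, facet containment 1e−9. Ties and degenerate
inputs fail loudly (errors or logged exclusions) rather than silently.

## Known limitations

* Hull-based functional volume is sensitive to outlying species and, like
  all convex measures, cannot represent holes in trait space.
* Halfspace intersection in >4 dimensions is untested territory for this
  package; the study design needs at most 4.
* The independent swap's mixing schedule is a convention (10 × presences);
  extremely sparse or structured matrices may need more attempts for
  adequate mixing.
* SES inference treats the 1.96 band as a per-comparison test; no multiple
  comparison correction is applied to the tidy table.
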