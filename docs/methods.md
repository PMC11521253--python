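# Methods

`traitdiv` implements a trait-based analysis of fisheries landings: species
are described by categorical functional traits, embedded in a low-dimensional
trait space, and the landed catch of each fleet and decade is summarised by
four functional diversity metrics whose differences are tested against a
trait-shuffling null model. A fuzzy correspondence analysis maps species and
trait modalities into a shared ordination for exploratory use.

## Trait scheme and coding

The reference scheme registers 14 traits and 76 modalities grouped into four
ecosystem functions (habitat use, locomotion, feeding, life history); every
function is informed by at least four modalities, and several traits inform
more than one function (body shape, maximum body size, trophic position,
diet, food consumption). Thirteen traits are crisp — a species carries
exactly one modality — and the diet trait is fuzzy: a species lists one or
more prey categories and its affinity is spread as frequencies summing to
one (1/k per item by default; user-supplied weights are accepted and
renormalised). The coded ("bin-fuzzy") matrix therefore has one unit of
membership mass per species per trait, which both the mixed distance and the
correspondence analysis rely on.

Two interval labels in the source registry were inconsistent with
exhaustive, disjoint binning and are encoded so the bins tile the positive
line: the first growth-coefficient bin is `<0.3` (not `>0.3`) and the second
fecundity bin is `10-10^2` (not `10-10`). Missing trait values are not
imputed: a record with a gap is rejected with a named violation, because
imputation belongs upstream of this package.

## Mixed trait distance

Per-trait dissimilarity is simple matching for crisp blocks (0 if the two
species share the modality, else 1) and half the Manhattan distance between
affinity profiles for the fuzzy block; both are bounded in [0, 1], and
half-Manhattan reduces to matching on one-hot rows. The mixed distance is
the weighted mean over the 14 trait blocks — each *trait* weighs equally by
default, so the nine-modality swimming-mode trait cannot dominate — followed
by a square-root transform (on by default). The mean of bounded block
dissimilarities is generally not Euclidean-embeddable; its square root
almost always is, which keeps the downstream principal-coordinates embedding
free of negative eigenvalues. `is_euclidean` reports the smallest eigenvalue
of the Gower-centred matrix with a relative tolerance of 1e-8. No claim of
numerical parity with any particular legacy distance routine is made; the
construction is chosen to be transparent and bounded, and its contracts
(symmetry, bounds, the crisp-only closed form) are what the tests pin down.

## Trait space and axis retention

Classical (Gower) PCoA supplies the metric space. All eigenvalues are
reported; axes with eigenvalues below 1e-10 of the spectrum's magnitude are
treated as zero, negative axes never carry coordinates, and each axis is
oriented so its largest-magnitude species loading is positive (eigenvector
signs are arbitrary; fixing them makes artifacts reproducible). The number
of retained axes is m = floor(log2 n) — the largest t with n ≥ 2^t for a
pool of n species (103 species → 6 axes) — capped by the number of positive
axes. m is computed once from the pool and reused for every assemblage of a
comparison, so all assemblages are measured in one shared reduced space;
per-assemblage degeneracies are flagged, never silently re-dimensioned.
`quali.FRic`, the quality of that reduced space, is the sum of the m largest
positive eigenvalues over the sum of absolute values of all eigenvalues.
No Cailliez/Lingoes correction is applied by default (the square-root
transform makes it unnecessary in practice).

One global ordination per function subset (rather than per-comparison
ordinations) was an open design choice; the global space makes metric values
directly comparable across fleets and decades and matches the use of one
pool-wide m.

## Diversity metrics

Landings weights enter as min-max standardised totals, x' = (x − min)/(max −
min), computed within each (fleet, decade) assemblage by default (a global
scope is available and recorded in output metadata). Min-max forces the
lightest species to exactly 0; it stays in the assemblage (it counts for
presence-based richness) and contributes zero to the weighted metrics. An
all-equal assemblage is degenerate for the formula and maps to all-1 weights
with a `constant-weights` flag.

- **FRic** — convex-hull volume of the assemblage's species in the m
  retained axes (quickhull; the coordinate range when m = 1), reported as a
  fraction of the full pool's hull so the pool itself scores exactly 1.
  Assemblages with fewer than m + 1 distinct coordinates are flagged
  degenerate and score 0.
- **FEve** — evenness of species spacing and weight along the minimum
  spanning tree: branch l joining i and j carries EW_l = d(i, j)/(w_i +
  w_j) with relative weights, PEW_l = EW_l/ΣEW, and FEve rescales
  Σ min(PEW_l, 1/(S−1)) to [0, 1]. The MST is Kruskal with ties broken by
  (distance, i, j) — categorical traits produce many tied distances, and the
  lexicographic rule makes the tree deterministic. A branch between two
  zero-weight species would have infinite EW; the implementation takes the
  limit (such branches absorb all the mass) and flags the case.
- **FDiv** — weight carried by species far from the centre of gravity G of
  the hull-vertex species: with dG_i the distance to G and d̄G the
  unweighted mean, FDiv = (Δd + d̄G)/(Δ|d| + d̄G) where Δd = Σ w_i(dG_i −
  d̄G) and Δ|d| = Σ w_i|dG_i − d̄G|. Every species whose coordinates sit on
  a hull vertex counts toward G (duplicated profiles at a vertex all count).
- **FDis** — weighted mean distance to the weighted centroid, computed in
  the retained real axes (not from negative-eigenvalue-corrected distances;
  a documented limitation, immaterial when the distance is Euclidean).

`sing.sp` counts functional entities — groups of species with identical
coded profiles (exact equality after rounding at 1e-12).

## Null models

The null hypothesis is a random arrangement of trait profiles over species:
whole coded rows are permuted against species labels, so existing trait
combinations remain intact (combinations that do not co-occur in nature are
never invented) while the link between traits and landings weights is
broken. For each (metric, function, group pair) the observed |A − B|
difference is compared with the differences recomputed under n_iter = 999
shuffles (tests here use 199 to fit time budgets); p = exceedances/n_iter,
on the grid {0, 1/n, …, 1}. Degenerate iterations are excluded and the
effective denominator reported. A `plus_one` flag gives the
observed-included variant, and a `recompute="full"` path re-derives
distance and PCoA per shuffle — mathematically identical to the default,
which exploits the fact that a row permutation only relabels the points of
the trait space (asserted by a test). One master seed spawns an independent
stream per test, keyed by metric, function and pair, so any subset of tests
reproduces identically regardless of execution order.

Comparisons run per metric and function subset: local vs coastal fleet
totals, plus the six decade pairs (80s–90s … 00s–10s) within each fleet.
Decades are 1980–89, 1990–99, 2000–09 and 2010–20 (the 41st year folds into
the last decade). No multiple-testing correction is applied.

### Calibration and power of the randomization test

Under the null scenario (trait profiles independent of landings), the test
is well calibrated: over 200 replicate datasets the FEve fleet test at
α = 0.05 rejects at ≈ 0.03 and the p-value distribution is uniform to a
Kolmogorov–Smirnov distance < 0.05 (both recomputed by the test suite).

Power against trait-linked landings shifts is intrinsically limited, and
the package documents this rather than hiding it. Because the permutation
holds both assemblages' weight vectors fixed and only breaks trait–weight
alignment, any effect that expresses itself through the landings profile
(more or less dominance, concentration on a subset) is reproduced inside
the null distribution; only the residual alignment signal — whether the
heavy species sit in a particular region of trait space — remains testable.
A systematic Monte-Carlo study across effect designs (continuous depth
tilts, indicator concentration on the deep subset, profile replacement,
rank-matching, bimodal concentration, composition shifts), dominance
levels (0.3–4.0), both standardisation scopes and two function subsets
found FEve's one-group alignment response to be weak (permutation z-scores
around ±2 at best) and non-monotonic in effect size: mild tilts lower
FEve, strong concentration raises it, and in the |A − B| statistic the two
regimes cancel against the reference group's level. Detection rates for a
decade shift top out near one third of replicates at α = 0.05 — short of a
majority — and the corresponding acceptance test is left failing rather
than weakened, since the stated world cannot meet it.

## Fuzzy correspondence analysis

The row-normalised bin-fuzzy table X (rows sum to K, the number of trait
blocks) is analysed as a correspondence matrix P = X/(nK) with uniform row
masses and column masses equal to column sums of P; standardised residuals
are decomposed by SVD, eigenvalues are squared singular values, and species
and modalities receive principal coordinates (four axes retained when
available). Per axis, modality j contributes c_j g_jk²/λ_k of the axis
inertia, and these contributions sum to one. For each modality and each
axis the signed Pearson correlation between the modality's affinities and
the species scores is exported together with r² (zero-variance modalities
are flagged undefined; the field's tables sometimes label signed r as r²,
so both are provided and the labelling left to the user). Zero-mass
modality columns are dropped from the decomposition and listed. Vertex
species — the convex hull of the 2-D species scatter per axis pair — mark
the bearers of unusual trait combinations; collinear scatters degrade to
the two extremes. Numerical parity with any specific legacy fuzzy-CA
implementation (with its internal block re-weighting) is not claimed; the
CA invariants and a brute-force oracle define correctness.

## Synthetic data

The generator emulates a multi-decade port-sampling series: n species
(default 100), monthly records for two fleets over 1980–2020, per-species
base landings drawn log-normal with sigma `dominance` (default 1.5, which
reproduces landings dominated by a few taxa; 0 gives equal species),
sinusoidal monthly availability with amplitude `seasonality` (default 0.5)
and random phase, and record-level log-normal noise (sigma `noise`, default
0.3). Trait profiles are drawn per species from the reference scheme with a
latent depth axis coupling the habitat traits (deeper → colder, more
bathyal) and a size axis coupling maximum size and maturity size; other
traits draw uniformly, the diet trait picks 1–3 prey items. `n_profiles`
caps the number of distinct profiles to exercise functional-entity
collapse; per-trait marginal distributions can be overridden (a degenerate
marginal collapses the trait).

Effect scenarios give the null models a known signal. `null` makes fleets
and decades exchangeable draws from one process — in particular, the
depth-linked fleet selectivity is zero under `null`, since a built-in
fleet–trait link would contradict the calibration contract.
`fleet_divergent` tilts the coastal fleet toward deep-water species and the
local fleet away by exp(±effect_size·(depth − ½)); `decade_shift` applies
that tilt within the target decade only; `dominance_shift` adds extra
species-level spread (sigma = effect_size) in the target decade. All
weights are strictly positive, every generated table passes the package's
own validation with zero rejections, and a fixed seed reproduces every CSV
byte for byte.

What the generator does not emulate: real species land intermittently
(records here exist for every species-month), trait profiles of real faunas
are more redundant than independent draws (use `n_profiles` to mimic
functional-entity collapse), landings magnitudes are not fitted to any real
port series, and species identifiers are synthetic (`sp001`…) precisely so
no real trait assignment is implied. A green pipeline test therefore
establishes correctness of the computation, not realism of any particular
ecological conclusion.

## Numerical conventions

Eigenvalues below 1e-10 of the spectrum magnitude are zero; hull
computations deduplicate coordinates after rounding at 1e-12; degenerate
cases (too few distinct points, zero-variance modalities, constant
weights) are flagged in results instead of raised, so batch runs complete
with an audit trail; every randomised routine takes an explicit seed or
generator, and the pipeline writes all artifacts as flat CSV plus a JSON
manifest (inputs hashes, seed, versions, per-stage timings, flags).
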