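# Methods

## Spatial model

All geometry is planar, in kilometres, on a rectangular extent; degree-based
inputs must be projected before entering the pipeline. The analysis grid is
a flat-top hexagonal tessellation whose corner-to-corner diameter defaults
to 55 km — the approximate ground distance of 0.5° of arc, a unit size
chosen to neither inflate (larger cells) nor shrink (smaller cells) apparent
ranges. Cell ids are row-major and stable; a point on a shared boundary is
assigned to the lowest-id touching cell, so assignment is a function.
Tessellation correctness is enforced by area bookkeeping: the clipped cell
areas must sum to the extent area to 1e-6 relative.

Per-PA sampling is summarised two ways: record density (records per km²,
binned into the classes [0], (0,0.01], (0.01,0.1], (0.1,1], (1,10],
(10,130+] — decade steps between the empirically anchored extremes) and the
*sampled fraction*, the share of PA area within 1 km of any record (1 km
being the typical maximum distance between a collection event and its
recorded coordinate). Buffered discs use 32 quadrant segments, giving an
area error below 0.2%, well inside the tolerances used anywhere downstream.

## Sampling effort

The effort estimator is a disc-count density: raw effort at a record is the
number of records of any species within 50 km, divided by the disc area.
A species' effort is the mean over its records, normalised by the maximum
across species and clamped to (1e-5, 1−1e-5) — the correction formula is
undefined at exactly 0 or 1. The 50-km radius matches the neighbourhood
over which collection intensity is commonly smoothed; the disc-count form
is the simplest estimator consistent with an "average kernel density"
notion, and it is deliberately the *recorded* choice rather than an
inference about any particular historical implementation. A per-cell
variant (effort at hexagon centroids) is computed for mapping but does not
enter the species-level correction. Effort is attributed per species (mean
over its own records), not per cell; this is the reading most consistent
with correcting each species' own survey bias, and it makes the corrected
index a species property that aggregates over cells exactly like raw WE.

## Endemism correction

Per species: `A` = 1/range-size, clamped to the open unit interval;
`B = A × effort`; `C` rises linearly from 1e-5 at one record to 0.999 at
150 records and is constant beyond (the record-count distribution
saturates there); the corrected index is `A·B / (A·B + (1−A)(1−C))`. The
clamp constant ε = 1e-5 is the same constant the correction already uses
as its floor for `C`. The corrected index is strictly increasing in each
argument, so better sampling can only raise, never lower, a species'
corrected endemism — a property the tests check on a 20³ lattice. Cell
sums use the *unclamped* 1/range weights so that ΣWE over cells equals the
recorded species count to 1e-9 (each species contributes range × 1/range);
the cell-level corrected value is the sum of the per-species corrected
weights of the species present.

## Phylogenetics

Trees are handled as dendropy objects with Newick I/O; all branch lengths
are set to 1 because lengths are not comparable (or available) across
source trees — consequently PD counts nodes-to-root steps and PWE weights
clades equally per branch. PD is the rooted Faith variant: the summed
length of the minimal subtree connecting the species set *to the root*.
This reads "branches connected to the species" as the full spanning
subtree; it differs from the unrooted variant by the stem path of the
set's MRCA and is used consistently everywhere.

MRP encoding is Baum–Ragan: one binary character per non-root internal
node of each source tree (descendants 1, other taxa of that tree 0, absent
taxa `?`); polytomies contribute only their resolved nodes — no arbitrary
resolution is invented. Characters are scored by Hartigan's
minimum-mutation pass (exact on any arity, reduces to Fitch on binary
nodes), vectorised across characters with `?` as full ambiguity. The
supertree search starts from neighbour joining on MRP Hamming distances
(mismatch proportion over shared defined characters; 0.5 when none are
shared) and hill-climbs with nearest-neighbour interchanges; the ratchet
then alternates hill-climbing under perturbed weights (a random 25% of
characters doubled) and original weights, accepting candidates that do not
worsen the incumbent. Defaults: 200 iterations (8 suffice for the 6-taxon
recovery studied in the tests), deterministic under a fixed seed, and the
incumbent score is never degraded. On small problems the search provably
reaches the exhaustive-search optimum (checked against full enumeration of
all 105 six-taxon topologies).

"Proportion of lineages protected" weights branches by length (with unit
lengths, by count of branches whose clade range touches a protected cell);
the branch-count proportion is also reported. Branches whose clade has no
recorded range are excluded from the denominator — they carry no
observable signal.

## Distribution models

The environmental space is the first four axes of a PCA on the correlation
matrix (standardised layers) of 21 rasters. Suitability transforms:
Bioclim = min over axes of `2·min(F, 1−F)` with a midpoint ECDF `F` of the
training values and 0 outside the training envelope; Domain = Gower
similarity to the nearest training point (ranges from the training data);
Mahalanobis = `exp(−D²/2)` to the training mean and covariance (singular
covariance is a hard failure); GLM = unpenalised logistic regression of
presences against pseudo-absences. These are the classic formulations;
boosted trees, SVM and Maxent are deliberately out of scope — they are
off-the-shelf methods whose re-implementation would add no fidelity here.

Pseudo-absences are uniform random background cells, ten per presence,
excluded within one cell of any presence, seeded. Species with 15 or fewer
records are skipped with a logged reason. Binarisation uses the lowest
training-point suitability, which forces training omission to zero by
construction and is the most conservative threshold supported purely by
the samples. Models are kept only when the rank-based pseudo-absence AUC
(ties at half credit) exceeds 0.7. Representativeness is the percentage of
the binary range, restricted to remaining native vegetation, that falls in
PA cells; a range with no remaining vegetation is flagged undefined rather
than reported as 0. In synthetic worlds the native-vegetation mask removes
a configurable random fraction of cells (default 20%).

## Protection accounting

A species is "inside" the network when at least one record lies in a PA
polygon — the record-based reading, matching how occurrence data are
actually audited. WE and PWE, being cell-valued, are partitioned by
summing over PA-overlapping versus other hexagons (positive-area overlap).
Both accountings are explicit in the report, because mixing them silently
is the easiest way to produce irreproducible percentages. Overlapping
designations resolve by precedence strict > sustainable > indigenous
(conservative attribution to the most restrictive class; configurable).
Rank comparisons use hexagons as sampling units: Kruskal–Wallis for record
density across the four strata, Mann–Whitney for endemism inside versus
outside, both tie-corrected (scipy), with the method (exact vs asymptotic)
logged.

Accumulation curves add PAs in designation-year order and re-evaluate
protected species, WE, PWE and lineage length cumulatively; the epochs are
1903–1950, 1951–1980, 1981–1990, 1991–2000, 2001–2016. A slope "in
degrees" is meaningless without declared axis scaling, so both axes are
normalised — years to percent of the 1903–2016 span, each curve to percent
of its final (all-PA) value — and the per-epoch slope is the arctangent of
a least-squares fit through the yearly step-function values inside the
epoch. The accumulation endpoint equals the static all-PA accounting by
construction, and the tests assert it.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, not
any real geography: a 500×500 km extent; six Voronoi biomes; rectangular
PAs in three categories (six each by default, jointly capped at 60% of the
extent — beyond that the request is rejected as infeasible) with uniform
designation years in 1903–2016; species ranges as unions of 1–3 discs with
log-normal radii (clipped to 10–120 km); per-species record counts from a
rounded log-normal (median 8, σ = 1.4, minimum 1), giving a majority of
species under 15 records and an occasional tail past 150; occurrence
points uniform within the range, thinned by an effort surface of Gaussian
hotspots (five, 40-km scale, 10:1 peak-to-floor) over a uniform floor; 21
spatially autocorrelated environmental layers at 5-km resolution, two of
which carry broad geographic gradients and two of which are terrain
analogues, so that compact spatial ranges map to learnable environmental
envelopes; and a random unit-branch phylogeny over the species. Everything
derives from one seeded generator, and serialisation is byte-stable.

What the generator does *not* emulate: georeferencing error, taxonomic
synonymy, range fragmentation beyond a few discs, non-stationary effort
through time, and realistic PA shapes. Tests passing on these worlds
therefore demonstrate that the estimators recover known truth under the
assumed statistical structure — not that any particular empirical map is
correct.

`scenario_gap` engineers a world where a chosen fraction of species is
wholly unprotected: the selected species get ranges disjoint from every
PA, the others get PA-overlapping ranges *and a first record drawn inside
the overlap*. That last construction is part of the ground-truth contract:
it makes record-based protection accounting equal the range-based truth
exactly, so recovery tests measure the pipeline, not sampling luck. If a
range cannot be placed after 400 attempts (with progressive shrinking),
the target is reported unreachable with a diagnostic rather than silently
missed.

## Problem sizes and numerical choices

Default study conditions are 80 species on the 500×500 km extent (~110
hexagons, ~1,500–2,500 records); recovery scenarios use 100 species so one
species is one percentage point; supertree recovery is studied at 6–12
taxa where exhaustive enumeration is available as an oracle. Tolerances:
conservation laws to 1e-9; tessellation bookkeeping to 1e-6 relative;
raster-based representativeness to the discretisation of the raster (≤2
points at the sizes used). Degenerate inputs (empty PA sets, empty species
sets, zero-area regions, constant rasters, singular covariances) either
have a defined value (empty set ⇒ 0% protected) or fail loudly; nothing is
silently imputed.

## Known limitations

Planar geometry only; effort estimator is one defensible formalisation of
a kernel-density notion, not a reconstruction of any specific historical
workflow; the GLM is the only model in the ensemble that uses
pseudo-absences during fitting, so ensemble members are not exchangeable;
NNI-only tree search can in principle stall on large rugged matrices
(SPR/TBR are not implemented); biome-level accounting assigns cells by
centroid, which blurs biome edges at the hexagon scale.
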