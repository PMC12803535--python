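# Methods

## Bone-modeling quantification

Surface-histological scoring is modeled cell by cell on a grid of
5 × 5 mm squares drawn over a periosteal region.  Each cell carries one of
six statuses, coded to a percent-bone-resorption (%BR) value:

| status | %BR | rationale |
|---|---|---|
| formation_only | 0 | no resorptive surface present |
| resorption_only | 100 | the whole cell is resorptive |
| mixed | 100 · resorptive area / cell area | measured |
| missing | NA | surface not preserved; excluded everywhere |
| partial_missing_with_formation | 0 | preserved surface shows one activity; neighboring surface tends to share it |
| partial_missing_with_resorption | 100 | same promotion rule |

Mixed 5 mm cells may be refined into four 2.5 mm subcells
(`subdivide_mixed_cell`); refinement must conserve the parent's measured
resorptive area, so recomputing region %BR after subdivision changes the
result only through the finer measurements, never through bookkeeping.

Region %BR is 100 × Σ resorptive areas / Σ cell areas over *non-missing*
cells: excluding missing cells from both numerator and denominator avoids
biasing poorly preserved specimens toward low resorption.  This is
algebraically the area-weighted mean of cell %BR, which the tests exploit
as an identity.  The alternative denominator — an independently measured
region surface area — is retained as `total_region_area` for reporting but
deliberately not used, because with partial grids it would conflate
missingness with formation.

Age-group mean maps average cell values across specimens cell by cell;
a mean cell is missing only when no specimen contributes.  Cell index is
the cross-specimen correspondence: grids of one region must be indexed
identically (in real material this is achieved by drawing the grid
identically on each replica; the generator guarantees it by construction).
Maps are painted onto a triangulated surface through an explicit
vertex-to-cell assignment rather than geometric binning, keeping the
projection deterministic; the color convention is cold = high %BR,
warm = low, gray = missing.

## Shape kernel

Configurations are k × 3 landmark arrays in mm.  Superimposition is
*partial* Procrustes: center, scale to unit centroid size, and rotate by
proper orthogonal least squares (SVD with determinant correction; no
reflections, which would merge antimeres).  GPA iterates rotation against
the consensus and consensus re-estimation until the RMS change of the
consensus falls below 1e-8 (max 100 iterations) — far below any data
noise.  The consensus is initialized from the average pre-shape when that
average is non-degenerate, so already-aligned samples converge in one
pass.  Procrustes distance is the root-sum-square coordinate difference
after optimal rotation of unit-size shapes.  Shape statistics operate on
Procrustes coordinates directly; projection to a tangent space is a noted
option, immaterial at the shape variation the generator produces
(distances ≲ 0.15).

The thin-plate-spline kernel is U(r) = −r (3D biharmonic convention).
The sign makes the bending-energy matrix B — the upper-left k × k block of
the inverted bordered kernel system — positive semidefinite with a
4-dimensional affine null space, which is what a minimization needs.  With
U(r) = +r the same quadratic form is negative semidefinite; the physics is
identical but unusable as an objective.  The physical bending functional
(the integral of squared second derivatives of the interpolant over R³)
equals 8π · yᵀBy; the test suite verifies this against an independent
numerical quadrature of the interpolant's squared Laplacian (point-source
fields 2wᵢ/rᵢ, integrated by excluded-ball midpoint quadrature with
analytic in-ball corrections) to within 2%.

Semilandmarks slide to minimize the bending energy of the deformation
from the sample consensus to each specimen: curve points along the chord
through their two curve neighbors, surface points within the tangent plane
(normals from supplied values or local PCA of the 8 nearest points).  The
sliding displacements solve a generalized-least-squares system in the
tangent directions, so energy can only decrease in each pass.  The outer
loop re-estimates the consensus and re-slides, at most 5 rounds or until
the consensus moves less than 1e-8 RMS; convergence is effectively
immediate.  Whether published analyses slide once against a fixed mean or
iterate is usually unstated; iteration is the safer default and the
single-pass behavior is available via `slide_against_reference`.

## Ontogeny statistics

Growth is size change, development is shape change.  Relative growth takes
the four consecutive differences of age-group mean centroid size as
magnitudes and normalizes them to percent of total (signed differences are
kept for diagnostics); relative development does the same with Procrustes
distances between age-group mean shapes.  Group means (not medians) match
the "average size per age group" convention.

Permutation tests use 1000 iterations by default and the add-one
estimator p = (1 + b)/(1 + m), which never returns 0.  The test statistics
are package choices: |mean size difference| for size, Procrustes distance
between group mean shapes (on jointly GPA-aligned coordinates, labels
permuted without re-superimposition) for shape.  Both are standard; the
calibration tests show the nominal 5% level is held.

The region comparison is a one-way fixed-effects ANOVA of specimen %BR on
region.  With a single factor, Type III and sequential sums of squares
coincide, so this is the unequal-n Type III analysis; Tukey HSD uses the
Tukey–Kramer studentized-range intervals for unequal group sizes (computed
via statsmodels, verified against manual arithmetic).  Pairs are labeled
"second − first" in sorted label order (e.g. `maxilla-brow_ridge` means
maxilla minus brow ridge).  With zero residual variance the studentized
range is degenerate; tied means then get p = 1 and distinct means p = 0.

## Two-block PLS

Both blocks are column-centered, not variance-standardized (covariance
PLS, the convention for shape–texture covariation).  The SVD of
XᵀY/(n − 1) yields min(p, q, n − 1) pairs; % total covariance is
100·sᵢ²/Σsⱼ² (squared singular values).  Per-pair sign is fixed by making
the shape-block vector non-negative on its first nonzero coordinate, with
scores and the map-block vector flipped consistently.  Permutation
inference permutes specimen rows of the map block and compares each
observed singular value with its own index's null distribution (no
sequential exclusion — the simplest defensible scheme).  Cells missing in
some specimens are mean-imputed per cell before PLS by default; dropping
such cells entirely is available (`na_policy="drop"`).  Extreme
reconstructions at ±2 SD of an axis's scores are mean + 2·SD·vector per
block, with map values clipped to [0, 100] and clipping flagged.

## Synthetic cohorts

The generator emulates the *structure* of an osteological study of facial
ontogeny, not its anatomy:

- **Cohort** — five age groups with default sizes (5, 15, 13, 5, 8)
  (n = 46), matching the uneven age structure of real archaeological
  series; five regions generated independently with sub-seeded RNGs.
- **Size** — age-group mean centroid sizes are base_size (120 mm) plus the
  cumulative growth profile, default (30, 15, 10, 5) mm: half of total
  growth in AG 1→2, tapering thereafter.
- **Shape** — a fixed random direction in shape space (centered,
  orthogonal to the base shape) is the development trajectory; age-group
  mean shapes step along it by the development profile, default
  (0.06, 0.03, 0.02, 0.01) Procrustes units.  Specimen coordinates are the
  target-size mean shape plus isotropic Gaussian noise (default SD 1 mm).
- **Maps** — cell values are a regional level (brow ridge 15, zygomatic
  17, maxilla 35, external mandible 11, internal mandible 12 %BR — the
  relative ordering of human facial regions) plus a smooth low-order
  polynomial pattern over cell index (≈5 pp per-cell amplitude), a
  per-specimen offset (SD 10 pp), a rank-1 coupling
  (covariation_strength × 150 pp per unit shape score, default strength
  0.6) to the specimen's projection on the trajectory, and cell noise
  (SD 5 pp), clipped to [0, 100].  With these defaults the simulated
  region %BR means span ≈11–33% with SDs ≈7–11 pp.
- **Missingness** — independent Bernoulli per cell (default 2%).

Clipping to [0, 100] is a documented truth distortion: at the floor it
converts low-%BR cells into formation-only cells (which real maps are full
of) but bends the planted linear coupling, so coupling-recovery tests use
mid-scale baselines and moderate strengths where clipping is rare.  What
passing tests show is that the estimators recover *planted* structure
under Gaussian noise and the stated missingness; they cannot show
robustness to anatomical correlation structure, digitization error
profiles, or age-estimation error, none of which the generator attempts.

## Problem sizes and determinism

Default analysis sizes (46 specimens × 5 regions, 30 landmarks, 60 cells,
1000 permutations) run the full pipeline in a few seconds.  The
calibration studies in the test suite use 1000 null simulations with
199-iteration inner tests (the 5% level is exactly attainable at
m = 199) and 100–200 replicate datasets for PLS recovery and uniformity —
sizes at which Monte-Carlo error is well inside the asserted bands.

All stage seeds are spawned from one master seed via
`numpy.random.SeedSequence`; result tables carry the config hash and seed,
CSV floats are written as `%.17g` and parsed with round-trip precision, so
a rerun with the same config reproduces every table byte for byte.

## Known limitations

- Synthetic shapes are random point clouds; no anatomical realism, no
  bilateral structure, no size-shape allometry beyond the shared
  trajectory.
- No missing-landmark estimation; configurations must be complete.
- Surface-semilandmark normals from local PCA are only as good as the
  local point density; supply explicit normals for sparse configurations.
- The mesh used for map rendering is a planar stand-in, one quad per grid
  cell, not a bone surface.
- Permutation statistics and the PLS permutation scheme are documented
  package choices among several defensible ones; alternatives (e.g.
  re-GPA per permutation) would differ slightly in small samples.
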