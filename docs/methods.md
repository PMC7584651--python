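# Methods

## The per-cell distance model

A confluent epithelium is modelled as a partition of the pixel plane in
which every cell j owns a parametric distance function d_j whose level-1 set
approximates the cell's contour. The family is built in three steps:

1. **Affine Minkowski (MAT).** d(x) = ‖(R S)⁻¹(x − μ)‖_p. For p = 2 this is
   the Mahalanobis distance of a distribution with mean μ and covariance
   R S S′ R′; p > 2 squares off the level sets (plant-like cells), p < 2
   sharpens them toward diamonds. p ≥ 1 keeps the triangle inequality.
2. **Asymmetry (AMAT).** Two exponential cross-weights skew the level sets:
   d(x) = (e^(−a₁y₂)|y₁|^p + e^(−a₂y₁)|y₂|^p)^(1/p) with y = (RS)⁻¹(x − μ).
   a₁ skews across the major axis (egg/triangle shapes), a₂ across the
   minor axis.
3. For some (a₁, a₂, p) combinations the far field is not a distance (level
   sets can open up, e.g. both a's large with p near 1). Only the
   neighborhood of level 1 matters for tessellation, so fitting is
   constrained to p ∈ [1, 16], a₁, a₂ ∈ [−1.5, 1.5], s ∈ [0.5 px, image
   diagonal], and the asymmetry exponent is clamped to ±50. Draws inside
   these bounds can still (rarely) produce an open level-1 set; the contour
   extractor detects and reports the offending ray rather than returning a
   broken polygon.

Coordinates are (x = column, y = row) with y increasing downward; α is the
major-axis angle from +x in [0, π), i.e. clockwise when the raster is
displayed y-down. All machinery is handedness-agnostic; only the on-screen
interpretation of α differs from a y-up convention.

## Fitting

*Five-parameter mode* (a₁ = a₂ = 0, p = 2 fixed): closed form. μ is the
pixel centroid; α and (s₁, s₂) come from diagonalizing the pixel covariance
(plus 1/12 per-pixel variance for the finite pixel extent). The scale is
s_i = 2√λ_i: a uniformly filled ellipse with semi-axes (A, B) has covariance
eigenvalues (A²/4, B²/4), so this is the unique scaling that puts the d = 1
ellipse on the region boundary.

*Eight-parameter mode*: the cell boundary is traced by marching squares,
resampled to N = 100 points at equal arc length (index 0 nearest the
major-axis direction), and Σᵢ(d(xᵢ) − 1)² is minimized by L-BFGS-B within
the bounds above, starting from the moment solution. A second start at
p = 6 guards against the shallow local minimum at p = 2 for cornered cells;
the better of the two is kept, and the moment solution is returned whenever
the optimizer fails to improve on it. N = 100 is enough that the SSE is
insensitive to the sampling phase for cells larger than ~20 px.

## Tessellation (heterogeneous-metric Lloyd)

Minimize Σ_j Σ_{x∈C_j} d_j(x) over the partition {C_j} by alternating:

- **Assign**: each pixel to the cell with smallest AMAT distance. Ties go
  to the lowest cell id (deterministic, seed-independent). For efficiency
  each symmetric cell is evaluated only inside the window where its
  distance can be below a cover level of 2 (half-width √2·2·s₁; the bound
  ‖x−μ‖ ≤ √2 s₁ ‖y‖_∞ ≤ √2 s₁ d makes the restriction exact); pixels whose
  best distance exceeds the cover level, and all asymmetric cells (whose
  level sets need not be bounded), fall back to exhaustive evaluation, so
  the result always equals the brute-force argmin.
- **Update**: (μ₁, μ₂, α) of each interior cell re-estimated on its pixel
  set — closed form (centroid + covariance angle) for Mahalanobis cells,
  bounded quasi-Newton on the summed distance otherwise. Shape parameters
  never change; border cells (touching the frame, hence incomplete) are
  fully fixed and anchor the frame.

Termination: zero pixels changed label. Because assignment and the
moment-based update do not minimize the identical functional, the raw
iteration can end in a perpetual sub-pixel jitter (10–20 boundary pixels
trading owners indefinitely). A dead band of 0.05 px / 0.005 rad on the
update — a cell's position is kept bitwise unchanged when its update moves
it less — makes an exact fixed point reachable without affecting the
raster at pixel resolution; with it, relaxations converge in 20–130
iterations on all tested fixtures. Safety nets: an exact-revisit check on
the label raster (a true limit cycle stops with `converged=False`), a cap
of 200 iterations, and re-seeding of any cell that loses all pixels at the
currently worst-covered pixel.

Initialization decides the product: fitted positions give the
*reconstruction*; uniform positions (μ over pixels ≥ 2 px from the frame,
α on [0, π), no overlap avoidance — collisions are the relaxation's job)
give a *random shuffle*; per-subpopulation initialization (random or
explicit, all interior cells then free to autoadjust) gives partial and
engineered shuffles. The reconstruction is exchangeable with the shuffles —
same code path, only the initial positions differ — which is what licenses
using it as the observed draw against their null.

## Content morphing

Source and target contours of a cell (equal N, both start-aligned to their
major axes) define a correspondence; mean value coordinates — generalized
barycentric weights valid for arbitrary simple polygons, negative weights
accepted on non-convex cells — interpolate it to the interior. Organelle
points go forward (weights in the source polygon applied to target
vertices); textures are pulled backward per target pixel with bilinear
interpolation in the source image, clamping to the raster edge (counted)
when a back-mapped location falls outside. Forward and backward transport
agree to within a pixel for the near-congruent shapes the engine produces.
Organelles marginally outside the resampled source polygon (a boundary
pixel's worth) are pulled toward the polygon centroid until inside.

## Statistics

Features are computed on the cell-contact graph: two cells are adjacent iff
4-adjacent pixels of the two touch (8-adjacency would manufacture contacts
through corners of a raster with no membrane pixels). Border cells are
excluded from every feature. Available features: class contact counts,
neighbor counts, and the rank-r orientation feature — per cell, the mean
absolute angle (0–180°) between centroid→organelle vectors of cells at
graph distance exactly r, averaged over interior cells.

The null is the feature over B seeded shuffles; the observed value comes
from the reconstruction. Empirical p = max(r, 1)/B with the *at least as
extreme* (non-strict) convention — the floor reconciles a ratio definition
with a nonzero report when the observation lies outside all samples. The
tail is feature-supplied (clustering → greater, spacing → less), two-sided
doubles the smaller tail. For image-mean features the null is near Gaussian
(CLT) and a fitted normal tail gives a continuous p from the same samples;
shuffles that hit the iteration cap without stabilizing are dropped and
counted (limit-cycle terminations are kept — their rasters are valid
tessellations). A single-shuffle Gaussian estimate from within-image
per-cell values is possible in principle but not exposed: its independence
correction is fixture-dependent, and sampling B shuffles is cheap at the
scales this package targets.

Two deliberately naive comparison nulls are included: random re-marking of
a honeycomb of identical hexagons (pointy-top, row-major fill, observed
cell-type ratio) and random re-marking of the original segmentation's
interior cells. Both discard the coupling between cell type and cell
size/shape and are demonstrably biased when populations differ in size;
they exist as foils, not analyses.

## Synthetic fixtures

The generator is independent of the AMAT machinery it tests: cells are
multiplicatively weighted Voronoi regions of blue-noise (dart-thrown) seed
points, optionally anisotropic (per-cell random stretch). Controls: area
heterogeneity (lognormal weight CV), elongation, a two-population labeling
(clustered = BFS patch(es), random, repulsed = greedy max-min spread) with
an optional minority area factor (e.g. 0.1 ≈ the ten-fold apical-area
asymmetry of stem vs multiciliated ependymal cells), and per-cell organelle
points at radius u·s₂, u ~ U[0.1, 0.8] — like centrioles, anywhere between
center and membrane; a degenerate fixed radius would make every
between-cell distance comparison degenerate — whose orientations blend a
smooth global field with uniform noise (coherence 0 → i.i.d. uniform,
1 → pure field).

What the fixtures do **not** emulate: membrane pixels (real segmentations
often carry watershed ridges), puzzle-shaped/non-convex cells (a stated
limitation of the distance model), segmentation errors, and the
image sizes of real microscopy (thousands of cells). Consequences at desk
scale, measured on these fixtures: border cells are ~25–35% of all cells
(vs a few percent on real images), and random shuffles squeeze or inflate
individual near-frame cells far more than bulk cells (log area-ratio SD
0.70 near the frame vs 0.13 in the bulk on a 320×320/144-cell fixture).
Per-cell content features therefore survive morphing with r ≈ 0.95–0.97
here, where much higher values are expected on full-size images; the test
suite asserts the preserved-vs-broken contrast (preserved r > 0.9 against
relational |r| < 0.2), not a large-image ceiling.

## Problem sizes and numerical choices

- Rank-angle null: 160×160 px, 100 cells, 60 shuffles (mean standard
  error ≈ 0.45°).
- Cluster rejection: 64×64 px, 60 cells, minority fraction 0.3, B = 1000.
- Baseline-bias demonstration: 140×140 px, 100 cells, minority fraction
  0.44 in 9 clusters, area factor 0.12 (a stem/ependymal-like
  configuration at desk scale).
- Calibration: 16 seeded random labelings, B = 99 each, rejection rate at
  α = 0.05 required ≤ 10%.
- L-BFGS-B: function tolerance 1e−10, ≤ 500 iterations (fit) / 60
  (position update); level-set root finding by 80-step bisection after
  geometric bracketing; contour resampling by linear interpolation of
  cumulative arc length.

## Known limitations

Highly non-convex cells fit poorly (puzzle cells); 3D stacks are out of
scope; the empirical p resolution is 1/B; the Gaussian mode assumes the
feature is an image mean of weakly dependent per-cell terms; partial
shuffles keep non-movable cells' initial positions but cannot prevent them
from drifting during relaxation (by design — the tissue must re-close).
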