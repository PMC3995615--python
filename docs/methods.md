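# Methods

## Model and estimator

The package maps a residual spatial risk surface by comparing the observed
spatial distribution of cases `f` with an expected reference distribution
`f0` on a disk-shaped study region `S`.  Rather than comparing the two
distributions in the plane, it compares them along `N` one-dimensional
projections: for each fixed point `c_i` on a circle circumscribing `S`, the
distance `d = ‖c_i − X‖` has CDF `F_i` under `f` and `F0_i` under `f0`.
Estimating one-dimensional CDFs is cheap and stable at epidemiological
sample sizes, and averaging many projection angles restores the
two-dimensional information any single projection discards.

At an evaluation point `y`, each projection is scored by the difference
between the observed and expected probability content of an adaptive band
around `t = ‖c_i − y‖`:

    [lo, hi] = [F0_i⁻¹(q − p0/2), F0_i⁻¹(q + p0/2)],   q = F0_i(t)
    γ_i(y)   = [F̂_i(hi) − F̂_i(lo)] − [F0_i(hi) − F0_i(lo)]

with `F̂_i` the (weighted) empirical CDF of case distances.  The band is an
adaptive smoothing window: its probability content under the reference is
`p0` wherever no clipping occurs, so every projection contributes on the
same scale regardless of how the reference stretches distance.  The final
score `Γ(y)` is the mean of the `γ_i(y)` over a lattice of `r` grid points
covering `S`.

Properties that the tests exercise directly: `E[γ_i(y)] = 0` at every `y`
under the null (the ECDF is pointwise unbiased and the band is fixed given
the reference), so null maps are flat in expectation; `Γ` is equivariant
under rotations that preserve the projection set; and the surface contracts
toward zero as `n` grows (consistency).

The comparator is deliberately a difference of band *masses*, not a
band-average of the CDF difference `F̂ − F0`.  The latter is not a local
statistic: once a case excess occurs at distance `t*` from `c_i`,
`F̂(u) − F0(u)` stays elevated for every `u > t*`, so the averaged-CDF
variant scores all points farther than the cluster highly and cannot
localize anything (measured AUC ≈ 0.5 on cluster simulations).  The
band-mass difference is local by construction and is what makes the
evaluation results in this package possible.  Ratio and weighted-difference
comparators exist in the literature; only the difference comparator is
implemented.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `N` | 20 (simulations), 40 (centroid tables) | projection points, equally spaced at angles `2πk/N` on the circumscribing circle (radius factor 1.0) |
| `p0` | 0.1 | reference-probability content of the smoothing band; larger = smoother, flatter maps |
| `lattice_count` | 100 | evaluation lattice across the bounding square; gives `r = 7860` interior cell centers on the unit disk |
| `B` | 99 | null resamples for palette calibration |

All coordinates are unitless planar values; distances are Euclidean.

## Continuous and discrete data

For a uniform-disk reference, `F0_i(d)` is the area of the intersection of
the disk of radius `d` around `c_i` with the region, over the region area —
the closed-form two-circle lens formula.  Its inverse has no closed form and
is computed by vectorized bisection (60 iterations, ≈1e-15 absolute error).

For discrete data the sample space is the collection of unit centroids:
case counts (possibly non-integer, from dispersed unit assignments) induce
a weighted step ECDF and the population-at-risk table induces a step
reference CDF.  Tied distances accumulate into a single jump of combined
weight; the inverse is the left-continuous generalized quantile.  A
continuous case set supported exactly on the centroids yields the same map
as its aggregated counterpart (checked to 1e-12), so the two settings are
one framework.

Band clipping at the support edges shortens the band (content < `p0`)
rather than shifting it; a fully degenerate band (`hi = lo`, possible for
very coarse discrete references) contributes 0.

## Color-scale calibration and the "high" region

`calibrate_palette` draws `B` datasets of the observed size from the
reference, maps each, pools the `B × r` null scores and records (a) their
empirical quantiles at levels 0.05 … 0.95 and 0.99 and (b) their range.
Pooling across grid points (rather than calibrating each grid point
separately) was chosen for stability at moderate `B`; the per-point
alternative would equalize exceedance rates across the region at the cost
of `B`-fold more resampling for the same quantile resolution.

Two different uses follow:

* **Exceedance calibration** uses the pooled quantiles: under the null,
  ~5% of grid points exceed the 0.95 quantile (verified ±2% in the tests).
* **High-risk-region extraction** uses the palette's *value scale*: a grid
  point is "high" when its score reaches 95% of the pooled null score
  range, i.e. lands in the palette's top color band near the most extreme
  score ever seen under the null.  This choice is deliberate: a 0.95
  probability quantile flags ~5% of all grid points on *every* map —
  hundreds of scattered points whose convex hull spans the region — so no
  iteration could ever produce a geographically compact high-risk area and
  the compactness/DiD evaluation below would be vacuous.  The value-scale
  threshold flags only scores well outside null behavior, yielding regions
  that are empty or compact.

## Aggregation scheme

`build_scheme` lays a `k × k` lattice of squares (side `2/k` on the unit
disk) over the bounding square and keeps every cell whose intersection with
the open disk has positive area, tested exactly via the cell's nearest
point to the center.  This centered-lattice convention yields cell counts
m = 16, 36, 88 at k = 4, 6, 10 and m = 201 at k = 15 (a previously reported
count for the k = 15 design is 199; the exact lattice anchoring behind that
figure is not recoverable, so the achieved count is logged, not forced).

Centroids are cell centers jittered by a seeded uniform offset up to
±0.15·side per axis, re-drawn until inside both the cell and the disk —
slightly off-center so the aggregated geometry is not artificially regular.
Boundary cells whose center lies outside the disk fall back to a uniform
draw on the cell–disk overlap.  Cell membership is half-open per axis, so
every interior point belongs to exactly one cell and aggregation conserves
counts exactly.

`discretize_reference` gives each cell the reference mass of its area share:
exact for fully interior cells, seeded Halton quasi-random integration
(default 4096 points) for boundary cells, renormalized to sum to 1.  Cell
masses were cross-checked against exact polygon intersections.

## Synthetic outbreaks and the experiment

Cases follow `f = (1−w)·f0 + w·g0` with `w = 0.1`: uniform background on
the disk plus a uniform square cluster `C` of side `diameter ∈ {0.05, 0.2,
0.35, 0.5}` centered at a focus drawn uniformly from the disk.  An interior
side-0.5 square is 2.16× likelier to receive a case under `f` than under
`f0` (closed form: `((1−w)·A/π + w)/(A/π)`, `A = 0.25`).  When `C`
overhangs the boundary, cluster draws are taken uniform on `C ∩ S`, keeping
all case mass inside the sample space; the alternative (allowing
outside-disk cases) would change the reference comparison, not just the
cluster.

`run_experiment` draws, per replicate, one focus and one continuous dataset
of `n_cases = 100`, then discretizes that same dataset at every non-zero
side length (2/15, 0.2, 1/3, 0.5) — paired comparisons across aggregation
levels, which is both what the underlying question ("what does aggregation
do to *this* data?") demands and a large variance reduction.  Each map is
scored by:

* **AUC** of the in-cluster/out-of-cluster grid-point classification
  (rank-based, ties shared); undefined (recorded as NaN) when the cluster
  square contains no grid point.
* **Success**: the high region (above) is non-empty, differs from its
  convex hull by at most 80 grid points (~1% of the full-resolution disk
  grid) and has hull diameter at most 1.75× the aggregation side length.
  Degenerate hulls (<3 points or collinear) reduce to the subset itself.
* **DiD**, for successful aggregated maps: distance from the high region's
  center (arithmetic mean of its grid points) to the cluster focus, minus
  distance to the *average centroid* (centroids of the cells receiving the
  cluster-origin cases, weighted by their case shares).  Positive DiD means
  the located area tracks the centroids rather than the true focus.  The
  sign convention (focus term first) is recorded in the results metadata.
  Success and DiD are only defined for aggregated maps: the extent
  criterion is relative to a cell side and the average centroid requires a
  scheme.

Seed lineage: every dataset is generated from `(master_seed,
diameter_index, rep)` and every side-level structure (centroid jitter,
reference discretization, palette) from tagged children of `master_seed`,
so any subset of replicates reproduces the full run's rows bit-for-bit —
this is what makes the experiment resumable by rep range.

### Problem sizes used in the shipped checks

The test suite replicates the degradation experiment at 100 replicates per
cluster diameter for diameters {0.05, 0.5} (the extremes, where the
interaction between cluster size and cell size is sharpest) on the
full-resolution `r = 7860` grid — about half a minute of compute, and
enough for the monotone-median and DiD-sign conclusions, though not for
smooth boxplots across all four diameters; the 1000-replicate, 4-diameter
configuration remains the `ExperimentConfig` default for full runs.  Null
calibration checks use 200 null maps on an `r ≈ 100` grid.

## What the generator does and does not emulate

The synthetic data exercise a dichotomized risk (uniform background, one
square cluster), a uniform population at risk and square aggregation units.
Real data have heterogeneous population density (the reference must come
from census or historical data, as in the centroid-table path), irregular
unit polygons, multiple or non-convex risk anomalies and spatially
structured reporting artifacts.  Passing the shipped checks therefore
demonstrates correct mechanics and the aggregation effect under controlled
conditions; it does not certify performance on any particular real
registry.

## Numerical choices

* Lens-area evaluation clips arccos arguments and the triangle radicand to
  their valid ranges, so tangency cases are exact rather than NaN.
* Quantile inversion: 60 bisection steps on the CDF; step-CDF queries are
  `searchsorted` on cumulative-mass tables.
* Per-projection band limits and expected band masses depend only on the
  reference, the grid and `p0`; they are precomputed once and reused across
  the thousands of maps in an experiment (`prepare_projection_contexts`).
* Halton sequences (seeded) for boundary-cell areas; rejection sampling
  from the bounding square for uniform-disk draws.
* Convex-hull membership uses Delaunay point location over the hull
  vertices (boundary counts as inside); hull diameter is the maximum
  pairwise vertex distance.
* CSV readers parse floats in round-trip mode so written tables reload to
  full precision.

## Known limitations

* Only the difference comparator; no p-values or formal cluster-detection
  statistics for the map.
* Regions are disks (the canonical unit disk, or a covering disk derived
  from a centroid table); polygonal region boundaries are not modeled.
* Planar Euclidean coordinates only — project longitude/latitude before
  use.
* The high-region threshold depends on the extremes of the pooled null
  sample and therefore on `B`; with the default `B = 99` it is
  reproducible but conservative.
* Aggregation supports the square-lattice schemes used by the simulation
  framework and user-supplied centroid tables, not arbitrary polygon
  partitions.
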