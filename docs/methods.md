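# Methods

## Problem and model

Spatial cross-matching joins two sets of simple planar polygons and, for
every pair whose geometries overlap, reports intersection area, union area
and the Jaccard coefficient. The typical inputs are two delineations of the
same objects — two segmentation runs over a pathology image, two editions
of a map layer — so most true matches share an identifier and a location,
but the method makes no such assumption: every cross-pair whose bounding
boxes intersect is examined.

Two refiners compute the per-pair areas:

* **Exact refiner.** Polygon clipping through shapely/GEOS. Used as the
  fallback path and, in the test suite, as the independent oracle for the
  pixel refiner.
* **Pixel refiner.** Both polygons are mapped onto a shared integer grid
  and areas become pixel counts. Every pixel has unit area; a pixel belongs
  to a polygon iff its center `(i + 0.5, j + 0.5)` passes the even-odd
  ray-casting test against the ring. Per-polygon counts are enumerated over
  each polygon's own scaled bounding box, the intersection count over the
  overlap of the two boxes (pixels outside a polygon's box cannot be inside
  the polygon, so these domains are equivalent to any larger ones), and
  `union_px = a_px + b_px − inter_px` exactly, in integers.

## Adaptive scaling

The grid resolution is set per pair by an integer factor `K`: vertices map
to `(round(Kx), round(Ky))` (nearest integer, ties away from zero), MBB
bounds are floored (lower) and ceiled (upper) so the scaled box always
contains the scaled geometry. Pixelization distorts area; the distortion is
measured per polygon as

```
error = |pixel_count / K² − area_original| / area_original
```

with `area_original` the shoelace area of the float ring (compensated
summation). `K` is chosen from an ascending candidate set, default
`{50, 100, 150}`, as the smallest value at which **both** polygons of the
pair have error ≤ 0.05. A shared per-pair `K` is required — per-polygon
factors would put the two rings on different grids and make the
intersection count meaningless. A ring that collapses under rounding
(fewer than 3 distinct vertices, or zero area) simply disqualifies that
candidate; if no candidate qualifies the pair is routed to a configurable
fallback: the exact refiner (default), accept-largest-K, or reject.

`pixel_count` is the number of in-ring pixel centers, not the pixel count
of the scaled MBB: the error formula compares against the polygon's area,
and the two readings coincide exactly for axis-aligned rectangles with
integer scaled corners (where the error is 0).

## Position test

A pixel center is inside a ring iff a horizontal ray toward +x crosses the
boundary an odd number of times. For the edge `(x1,y1)–(x2,y2)` a crossing
is counted when the query `y` lies in the edge's half-open vertical span —
lower endpoint inclusive, upper exclusive, mirrored for downward edges — and

```
x ≤ x1 + (y − y1)·(x2 − x1)/(y2 − y1)
```

Horizontal edges are skipped. The half-open convention makes a ray through
a shared vertex count exactly once; the `≤` resolves the (measure-zero for
half-integer centers against integer vertices) on-edge case
deterministically as a crossing. The serial and the vectorized (numpy)
implementations evaluate this predicate with the identical expression and
IEEE-754 double arithmetic, so their results are bit-identical; this is
what makes "which executor ran the batch" unobservable in the output.

## Sampling boxes

Per-pixel enumeration costs `O(pixels × edges)`. The sampling-box path
tiles the enumeration domain into `box_side × box_side` blocks (default
16). A block whose closed extent intersects no edge of the polygon(s) under
test contains no boundary point, so membership is constant over it: one
center-pixel test classifies all of its pixels. Blocks touched by an edge
(segment-vs-box by Liang–Barsky slab clipping, closed on both sides) fall
back to per-pixel tests. Because block classification reuses the very same
position test, the accelerated counts equal the per-pixel counts exactly —
the contract is bit-identity, enforced by tests at `box_side ∈
{2, 8, 16, 64}`. The scheme is flat (no recursive subdivision) and
classifies a block jointly against all polygons of the domain; both choices
trade a little speed for simplicity without affecting results.

## Partitioning, filtering, deduplication

Tiles are half-open `[x0, x0+w) × [y0, y0+h)` cells of a fixed grid; the
default grid covers the union extent of both datasets with 8 tiles per
axis. A polygon is replicated into every tile its MBB intersects, so the
filter stage is tile-local: per co-located tile pair, a bulk-loaded R-tree
(shapely STRtree) over one side's MBBs is probed with the other side's.
Box intersection uses closed intervals — touching boxes stay candidates
(the refiner then reports zero overlap) so no true positive is ever lost.

Replication can surface the same pair in several tiles. Each pair is owned
by its *canonical tile*: the tile containing the lower-left corner
`(max(xmin_a, xmin_b), max(ymin_a, ymin_b))` of the MBB overlap. Non-owning
tiles drop the pair, so every pair is refined exactly once.

## Scheduling and the cost model

The query is a three-stage task pipeline: parse/partition, index/filter,
refine. Two policies order the queue: FCFS (submission order) and PQ
(priority order). Parse and filter tasks always carry the minimum priority
and run on the serial worker pool. Refine tasks are scored by a linear
work-vs-transfer margin

```
priority = work_gain · est_pixel_work − transfer_cost · (payload_bytes + batch_overhead)
```

where `est_pixel_work` sums the pairs' scaled-MBB-overlap pixel counts,
`payload_bytes` is 16 bytes per vertex, and `batch_overhead` (default
500 kB-equivalent) models the fixed setup cost of engaging the
data-parallel executor. A batch goes to the vectorized executor iff the
margin is positive; the decision is monotone in the estimated work. The
fixed overhead term is what makes small batches run serial — with a purely
linear margin the break-even could not depend on batch size at all, since
both sides scale with the number of pairs. All three coefficients are
configurable.

Scheduling affects only the order in which work happens. Each refine task
is a pure function of its candidate pairs, results are keyed by task and
finally deduplicated and sorted by `(id_a, id_b)`, so any combination of
policy, worker count and executor availability produces byte-identical
output files. This determinism is the portability contract replacing
hardware speedup claims: whether a batch runs on the loop or the
array engine is an efficiency decision, never a semantic one.

## Synthetic data

The generator emulates two runs of a segmentation over one plane. Polygons
are star-shaped rings: `n ∈ [8, 24]` vertices at strictly increasing
jittered angles around a center, radii jittered in `[0.6, 1]`, a 30%
fraction given concave notches (radius pulled to 0.25–0.45×), the whole
ring rescaled so its shoelace area hits a target drawn from `[0.5, 2]`
units² and placed uniformly in a 16 × 16 extent. Star-shapedness guarantees
simplicity without repair loops. The "second run" translates each polygon
by Gaussian displacement of scale `perturbation` (default 0.05 units) and
jitters vertices radially about the centroid (σ = half the perturbation,
factors clipped to ≥ 0.2, preserving simplicity), so matched-pair overlap
decreases monotonically in the perturbation scale. Generation is pure in
`(spec, seed)` via per-index seeded generators.

What this emulates: compact convex-to-moderately-concave objects of
comparable scale with high but imperfect pairwise overlap. What it does
not: extreme aspect ratios, thousands-vertex coastline-style rings,
heavy-tailed size distributions, data skew across tiles, topological
errors (self-intersections) present in real exports. Passing tests
therefore demonstrate correctness of the algorithms and their contracts,
not robustness to every real-world pathology; the ingest path rejects
(rather than repairs) invalid rings by design.

Default sizes used by the test suite and the acceptance script — 200
matched pairs for the scaling/sampling/determinism checks, 60 pairs for
oracle convergence, 50 random tiles for filter checks, 10⁴ point cases for
the position test — are chosen to exercise every code path at desk scale.

## Numerical choices and edge cases

* Vertex rounding: nearest integer, ties away from zero (symmetric across
  quadrants; banker's rounding would bias paired coordinates differently).
* Shoelace area with Neumaier compensation; integer shoelace (exact) for
  scaled rings.
* Jaccard of an empty union is defined as 0 (total function; cannot occur
  for qualified pairs).
* Exact-refiner fallback results carry `k = 0` and zero pixel counts;
  their Jaccard comes from clipped areas.
* Degenerate inputs (collinear rings, bowties, < 3 vertices, non-finite
  coordinates) are rejected at ingest with the record locus in the error.
* Tile-boundary membership is decided against the exact tile bounds
  `origin + i·size`, avoiding float-division slop at half-open boundaries.

## Known limitations

* No holes, multi-polygons or CRS; planar Cartesian only.
* The filter requires record IDs orderable after `str()` for the canonical
  result sort.
* The vectorized executor materializes a boolean grid per polygon pair;
  very large `K` on very large polygons costs memory proportional to the
  scaled MBB area (the sampling path reduces time, not peak per-block
  memory, though blocks cap the grid size).
* Thread-pool "parallelism" targets correctness of the scheduling
  contract, not wall-clock speedup.
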