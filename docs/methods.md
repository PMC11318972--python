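# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `arbornet`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions and units

All geometry lives in world micrometres in a right-handed frame with
X = anteroposterior (positive posterior), Y = dorsoventral (positive
ventral) and Z = medio-lateral depth. Voxel or pixel units never cross a
module boundary: rasterisation is internal to the spatial metrics, and the
SNT CSV reader exposes a `scale` flag for uncalibrated (voxel-space)
exports. When a trace carries no radius, the default neurite radius is
0.5 µm, the average afferent neurite radius in this system.

## From traces to a junction graph (`arbor_graph`)

A trace is a set of unbranched 3D polylines with optional parentage and a
flagged lateral-line trunk. Graph construction:

1. **Crossing detection.** For segments of *different* paths, the minimum
   segment–segment distance is computed (KD-tree prefilter on segment
   midpoints, then exact closest points). Pairs closer than `merge_tol`
   (default 0.5 µm ≈ the neurite radius — contact at the scale of touching
   membranes) are fused at their mutual closest points. Contacts within
   2 × `merge_tol` of a point where the two paths already share a vertex
   are junction geometry, not crossings, and are skipped. Contiguous
   sub-threshold contacts along a pair of paths are clustered and only the
   closest representative is fused. `merge_tol = 0` recovers the strict
   interpretation in which only exactly shared skeleton points join.
2. **Endpoint merging.** Every path endpoint merges with the nearest vertex
   of another path within `merge_tol` (union–find), which realises SWC
   parentage and the exact shared anchors of generated geometry.
3. **Degree-2 collapse.** Chains of degree-2 vertices collapse into single
   polyline edges; edge length is the polyline arc length (preserved to
   1e-6 µm, tested). Pure cycles with no junction are anchored at their
   lexicographically smallest vertex as a self-loop.
4. **Canonical ids.** Nodes are renumbered by lexicographic (x, y, z), so
   construction is invariant to the order of paths in the input file, and
   all tie-breaks ("lowest id") are deterministic.

Junctions are nodes of degree ≥ 3 (degree counts self-loops twice); the
degree census excludes degrees 1–2 — free ends are bare-terminal tips, not
nodes. The **arborization point** (graph root) is the node joining trunk
and arbor edges that lies nearest the cluster boundary; ties break to the
lower node id with a warning, at the resolution of the sampled boundary
(0.1 µm). If the base of the arborization carries fewer than three incident
structures it collapses into a mixed trunk+arbor chain; any edge containing
trunk geometry is treated as trunk when excluding the trunk's free end from
the terminal census.

## Loops and terminals (`topology_features`)

Loops are the **minimum cycle basis** of the junction multigraph with edge
weight = contour length: ν = |E| − |V| + C independent cycles minimising
total geometric length. The implementation builds Horton's candidate set
(for every vertex x and edge (u,v): shortest path x→u, the edge, shortest
path v→x), with a deterministic per-edge epsilon perturbation
(1e-9 × max weight, scaled by edge index) to make shortest paths unique as
Horton's correctness requires; candidates that are not single circuits are
discarded, self-loops and parallel-edge pairs are added explicitly, and a
greedy GF(2) elimination over bitmask edge vectors selects the basis in
weight order. This in-house implementation exists because the graphs are
weighted *multigraphs* (parallel edges between two junctions are common)
and because cycles must map back to concrete edge polylines; it is verified
in the tests against exhaustive simple-cycle enumeration on 200+ random
graphs and against `networkx.minimum_cycle_basis` on simple graphs.

A loop's `node_count` counts junction (degree ≥ 3) nodes on the cycle;
basis cycles may share edges, and per-loop contour lengths count shared
edges in every loop that uses them, while the length *partition*
(trunk / loop / terminal / connector) assigns every edge exactly once.

Bare terminals are degree-1 tips not on the trunk; after collapse each is a
single edge, oriented branch node → tip.

Relative organ height is h = (u·v)/‖v‖² with u from the arborization point
to the node and v from the arborization point to the cluster apex; h < 0
(below the base) and h > 1 (overshooting the apex) are retained. Region
bins are half-open with boundary values going up: basal [0, 0.10),
basolateral [0.10, 0.60), apical [0.60, ∞); negative h is basal.

Occurrence statistics use length bins {0–10, 10–20, 20–30, 30–40,
40–70} µm by default; empty bins report NaN fractions, never 0. Cohort
feature counts are divided by the organ's hair-cell count, min–max scaled
to [0, 1] across the cohort (a constant cohort scales to zeros with a
warning), optionally divided by cohort size for density plots.

## Total curvature (`curvature`)

κ_total = ∫ κ(s) ds with κ = |r′ × r″| / |r′|³ on an interpolating cubic
B-spline (`splprep`, smoothing 0; smoothing is configurable for noisy
tracings), evaluated on a grid of 10 × the input points and integrated by
composite Simpson (∫ κ |r′(u)| du). In 3D the Frenet curvature is
non-negative, so the integral itself is non-negative and equals 2π for a
closed planar loop — the property the acceptance suite checks to 1%.
Fallbacks: polylines with < 4 distinct points, degenerate (collinear)
fits, or vanishing spline speed use the discrete turning-angle sum, which
is also the independent oracle in the tests. Near-duplicate points
(< 1e-3 µm apart) are removed with a warning before fitting. The estimator
is invariant to rigid motion, uniform scaling and point-order reversal
(tested), and matches the prescribed turning of sampled circular arcs to
well under 1% at 100+ points.

High vs low curvature splits strictly at π/6 (30°): high iff
κ_total > π/6, so the exact threshold value classifies as low.

## Spatial metrics (`spatial_metrics`)

**Registration** translates each neuromast so its apex center sits at the
origin; no rotation or scaling (traces are not mirrored to a canonical
rostro-caudal orientation). **Radial density** works on the X–Y projection
of the combined trace: the disc to `r_max` = 60 µm is divided into
`round(π r_max²/A)` = 3600 sections of area A = π µm², outer radii
r_k = √k. Occupancy is rasterised at 0.1 µm pixels with an unbiased
pixel-center-within-radius test against densely resampled skeleton points
(a naive dilation overestimates tube width by one pixel). Outer annuli are
thinner than a pixel, so *per-annulus* occupancies are
quantisation-dominated; quantitative use should aggregate bands or use the
kernel-smoothed density trace (Gaussian kernel, default bandwidth 2 µm),
which is also what the fall-off radius uses. The **fall-off radius** — the
outermost radius where the smoothed density still reaches 5% of its peak —
is this package's operational definition (the criterion is not standard);
both the fraction and the bandwidth are exposed.

**Contact** resamples all non-trunk paths at 0.2 µm arc length
("voxels" made deterministic and resolution-independent) and counts points
inside the union-of-ellipsoids cluster boundary or within 0.5 µm of it,
as a percentage of all points. Inside tests use the implicit union
(min-over-cells quadratic form ≤ 1; surface points count as inside);
distances to the boundary use a quasi-uniform Fibonacci-lattice sampling of
the union surface (default 0.1 µm spacing). Contact is monotone
non-decreasing in the tolerance (tested).

**Guidance metrics** represent an ectopic source cell by the single
boundary point nearest the projection terminus; source path, projection
path and projection proximity are Euclidean distances from/to that point
and the arborization point.

## Synapse mapping (`synapse_mapping`)

Puncta are assigned geometrically: every collapsed edge is resampled at
0.1 µm with a feature label (bare-terminal edges first — they cannot lie
on a cycle; edges on several basis loops take the lowest loop id; trunk
and internal connectors map to "unassigned"), and each punctum takes the
label of its globally nearest sample if within the cutoff (default 1 µm ≈
2 × neurite radius). Node-distance histograms use equal-volume concentric
shells r_k = R (k/n)^{1/3} (defaults n = 100,000, R = 10 µm); a punctum at
distance d falls in shell ⌈n (d/R)³⌉; puncta beyond R overflow with a
warning; densities are reported per µm³ so they are n-independent.
Per-hair-cell summaries assign each punctum to the nearest cell base
within a basal-region radius (default 3 µm); equidistant ties go to the
lower cell index with a warning.

## Synthetic neuromasts (`synthetic_data`)

The generator emulates the study conditions with exact, parametric ground
truth. Defaults: ~12 hair cells (per-organ counts jitter, even preferred,
alternating rostral/caudal polarity on a rosette), 10 µm cluster radius,
Poisson-distributed arbor count with mean 9.3, arbor contour lengths
uniform on 5–55 µm. Each arbor becomes a loop with a probability given by
its length bin — control: 0 / 0.3 / 0.75 / 1.0 / 1.0 over the five bins
(arbors < 10 µm always terminals, > 30 µm always loops); mutant:
0 / 0.05 / 0.3 / 0.45 / 0.55 — otherwise a bare terminal whose total
curvature is drawn from a high/low mixture (control: 55.2% high, high
uniform on 0.75–2.6 rad, low on 0.05–0.42 rad; mutant: 43.6% high). The
low range stays clear of the π/6 threshold so the 2% curvature-recovery
tolerance cannot flip a class.

Geometry: loops are circles of radius L/2π in the radial–vertical
("petal") plane of an azimuth slot, their inner edge riding the cluster
surface (control offset −0.3 µm) or standing off it (mutant +0.8 µm),
threaded through `nodes_per_loop` anchor points (control 4, mutant 3).
Each ring attaches to the network by exactly one bridge (a bowed polyline
from the arborization point, or — beyond five base slots — from a free
anchor of an earlier ring), so the cycle space is exactly the set of rings
and the minimum cycle basis equals the planted loops. Terminals are
circular arcs of prescribed length and turning angle, launched
perpendicular to their host ring's plane (or radially from the base, or
from points along the trunk when the base budget of ~7 attachments is
exhausted), with a soft radial-reach cap (`radial_extent`: control 34 µm,
mutant 57 µm). Only anchors that receive an attachment survive as
junctions, so realized nodes-per-loop span 1..`nodes_per_loop` depending
on the terminal/loop mix.

Every placement is collision-checked against the accumulated geometry with
clearance requirements strictly stronger than the analysis-time fusion
rule (full clearance 1.2 µm away from attachment points, reduced clearance
in the near-anchor band, exemption only strictly inside the analysis skip
window), with deterministic retries; the rare feature plan that cannot be
placed (mostly extreme loop-rich draws) is redrawn from a derived sub-seed,
a slight rejection-sampling bias against such outliers. All randomness
flows through one PCG64 generator; a fixed seed reproduces outputs bit for
bit, including written SWC files.

Ground truth records realized polyline lengths (what the pipeline
measures), prescribed turning angles, per-ring junction counts, puncta
labels, and a contact fraction computed at 4× finer resampling and
boundary sampling than the pipeline default. Puncta are placed on features
(length-weighted choice, configurable loop fraction, default 531/567) at
exponentially decaying arc distances from ring anchors — aggregating near
nodes — but never closer than 1.2 µm to a junction, so positional jitter
(default 0.15 µm, tested to 0.3 µm) cannot flip the nearest-feature
assignment; this truncation also truncates the node-distance histogram
below ~1 µm. Dwell stacks contain a moving blob with known per-pixel
on-times plus a stationary bright anchor so per-frame min–max
normalization is never applied to a pure-noise frame.

What the generator does **not** emulate: tracing noise and gaps, arbors
that conform to the curved cluster surface (loops are planar), true 3D
self-crossings of a single neurite, and the absolute contact magnitudes of
real organs — generated contact percentages are far below real ones
because most planted arc length lies off the cluster surface. Passing
tests therefore certify the *measurement pipeline* (exact recovery of
planted topology, curvature to 2%, contact to 1 percentage point, puncta
labels to 99%) and the *direction* of preset contrasts (control contact
above mutant; control density fall-off around 33 µm vs mutant around
50 µm), not real-data effect sizes.

## Statistics (`stats_report`)

Mann-Whitney U is the default two-group test for continuous per-neuromast
metrics. Distribution shifts (node heights, nodes per loop, loop lengths)
use the one-sided two-sample KS test; the direction is a required input
(`ks_alternative`) and is recorded in the output, since a default choice
would silently encode a hypothesis. Loop-vs-terminal occurrence per length
bin and curvature-class splits use Pearson chi-square without continuity
correction; degenerate tables (an all-zero row/column) are skipped with a
logged notice. Arbors are pooled across the neuromasts of a cohort for the
distributional tests. No multiple-testing correction is applied by
default; Benjamini–Hochberg is available. Exact small-sample behaviour of
the KS p-value is verified against full permutation enumeration in the
tests. The pipeline (`run_pipeline`) analyses each neuromast independently,
logs and skips failures, and writes `metrics.csv`, `features.csv`,
`tests.csv` and `report.json` with all parameters recorded.

## Problem sizes

The shipped test-suite and acceptance-script runs use synthetic cohorts of
10–25 neuromasts per arm, 20 seeds per preset for ground-truth recovery,
200 random graphs (≤ 12 nodes) for the cycle-basis oracle, and 50
replicate cohorts of 25 feature plans per arm for the discrimination
check; the discrimination replicates run on the generator's statistical
layer directly, which is equivalent because the recovery tests certify
that geometric extraction reproduces the planned features exactly.

## Known limitations

* Loop contour lengths count edges shared between basis cycles once per
  cycle; whether to count them once globally is a convention, flagged in
  the outputs via the length partition.
* The minimum cycle basis is not unique under weight ties; the epsilon
  perturbation picks a deterministic representative, so loop *identities*
  (not counts or total weight) may differ from other implementations.
* The fall-off radius definition (5% of smoothed peak) is operational, not
  standard; compare only within a fixed bandwidth and fraction.
* Per-annulus densities below the pixel scale are quantisation-limited
  (see above).
* `HairCellCluster.boundary_mesh` is carried through I/O but geometric
  queries always use the implicit ellipsoid union and its sampled surface.
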