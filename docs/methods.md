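# Methods

## Model and assumptions

The Potential Path Volume treats each trajectory segment as a space-time
accessibility problem: given fixes P_i and P_{i+1} observed Δt apart and a
maximum speed v_max, the reachable spatial set is the locus
|p − P_i| + |p − P_{i+1}| ≤ v_max·Δt — a prolate spheroid with the fixes at
its foci. The construction assumes:

- **Metric, projected coordinates.** All distances are Euclidean in
  (x, y, z); the package never reprojects. Geographic inputs must be
  projected upstream (e.g. a polar stereographic projection for high-latitude
  tracks).
- **Isotropic movement about the segment axis.** The two minor axes are
  equal; anisotropic (scalene) ellipsoids that would encode, say, the
  energetic asymmetry of climbing vs. diving are out of scope.
- **Constant speed within a segment** (the usual high-frequency-sampling
  approximation behind accessibility ellipses).
- The PPV is an *outer bound*, not a density: every voxel is either reachable
  (1) or not (0), with no occupancy weighting.

Quantities per segment: midpoint P_c; focal distance d (3D Euclidean);
a = v_max·Δt/2; b = sqrt(a² − d²/4); azimuth α = atan2(Δy, Δx) and elevation
β = arcsin(Δz/d). A two-argument arctangent is used because an arctan of the
slope ratio is undefined for Δx = 0 and quadrant-ambiguous.

### Frame convention

The data-to-ellipsoid transform is pinned to the normative contract *the
foci map to (−d/2, 0, 0) and (+d/2, 0, 0)*, implemented as translation by
−P_c followed by R = Ry(β)·Rz(−α). Textbook yaw/pitch matrix conventions
differ by transposition (active vs. passive); fixing the endpoint images
instead of the matrix entries makes the containment form unambiguous, and a
unit test enforces the contract to 1e−9 m on random and purely vertical
segments.

### Degenerate geometry

- d = 0 (stationary interval): α = β = 0 and the spheroid is a ball of
  radius a — not an error.
- d = v_max·Δt (segment moved exactly at the speed budget): b = 0. The
  quadratic form is undefined, so containment falls back to the focal-distance
  test with a 1e−9 relative tolerance; the segment still rasterizes as a
  one-voxel-thick line rather than vanishing.
- Boundary inclusivity: the form is compared with ≤ 1 + ε, ε = 1e−12
  relative, matching the inclusive inequality of the model.
- A segment whose displacement exceeds v_max·Δt (possible only with a user
  v_max override) raises an infeasibility error naming the segment; overrides
  below the maximum observed speed are rejected up front.

## Maximum-speed estimation

v_max = 2·v_m − v_{m−1} from the two largest observed segment speeds: a
robust extrapolation past the sample maximum that keeps every observed
segment strictly feasible (using the raw maximum would make the fastest
segment's ellipsoid degenerate). Ties collapse to v_m; a single observed
speed falls back to itself with a warning so two-fix tracks remain
processable. The scope is per-trajectory by default (each individual's own
movement capacity), with a pooled option on the CLI. Horizontal and vertical
maxima (v_xy_max, v_z_max) are estimated with the same rule on the component
speeds; note the component estimators extrapolate independently, so v_xy_max
can slightly exceed the 3D v_max.

## Vertical rescaling

Because vertical speed capacity is usually far below horizontal, a single
isotropic v_max inflates the vertical reach. The package stretches z by
v_xy_max / v_z_max before constructing ellipsoids, records the factor as
`z_scale`, and reports volumes in original units as raw voxel volume ÷
z_scale. The sign of the ratio was a genuinely open choice (stretch vs.
compress); the implementation stretches z when v_z_max < v_xy_max, which —
after mapping back to original units — makes the accessibility volume flatter
in the vertical dimension, the intended correction. For a near-planar track
the stretched-space ellipsoids have essentially unchanged raw volume (d,
speeds, v_max are all insensitive to stretching a ~constant z), so the
reported, z_scale-corrected volume is close to 1/ratio of the unrescaled one;
the unit-ratio case is exactly (bit-for-bit) the unrescaled pipeline.

## Discretization

- Grid: origin at the padded extent's min corner; voxel (i, j, k) has center
  origin + ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz); dims = ceil(extent/edge). The
  convention is normative because volumes are resolution- and
  alignment-dependent; both are explicit, logged parameters.
- Default extent: the fix bounding box padded by the largest semi-major axis,
  which provably never clips any ellipsoid.
- Default voxel edge: largest extent edge / 200 — keeps default grids at desk
  scale (≤ ~8M voxels) while resolving typical minor axes; precision work
  should set the edge explicitly (e.g. b/20 gives ≲ 0.1% volume error on a
  single spheroid, b/40 ≲ 0.01%).
- A voxel is inside iff its center passes the containment test; partial
  overlap is not fractionally weighted. Per segment only voxels intersecting
  the center ± a bounding cube are tested (at most (a/b)² wasted tests,
  traded for branch-free code); the result is bit-identical to an exhaustive
  sweep, and the per-segment cost is bounded by the box, not the grid.
- Vertical clipping zeroes voxels whose centers fall outside [z_min, z_max]
  (e.g. a −100 m floor for below-surface GPS error and a flight ceiling).
  When z has been rescaled, clip bounds are multiplied by z_scale so they are
  expressed in original units.

## Gap filtering and subsampling

Tracks whose largest inter-fix interval strictly exceeds 3× the nominal
sampling interval are rejected (gappy segments produce ellipsoids that
swallow the rest of the volume). Strict inequality means an exactly-3×
interval — common after thinning — survives. The nominal interval is the
median inter-fix interval unless the programmed tag interval is supplied.
Subsampling keeps every k-th fix plus the last; merging consecutive prisms
under one speed budget can only enlarge the reachable set, so the PPV of a
subsampled track contains the original voxelwise and volumes are
non-decreasing in the sampling interval — the mechanism behind coarser tags
reporting larger accessibility volumes.

## Simulator

The 3D correlated random walk draws, per step and in documented order, a
horizontal and a vertical von Mises(0, κ) turning-angle increment and a step
speed (uniform [2, 12] m/s by default, producing visible thick/thin ellipsoid
alternation). Von Mises was chosen as the standard circular distribution in
the CRW literature. The elevation angle is clamped to (−π/2 + 10⁻³,
π/2 − 10⁻³) rather than wrapped, forbidding loop-the-loop steps and keeping
the elevation within arcsin's range. κ = ∞ is accepted as the degenerate
straight-line limit. Time steps are exactly uniform, and one seeded
generator makes trajectories reproducible across platforms.

What the simulator emulates: persistent 3D headings, heterogeneous speeds,
uniform sampling. What it does not: measurement error (especially the large
altitude error of real GPS), irregular sampling, behavioural modes, wind or
current advection, central-place attraction. Passing tests on simulated
walks therefore validates the geometry and bookkeeping of the estimator, not
its ecological calibration on real tags.

## Problem sizes and numerical checks

The test suite and the acceptance script use desk-scale problems chosen as
the package's own defaults: single-spheroid volume checks at edges b/5…b/40
(≤ ~0.6M voxels), containment-oracle sweeps of 100 ellipsoids × 10⁴ points,
frame checks on 10³ segments, coarsening checks on 20 walks of 24 steps at
an 80-division grid, and turning-angle statistics at 10⁴ steps (the sample
mean cosine is compared with I₁(κ)/I₀(κ) within three Monte-Carlo standard
errors). Reported volumes in the demo use 100 m voxels. All random draws
derive from explicit seeds.

## Known limitations

- Volumes depend on voxel size and grid alignment; comparisons are only
  meaningful at a shared grid. There is no canonical resolution.
- The Boolean union carries no information about *how often* a region was
  reachable; it is an accessibility bound, not a utilization distribution.
- Center-point rasterization under-resolves ellipsoids thinner than about
  one voxel (degenerate segments reduce to a line of voxel centers and can
  miss off-center grids entirely).
- The gap filter drops whole trajectories rather than splitting them at the
  gap; splitting is left to upstream preparation, as is trip labelling.
- Environmental deformation of the accessibility volume (wind, currents) and
  kinetic/energetic prisms are out of scope.
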