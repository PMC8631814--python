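# Methods

`channelmill` models the planning, robotic milling and postoperative
metrology of an electrode-lead channel on the temporal bone surface, as used
when a cochlear-implant electrode lead is stowed in a milled press-fit
channel instead of a mastoidectomy cavity. This note documents the models,
the numerical choices, and what the synthetic experiments do and do not
show.

## Channel model and planning

The surface channel is a composite of three cubic Bezier segments joined
with G1 continuity, forming an S (or mirrored S) with two curves. The ends
are pinned exactly to the middle-ear-access drill-hole entry and to the
fantail lead-exit point of the receiver-stimulator. The required channel
length is arithmetic: electrode-lead length minus drill-tunnel length,
minus an insertion offset (zero under the full-insertion assumption;
negative when the array sits shallower, leaving more lead on the surface).

The user-facing shape parameters mirror an interactive planner: two sliders
place the curve control points along the entry-to-receiver direction and one
slider sets their common perpendicular offset. When sliders are not given,
the free degrees of freedom (node positions, shared tangent angles, six
tangent magnitudes) are set by minimizing the maximum curvature subject to
an arc-length equality constraint. "Curvature-optimized" is formalized as
this minimax problem; the optimizer is initialized at the symmetric biarc
solution (two mirrored circular arcs whose half-angle theta solves
sin(theta)/theta = chord/length — the exact minimax S among two-arc paths),
split into three cubics at equal turning angle, then polished with SLSQP on
a p-norm (p = 16) soft maximum of sampled curvature. A final exact
arc-length correction scales the perpendicular offsets (a linear map, so G1
continuity is preserved) until Gauss-Legendre quadrature of the length
matches the target; achieved lengths are within 0.5 mm of target by
contract, typically within 0.05 mm. A warning flag is raised when the
minimum curvature radius falls below the critical 5.0 mm; a separate flag
marks planar self-intersection.

One consequence of the minimax completion worth knowing: even extreme
length-to-distance ratios (e.g. a 60 mm channel between points 15 mm apart)
can stay above the 5 mm radius by growing large lobes, so the curvature
warning fires only when the parameterization genuinely cannot avoid a tight
turn — not merely when the ratio looks aggressive.

Planning happens in a local 2-D frame (projection along the mean outer
surface normal at the two endpoints) and is lifted to the outer mesh by ray
casting along that normal; the lifting error is bounded by the surface
slope within one waypoint spacing (0.1 mm default) and is orders below the
milling tolerances. The depth profile places every bottom waypoint exactly
`channel_depth` (2.3 mm) below its surface waypoint along the local tool
axis — the barycentric-interpolated surface normal, optionally rotated by a
tilt angle about the entry-to-fantail axis. Intervals where bone thickness
along the tool axis is below depth + margin are flagged.

Safety distances are measured from the margin-inflated swept tool volume
(approximated by spheres of the tool radius on the dense surface and bottom
waypoints) to each named forbidden structure (fiducial screws, tripod legs,
marker volume, incision trace). A structure exactly at the margin passes;
violation is strict inequality.

## Toolpaths

* Access-point preparation: per 1.0 mm level down to 5.0 mm, a central
  plunge along the drill trajectory then a circle about the axis at radius
  (prep diameter − tool diameter)/2. The prep diameter defaults to the
  1.8 mm drill diameter.
* Tunnel-to-surface transition: a single G1 cubic whose two tangent
  magnitudes are optimized (Nelder-Mead) for minimax curvature; verified in
  tests against a brute-force grid search.
* Widening: the boundary is two Bezier curves tangent to the channel at the
  ends of an arc-length window centered on the chosen curve, generated from
  one Hermite family by scaling the tangent arms; the inner curve's length
  is the planned window length − 1.0 mm (the shortest lead route through
  the region — the inner boundary is convex, so a taut lead hugs it) and
  the outer curve's is + 2.0 mm (the longest smooth route). The window is
  kept on one side of the S inflection, where the bulge direction flips.
* Pocketing: iterative inward polygon offsetting (shapely) at step
  tool_diameter × (1 − overlap) = 0.36 mm after an initial inset of one
  tool radius, connected center-outward into one continuous spiral;
  counter-clockwise ring traversal implements climb milling for a
  clockwise-rotating spindle seen from the shank. Coverage is verified on a
  0.05 mm grid over the tool-reachable region (the morphological opening of
  the boundary by the tool radius — a cylindrical cutter cannot enter
  sharper corners). Boundaries narrower than the tool collapse to a
  center-line or single-point pass.
* Implant bed: spiral fill of the (rounded) fantail outline with a linear
  depth ramp into the channel end; optional pin holes are appended as
  single plunge waypoints.
* Feed law: velocity = setpoint (2.0 mm/s) up to 4 N, linearly decreasing
  to zero at 10 N where an interrupt is raised. The zero lower endpoint at
  10 N is a conservative choice; only the linear region boundaries are
  prescribed.

## Milling simulation

The carve substitutes robotic execution plus micro-CT surface
reconstruction. Bone occupancy (the slab between outer and inner surface,
minus spherical air cells) and the union of swept flat-ended cylindrical
tool volumes along the toolpath are evaluated as signed-distance fields on
a voxel grid (0.05 mm default, matching the 40–50 um micro-CT
reconstruction window); the difference is extracted with marching cubes.
Because the SDF is linear near flat walls, the extracted surface is exact
to well below a voxel there; waypoints are densified to the voxel size so
the union-of-cylinders scalloping is O(voxel²/tool radius). The carve grid
is a band around the toolpath — like a cropped micro-CT reconstruction,
downstream analysis only needs the channel and its surroundings. Bone
occupancy is rasterized by height-field interpolation of the site meshes;
the synthetic sites are slab-like sheets, which this assumes.

Execution error has two parts, mirroring an image-guided system: a
per-case rigid bias (registration error; translation i.i.d. normal per
axis, optional small random rotation — zero-mean over cases) and a smooth
zero-mean Gaussian-process jitter of the tool position along the path
(navigation drift). The jitter uses a squared-exponential kernel with a
3 mm correlation length, sampled exactly via Cholesky at one-third of the
correlation length: the marginal sigma is preserved everywhere (knot
interpolation would lose ~18% of it) and sample paths are smooth at the
tool-contact scale, so the carved groove tracks the jitter rather than its
envelope. White per-waypoint noise would model tool vibration, not
navigation error, and its envelope would systematically bias the width.

## Metrology

The measurement pipeline mirrors a postoperative micro-CT analysis. The
postoperative surface is co-registered through paired-point (Kabsch)
matching of the four fiducial screws. The resulting center line is
estimated starting from the planned one: a first sampling pass recenters
each cross section at the midpoint between the left and right wall on the
bottom, then the final pass measures. Cross sections are radial ray fans
(1 degree spacing by default) in the plane exactly perpendicular to the
local path tangent, cast from a point 0.8 mm above the planned surface so
a single fan reaches the bottom, both walls and the adjacent top surface
on both sides. Ray casting is vectorized Moller-Trumbore with KD-tree and
fan-plane pruning; first positive hit wins, ties at shared edges resolve to
the smallest face index.

Hits are classified by normal and position: up-facing normals (within 45
degrees of the planned tool axis) split into bottom versus adjacent top
surface at half the planned depth; side-facing normals split left/right by
the sign of their lateral component. Sections with underpopulated essential
groups, or whose wall points scatter wider than a gap-free channel allows
(0.45 mm), are flagged missing — this is the operational stand-in for the
manual removal of air cells from a real mesh, and missing sections are
excluded from every statistic rather than imputed.

Per section: LD is the signed lateral offset of the resulting center line
(negative = left of the milling direction), DD the signed depth offset
(negative = deeper than planned), CW the right-minus-left wall distance,
CD the mean top-left/top-right height minus the bottom height. The
margin-violation length is the measured arc length where
max(|LD|, |DD|) exceeds the margin. In the full-procedure study the
measured window excludes the access-preparation/transition region, the
implant bed, and the widening (whose walls are intentionally not at the
channel width); the widening interval is available separately through the
plan's widening spec.

## Risk model

A per-patient probability r of violating the safety margin maps to a
per-point probability p through the binomial model 1 − (1 − p)^n = r, with
n = round(length / 1.2 mm) independent points (one per tool diameter; 50
for a 60 mm channel). Under a zero-mean Gaussian execution-error model the
admissible RMSE for margin m is m / z(p) with z the one-sided upper normal
quantile: a violation is a signed exceedance toward the protected
structure. The one-sided convention is the one that reproduces the
admissible limits of 0.22 mm (safety, r = 0.01%) and 0.28 mm (efficacy,
r = 1%) for the 1.0 mm margin; the end-to-end Monte-Carlo validation
simulates that same one-sided event and recovers the per-patient rate. The
inverse computation (minimum margin for a given RMSE) optionally folds in
the surface-reconstruction error (50 ± 50 um) as an independent additive
error: mean into the bias budget, SD convolved into the Gaussian width.

Summaries report mean, SD, RMSE, min, max per metric; the 99.9% RMSE
confidence interval is a chi-square interval on the sum of squares with
the effective sample size measured length / 1.2 mm, since adjacent samples
0.1 mm apart are correlated over about one tool diameter. The sample-size
calculator inverts the one-sample chi-square variance test (H0: sigma at
the admissible limit, H1: sigma at a pilot value, alpha 0.1%, power 95%)
over pooled measurements per specimen; it is validated against a
Monte-Carlo power oracle rather than against any fixed historical count,
whose exact inputs are not recoverable.

## Synthetic anatomy and study conditions

The generator emulates a curved temporal-bone slab: a domed outer surface
with smooth sinusoidal bumps, an inner (dura-side) surface at spatially
varying thickness, spherical air-cell voids in the interior, four fiducial
screws placed astride the entry-to-fantail corridor (so the channel passes
between them with margin, as a surgeon would plan), a fantail pose, a
tripod with marker volume, and a lazy-S incision trace. Full-scale defaults
are a 60 × 40 mm slab with the fantail ≥ 40 mm from the entry so a ~60 mm
channel fits; slab thickness 6 ± 1.5 mm keeps the 3.3 mm
(depth + margin) requirement satisfiable. Everything is deterministic per
seed.

The bundled study runs at desk scale so a full 12-site closed loop
completes in minutes on one core: 40 × 30 mm slabs, ~24 mm entry-to-exit,
30 mm channel target (lead 55 mm minus 25 mm tunnel), 0.05 mm carve
voxels, cross sections every 0.1 mm with a 4-degree fan, measured window
clipped 2.5 mm after the entry and 6 mm before the fantail. These sizes
are the package's own choices; the per-section metrics and their
recovery properties are scale-free.

What the synthetic loop shows: that planning, carving and metrology are
mutually consistent (zero-error carves measure back to the plan within
two voxels; injected rigid biases and smooth jitter are recovered
quantitatively; air-cell gaps become missing data, never substituted
values). What it does not show: any claim about a physical robot —
real milling forces, bone inhomogeneity, registration quality of a real
tracking system, or segmentation behavior of real CT reconstructions are
all outside the simulation, so the study's endpoint table describes the
pipeline, not a device.

## Known limitations

* The carve rasterizes bone by height-field interpolation; strongly
  overhanging anatomy would need a generic voxelizer.
* The widening's separate left/right wall treatment is exposed through the
  widening spec and boundary curves, not as a dedicated statistics table.
* The gap heuristic (group counts plus wall-scatter threshold) is an
  operationalization of a manual judgment; its thresholds are tuned to the
  rectangular-groove geometry and verified on constructed voids.
* The exposed-region side of the incision polyline uses an xy-projected
  nearest-segment convention; pathological 3-D incision traces could
  misclassify.
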