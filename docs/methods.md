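# Methods

This note documents the models, parameters and design decisions behind
`netquant3d`: what each stage computes, why the defaults are what they are,
what the synthetic phantoms do and do not emulate, and where the known
biases lie.

## Coordinate and unit conventions

All volumes are indexed `(z, y, x)`, channel-first when multi-channel,
matching z-stack acquisition order.  Physical voxel spacing `(dz, dy, dx)`
is attached in micrometres and supplied by the user (config or CLI): TIFF
resolution tags come in too many dialects to trust, so when tags and config
disagree the config wins and a warning is logged.  All internal lengths are
µm and volumes µm³; reporting units (default `m/m³`) are applied only at
output, with exact power-of-ten factors, so every intermediate number is
auditable.

Apparent z compression from the refractive-index mismatch between
immersion and clearing media is corrected by a user-supplied scalar factor
on `dz` (default 1.0, i.e. off).  The voxel data are never touched;
composing two corrections multiplies the factors.

## Segmentation

Trainable segmentation is a random forest (100 trees, fixed seed) over a
multiscale filter bank.  Default bank: Gaussian, difference-of-Gaussians
(σ vs 1.6σ), gradient magnitude, Laplacian and Hessian eigenvalues at four
scales σ ∈ {1, 2, 4, 8}·dx — a standard trainable-segmentation bank in
which the Hessian eigenvalues carry the tubeness information.  Sigmas are
expressed in µm and converted per axis to voxel units, so filters stay
physically isotropic on anisotropic grids; a σ below half a voxel along an
active axis is rejected (unresolvable scale).  For strongly anisotropic
stacks (dz ≫ dx, where a 3D σ cannot be honest in z) a per-slice 2D bank is
available.

The decision rule is foreground iff the forest posterior ≥ 0.5, ties going
to foreground — deterministic, and slightly favouring recall of thin
structures.  Classifiers are persisted as versioned archives carrying the
bank specification, seed and class names; loading an archive against a
mismatched bank is an error rather than a silent feature mismatch.

The acceleration toggle only switches prediction to chunked batches; the
contract (enforced by tests) is numerically identical masks either way.

The fixed-threshold baseline counts voxels *strictly* above a gray value
(the comparator convention is `value > 170` on 8-bit data, so a uniform
stack at exactly 170 counts zero voxels) and reports count, per-slice area
and volume in physical units.

## Particle exclusion

Operates per 2D slice: circularity is a 2D quantity and the classic
particle-analysis convention is slice-wise.  A component is removed iff its
area (pixel count) is ≤ `max_size` *and* its circularity `4πA/P²` falls in
`[lo, hi]`.  The perimeter estimator is the boundary crack length (number
of exposed pixel edges) — simple and exactly reproducible, but it
systematically overestimates smooth perimeters by up to ~27% (4/π), so
circularity values are lower than with polygonal estimators; the filter
band must be chosen for *this* estimator, and the single-pixel component is
defined to have circularity 1.  Defaults (filter off; when on, 50 px²,
circularity [0.5, 1.0], 8-connectivity) are placeholders and prominently
configurable — the appropriate values depend on magnification and labeling.

The filter only removes voxels (output ⊆ input), is idempotent, and
processes slices independently.

## Skeletonization and length

Binary masks are thinned with Lee-type 3D homotopic thinning
(`skimage.morphology.skeletonize(method="lee")`): connected components and
loops are preserved and the result is one voxel wide.  The skeleton is then
a graph whose nodes are skeleton voxels and whose edges are **all**
unordered 26-adjacent voxel pairs, each once.  Total length is the sum of
per-edge Euclidean distances between voxel centers in physical units.

Properties of this definition, all covered by tests: length scales exactly
with spacing; it is invariant under axis permutation (with matched spacing
permutation); it is additive over disjoint networks.  Known biases, which
are accepted and documented rather than corrected:

* a 26-adjacency voxel chain overestimates smooth oblique curves by a few
  per cent (no chain-code length correction is applied);
* thinning erodes tube ends by roughly one tube radius per end;
* at junctions every incident edge counts, so tight junction cliques add a
  small surplus.

On rasterized tube phantoms at radius 2–4 voxels these effects roughly
offset and net recovery lands within a few per cent of truth; the test
suite enforces a ±15% band per stack.  Anisotropy is handled at measurement
time (edges weighted by physical spacing) rather than by resampling, which
would interpolate structure at coarse z steps.

No spur pruning is performed: silently dropping short branches changes the
length; users who need despeckling can enable particle exclusion upstream,
where the removal is explicit and logged.

## Lobe volume and density

Sparse networks sketch the envelope of the tissue they innervate.  The
lobe estimate is: voxelwise union of the channel masks → morphological
closing with a *Euclidean ball of physical radius* (default 50 µm,
configurable; implemented with two anisotropy-aware distance transforms,
exact and memory-friendly at large radii; the volume is padded by the
radius first so closing is genuinely extensive at borders) → 3D hole
filling → voxel count × voxel volume.  The closing radius should be of the
order of the typical inter-structure gap; too small under-fills the
envelope, too large inflates convex deficits.  An empty union yields volume
0 with a warning and downstream results are flagged.

Density is length/volume with exact unit conversion (`m/m³`, `mm/mm³`,
`µm/µm³`).  Zero length over positive volume is a true density of 0; zero
volume is *flagged* (NaN), never reported as 0 — "no tissue" and "tissue
without network" are different findings.

For heatmaps, the lobe mask is built on the whole stack *first* and then
tiled together with the skeleton, so per-tile volumes are exactly additive
(closing across tile borders would otherwise create seam artifacts).
Skeleton edges crossing a tile border are dropped, a deficit bounded by
(number of cut edges) × (max edge length) and covered by a test.  Tiles
whose lobe volume is below 1% of the tile extent are reported NaN
("outside lobe").  Heatmap cell values are exactly re-derivable from the
accompanying CSV.

QC montages show, per stack and channel: max-intensity projection of the
raw data, MIP of the skeleton, and the overlay with the skeleton in
magenta.

## Synthetic phantoms

The phantom generator provides the ground truth that manual annotation
provides for real data, with one decisive advantage: the centerline length
is exact geometry, independent of rasterization.

Tubes are persistent random walks with fixed step length (4 µm), direction
persistence 0.95 and a per-step turn cap of 20° — curvature radius ≥ ~11 µm,
safely above the tube radius, because a fiber that bends tighter than its
own radius would fuse with itself in the mask and invalidate the length
ground truth.  Two further geometric guards serve the same purpose: tubes
keep a minimum clearance of 3× radius from each other and from their own
earlier course, and steps are re-drawn when they would violate it.  Near
the domain boundary (the grid box, or an ellipsoid envelope emulating a
tissue lobe, which also supplies an exact analytic volume) a soft inward
bias makes walks graze rather than hit walls; residual hits reflect
specularly with the wall point inserted into the polyline, so each step
contributes exactly its step length.  A fiber that runs out of admissible
directions ends, and growth restarts at a fresh clear location ("fiber
segments"), spending a fixed per-tube step budget; total truth length is
the exact polyline sum whatever the segment structure.

Rasterization marks every voxel within the tube radius (default 3 µm) of a
centerline, using an anisotropic distance transform, then renders
background 30 / tube 200 (8-bit), a Gaussian blur of σ 0.5 µm standing in
for the point-spread function, and additive Gaussian noise of σ 15 —
separable but not trivially so, roughly the contrast of a well-stained
confocal stack.  Default grid: 44 × 160 × 160 voxels at (1.25, 1, 1) µm —
anisotropic z like real stacks, scaled to desk size.  Study sets default to
10 stacks split 2 training / 8 validation, with tube count varying from 3
to 10 across validation stacks so regression spans a realistic length
range.  Per-stack seeds derive deterministically from one master seed.

What the phantoms do **not** emulate: realistic light-sheet/confocal
optics (depth-dependent PSF, attenuation, stripe artifacts), branching
trees, touching/crossing fibers, intensity variation along fibers, or
autofluorescent background structure.  Passing the phantom study therefore
demonstrates the correctness of the measurement chain on clean tubular
signal — not segmentation robustness against every real-tissue artifact,
which remains the responsibility of classifier training on real data.

Annotation for training is synthesized the way a user scribbles in an
interactive labeler: foreground strokes well inside tubes, background
strokes both in the annulus just outside tube surfaces and in the far
background (300 voxels per class per stack).

## Evaluation harness

Automated lengths are regressed on reference lengths with OLS *including
an intercept* (forcing through zero would hide exactly the additive bias
the harness is meant to expose); r² is the squared Pearson correlation,
which for OLS-with-intercept equals the coefficient of determination.  MAE
is reported in the input unit with no silent conversion.  The annotator
spread utility reports per-measurement absolute error to the group mean.
The fixed-threshold baseline pairs reference lengths with thresholded
*areas* — different units, so only its r² is meaningful, and it degrades as
soon as tube radius varies across stacks, which is the point of the
comparison.

## Problem sizes and numerical choices

The shipped study runs at desk scale: 44 × 160 × 160-voxel phantoms
(~1.1 M voxels), 10-stack sets, 100-tree forests — large enough for every
bias discussed above to be measurable, small enough that the full suite
and the acceptance script each complete in minutes on one CPU.  Stochastic
stages draw from `numpy.random.default_rng` seeded per stage; reruns with
one config and seed are byte-identical, with or without acceleration.
Degenerate inputs are contracts, not crashes: empty masks yield empty
skeletons and zero length; empty unions yield flagged volume 0; constant
reference vectors are rejected as degenerate regressions; single-class
annotations are rejected with instruction to label both classes.
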