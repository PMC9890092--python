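# Methods

This note records the models, numerical choices and known limitations of
`ossomech`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Articulated skeleton and joint coordinate systems

A limb model is a tree of rigid segments; each segment's `rest_transform`
places it in its parent's frame at the reference pose, defined as 0° at
every joint angle. Coordinates are right-handed with +x anterior, +y
dorsal, +z lateral (right side); lengths are metres and all interface
angles degrees (radians internally).

Joints carry three rotational axes through one fixed centre: one axis
parented to the proximal segment, one to the distal segment, and a
floating axis. The composition order is proximal → floating → distal, a
Grood–Suntay-style joint coordinate system; expressed in world matrices
the joint rotation is Q = R(a₃″,θ₃)·R(a₂′,θ₂)·R(a₁,θ₁), where a₂′ and a₃″
are the floating and distal axis directions updated by the preceding
rotations. This order makes the floating axis well defined and matches
standard biomechanics practice; the alternative orders differ only in the
meaning of stored angles, not in expressiveness. At any pose the floating
axis is recomputed as the sign-fixed unit cross product of the proximal
and distal axes; when those two axes come within 0.5° of parallel the pose
is rejected as gimbal-singular rather than silently ill-conditioned. The
three axes must be mutually perpendicular at the reference pose (|dot| ≤
1e-6), which every generated and validated model satisfies exactly.

Positive rotation sense is the right-hand rule about the declared axis
direction, and each direction is named by its `action_pair` in the model
file — sign conventions are data, not code. The reporting convention used
by the standard protocols takes protraction, adduction and medial rotation
as positive at the shoulder, and flexion, adduction and medial rotation at
the elbow.

Joint centres are normally model inputs; `fit_joint_centre` is a helper
that fits a circle (best total-least-squares plane, then an algebraic
Kåsa fit refined by nonlinear least squares) or a sphere to digitized
articular points and reports the RMS radial residual.

## Muscle paths and wrapping

Muscles are 1 or 3 strands (posterior/midline/anterior for broad
attachments) from origin to insertion. Via points are inviolable anchors;
between consecutive anchors the path is the shortest route around that
leg's wrapping cylinders. For a single cylinder the solution is closed
form: in cylinder coordinates the planar segment either misses the circle
(straight path) or is replaced by tangent line – arc – tangent line, with
the deflection side chosen as the tangent solution whose arc midpoint has
positive dot product with the declared side hint (tie at exactly zero →
the first-listed, counterclockwise solution). The axial coordinate is
distributed linearly over planar arc length — the on-cylinder portion is
then a geodesic helix — giving total length hypot(t₁ + rφ + t₂, Δz).
Multiple cylinders on one leg are resolved by fixed-point iteration,
re-solving each cylinder against its neighbouring tangent points until the
total length changes by < 1e-10 relative (max 100 iterations, then a
convergence error with diagnostics).

Cylinders are infinite for the tangency math; a wrap whose touch points
leave the declared ±half-length band raises a warning, not an error,
since end-cap behaviour is not otherwise defined. Strands may slide on
and off cylinders across a sweep; path length is continuous at the
tangency transition by construction.

## Moment arms

Moment arms use tendon excursion: r = −dL/dθ with θ in radians, evaluated
by central differences. On a sweep's own degree of freedom the derivative
is taken on the 5° grid itself (one-sided at the two ends); for the other
two DOFs of the joint, an off-grid central difference with step h = half
the grid spacing (2.5°, configurable) is used at each grid pose. The grid
scheme has the property that the trapezoid integral of r telescopes
exactly back to L(θ_end) − L(θ_start), so the excursion–integral identity
holds to round-off; fine-step differences (h ≈ 0.1–0.25°) are used when
comparing against analytic oracles, where truncation error O(h²) matters.

The standardized protocols are: glenohumeral, 17 poses from 40° retraction
to 40° protraction at 5°, humerus adducted 90°, long-axis neutral, elbow
flexed 45°; elbow, 19 poses from 10° to 100° flexion at 5°, humerus
adducted 90° and protracted 20°. Normalization divides raw moment arms by
the taxon's minimum humeral shaft circumference C_min (a body-size proxy),
applied at sweep level so every downstream statistic is dimensionless; raw
values are retained alongside. C_min is a model-file scalar, or can be
measured from a watertight mesh as the minimum convex-hull perimeter of
≥100 cross-sections over the middle 60% of the shaft.

Multi-strand pooling computes mean/min/max over the pooled multiset of all
strand × pose values (not per-pose averages first) — the plain reading of
pooling "from the values obtained from all strands". Cells adjacent to a
wrap on/off transition are flagged but remain in the pooled statistics; no
exclusion rule is defined for them.

## Action summaries

For each joint DOF, a muscle contributes |mean r_norm| to the positive- or
negative-named action column according to the sign of its mean; an exactly
zero mean contributes to neither. This "magnitude of means" rule collapses
within-sweep sign variation before summation and is deliberate — it
changes results relative to "mean of magnitudes" and mirrors summing from
the per-muscle mean moment arms. Ratios are oriented positive/negative
action; a zero denominator with positive numerator is recorded as +inf and
flagged, 0/0 as NaN.

## Tree time-scaling and pPCA

Time-scaling is "basic" dating: node age = oldest first appearance among
descendants, with a minimum branch length (default 1.0 Myr) enforced in a
single children-first pass, so each parent is pushed rootward exactly as
far as its oldest child requires. The minimum also guarantees an
invertible Brownian covariance C, whose entries are root-to-MRCA path
lengths; polytomies are handled naturally.

The pPCA uses the GLS phylogenetic mean and evolutionary covariance given
in the README. Four modes: `bm-correlation` (default — the evolutionary
*correlation* matrix is decomposed and scores are computed on
standardized deviations), `bm-covariance`, `uniform-bl` (all branch
lengths set to 1 before C), and `ordinary` (arithmetic mean and sample
moments, no tree). The correlation default follows the primary analysis
convention; covariance mode is retained as first-class because reference
implementations default to it. The implementation is verified in the test
suite against phytools' `phyl.pca` (via Rscript) to 1e-8, but phytools is
only an oracle, never the computation. Eigenvalues are sorted descending
(stable ties by trait order), negative values above −1e-12 are clipped to
zero, and each loading column is flipped so its largest-magnitude element
is positive — PCA signs being arbitrary, this makes outputs deterministic.

## Sensitivity variants

`pose-adduction` (75° splayed / 115° tucked) edits only the sweep context.
`scapular-slope` rotates the scapulocoracoid's rest placement about the
mediolateral axis anchored at the glenohumeral centre, so the glenoid
stays fixed in space and glenohumeral geometry remains comparable; the
model declares its base slope in `meta`. `elbow-axis-translation` moves
the (shared) elbow joint centre along the epicondyle-to-epicondyle chord
to the stated fraction of condyle width; because the extension–flexion
axis runs along that chord, its line is unchanged, so the variant isolates
the abduction–adduction (and long-axis) lever geometry, which is the
quantity of interest. Any off-chord component of the original centre is
preserved.

Rank consistency compares taxa ordered by summed magnitudes (ties broken
alphabetically) via Kendall's tau against the base set, lists the inverted
pairs explicitly, and flags taxon pairs whose min–max envelopes across
variants overlap. The direction of the lateral-translation check (a more
lateral axis raising summed abduction and lowering adduction) depends
entirely on the declared positive sense of the abduction–adduction pair;
the tests declare that sense to match the study convention for this check.

## Osteometric correlations

Landmark displacements are measured at the reference pose: landmark and
joint centre are expressed in the declared segment frame, projected onto
the named coordinate plane (XY/XZ/YZ), and the in-plane distance is
divided by C_min — the normalization commutes with projection, so its
order is immaterial. Regression of mean moment arms on displacements is
ordinary least squares (no error model is implied for the trendline);
reduced major axis is available behind a flag. Exclusion of taxa is purely
data-driven (a per-taxon flag with a reason string), never inferred from
geometry, and both the excluded and all-taxa fits are always reported.

## Synthetic data: what it emulates and what it does not

The generators provide every input class with known ground truth, all pure
functions of (spec, seed); one 64-bit seed fans out to per-component
streams by stable hashing, so adding a generator never perturbs existing
fixtures.

*Limbs* are abstract three-segment chains (trunk → upper arm → forearm)
with two standard three-axis joints and muscles drawn from three
archetypes, each carrying a closed-form moment-arm annotation for the
shoulder sweep: straight-line strands (lever by the cross-product formula;
origins placed dorsal/ventral of the joint so the lever stays ≥ 0.03 ×
scale over the whole ±40° range, retried up to 100 placements), coaxial
wraps (a cylinder on the swept axis with attachments at ~2 radii on
opposite sides, so the wrap never disengages within the sweep and |r|
equals the radius exactly), and zero strands (spanning only the distal
joint, hence rigid to the shoulder sweep). Geometry is deliberately
abstract: no attempt is made to mimic real ornithischian anatomy, muscle
counts, or attachment topology, so oracle agreement demonstrates numerical
correctness of the pipeline, not anatomical realism of any model.

*Clades* are random rooted binary topologies with uniform first
appearances (default 70–200 Ma, spanning a Mesozoic-like interval) dated
by the basic+minimum rule. *Action tables* (default 17 taxa in 4
monophyletic clades on a pectinate backbone with staggered 25 Myr
stratigraphic windows from 200 Ma) evolve log-values by Brownian motion
(rate 0.0015 per Myr, giving tip standard deviations ≈ 0.4 log units over
the tree depth) around per-action baselines drawn once in 0.3–1.2, with
optional clade-level mean shifts: one shared ±1 pattern over designated
actions with per-clade scalars when actions are given explicitly (a
rank-one planted signal recoverable on PC1), or independent per-clade
action choices otherwise. Values are strictly positive by construction
(exponential link), matching the nonnegativity of summed magnitudes.
These defaults were chosen once as plausible study-scale conditions and
are not tuned.

The clade-separation permutation test whitens by C^{-1/2} after removing
the GLS mean; without this, shared ancestry alone separates monophyletic
clade centroids and the pure-BM null would always reject.

## Problem sizes and determinism

The verification suite evaluates 50 seeded limbs (~10⁴ oracle cells) with
fine-step differences, 100 Brownian replicates at 64 tips for planted-axis
recovery, and 2000 replicates on a 3-tip tree for the tip-covariance law;
these sizes give comfortable statistical margins while keeping the whole
suite and the acceptance script each under a minute of compute. All
numeric outputs are bitwise reproducible for fixed seed and inputs, and
pipeline runs index every output file by content hash in a JSON manifest.

## Known limitations

- Only cylindrical obstacles; no spheres/ellipsoids, no mesh collision.
- No muscle force, architecture, PCSA or dynamic simulation — leverage
  geometry only.
- The wrapping fixed point has no global-optimality guarantee for many
  mutually interacting cylinders on one leg, though it is exact for the
  single-cylinder case and converges rapidly in practice.
- Time-scaling implements basic dating only; stochastic tip-dating
  variants are out of scope.
- Phylogenetic signal statistics and ancestral-state reconstruction are
  out of scope; the pPCA assumes Brownian motion as given.
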