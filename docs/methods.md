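# Methods

This note records the models implemented in `shapecode`, the parameter
choices that matter, and the places where the design was genuinely open.

## Superquadric geometry

A shape is the level set `F = 1` of

    F(x, y, z) = (|x|/A1)^(2/eps1) + (|y|/A2)^(2/eps2) + (|z|/A3)^(2/eps3)

in object-aligned coordinates. The `2/eps` exponent convention makes
`eps = 1` an ellipsoid and `eps -> 0` a box, and the absolute values keep
fractional powers well defined; the frequently printed variant with
exponents `1/eps` and level `0` cannot bound a closed surface, so the
standard form is used. Rotation uses the three-angle matrix
`R = Rz(-th3) Ry(-th2) Rx(-th1)` (orthonormal, det +1), applied as the
world-to-object transform. Exponents are floored at 0.01: far below
that, `2/eps` exceeds a few hundred and the implicit function overflows
to infinity within a grid cell of the surface, which the renderer
tolerates (the sign of `F - 1` is all bracketing needs) but root-finding
conditioning degrades.

### Canonicalization

One surface admits many parameterizations (a tall box is a wide box on
its end). To make shape -> depth map invertible on canonical forms, each
class gets a restricted angle range:

- true spheres: angles set to 0 (full rotational symmetry);
- cylinder-like shapes (round cross-section about object z): the spin
  angle `th3` is redundant and set to 0; the symmetry axis is flipped
  into the `th1, th2 in [-pi/2, pi/2]` range;
- box-like shapes (including plates and non-spherical ellipsoids): of
  the 24 octahedral relabelings `(S^T R, A permuted, eps permuted)`, the
  candidate whose angles lie within (or closest to within) +/- pi/4,
  ties broken lexicographically.

The Euler-angle cube `(+/- pi/4)^3` has Haar volume `sqrt(2)/32`, just
above `1/24` of SO(3), so a valid candidate exists for almost every
rotation; boundary ties are resolved deterministically. Tests verify
the contract with the renderer: canonicalized shapes render identically
to 1e-6 m, and the map is idempotent.

## The synthetic shape database

The database sampler is the package's data generator; its defaults are
the study conditions. Box-, sphere-, and cylinder-like shapes appear in
equal thirds. Semi-axes are uniform with widths `2A in [0.02, 0.12] m`
(graspable object sizes at arm's length). Round edges use `eps = 1`;
squared edges draw `eps` from the shifted exponential
`p = 10 H(eps - 0.01) exp(-(eps - 0.01)/0.1)` (mean 0.11), which keeps
corners sharp but numerically non-degenerate. Rotations are sampled
uniformly per angle over each class's canonical range — the database
needs arbitrary-but-canonical poses, not Haar-uniform ones. The split
is 70/30 train/validation. Sphere-like entries are mild ellipsoids
(per-axis jitter of +/-15% around a common radius): exact spheres would
make the class a measure-zero slice with no orientation content.
Cylinder-like entries have an elongated third axis (`A3 in [0.035,
0.06]`, cross-section radius at most 0.65 A3) so the class is visually
distinct from the boxes.

What the generator does *not* emulate: natural-object surface texture,
concavities, multi-part objects, or measurement noise in depth. Tests
passing on this database show that the pipeline behaves as designed on
the idealized shape family, not that it would survive real stereo data.

## Depth-map rendering

The observer sits at the origin looking along +z; shapes are centered at
(0, 0, 0.75) m. Rays pass through a 16 x 16 grid of visual angles
covering +/- 10 degrees: `angle = sign(a) |a|^1.5 x 10 deg` for `a`
evenly spaced in [-1, 1], concentrating samples foveally so even the
smallest shapes catch a few rays. Depth is the Euclidean distance along
the ray (not the z-coordinate). Intersections are found by a 512-step
coarse march over ray distance t in [0.6, 0.95] m (every shape's surface
lies inside this bracket: maximum half-diagonal 0.06 x sqrt(3) ~ 0.104 m)
followed by bisection to 1e-6 m. Rays that miss are filled with the
distance to a frontoparallel background plane at z = 0.9 m — a choice
the source conditions leave open; a plane keeps the derivative channels
finite and smooth at silhouettes, unlike an infinite or NaN fill.

## CIP-like features

Five channels per shape: depth, dz/dx, dz/dy, d2z/dx2, d2z/dy2, each
16 x 16, flattened row-major channel-last to 1280 values. Derivatives
are correlations with the separable kernels `[1 1 1]^T [1 0 -1]` and
`[1 1 1]^T [0.5 -1 0.5]` (and transposes), replicate padding, applied in
grid-index space — deliberately ignoring the warped grid metric, because
the modeled population convolves the sampled map directly. Sign
convention: `[1 0 -1]` responds positively to depth decreasing with
column index.

Curved-surface stimuli `z = (K1 x^2 + K2 y^2)/2` come with the
curvature decomposition `C = sqrt((Kmax^2 + Kmin^2)/2)`,
`SI = (2/pi) arctan((Kmax + Kmin)/(Kmax - Kmin))`; the symmetric case
`Kmax = Kmin` takes the limit SI = +/-1 (0 when flat). The expanded
tuning variables `(3X^2 - 1)/2` on the second-derivative channels are
the quadratics that linear readout from cosine-tuned LIF populations
reconstructs most accurately.

The V3A variant applies 7 pointwise disparity-tuning functions to depth:
Gaussians centered at 0.65–0.85 m in 0.05 m steps (SD 0.05 m) for tuned
near/zero/far cells, and complementary near/far sigmoids (center 0.75 m,
slope 25 /m). No published parameter set pins these down; they are
config-exposed defaults chosen to tile the working depth range.

## Neuron models

**Cosine-LIF.** `I = phi^T x + b`;
`r = 1/(tau_ref - tau_rc ln(1 - 1/I))` above the unit threshold, 0 at or
below it (the closed form is undefined there; zero is the standard LIF
convention). `tau_ref = 5 ms`; `tau_rc` is a fit parameter in
[0.02, 0.2] s unless noise is on.

**Noisy rates.** Gaussian background current noise makes the effective
rate function sigmoidal or nearly linear instead of hard-thresholded.
Rates are simulated by Euler steps of `tau_rc dV = (-V + I + sigma xi) dt`
with `dt = 1e-4 s`, iid standard-normal `xi` per step (the noise
convention is per-step current noise of SD sigma at this dt; no
`sqrt(dt)` scaling is applied, so sigma is interpreted at the simulation
resolution), 5 s per cell, on a grid `I in [0, 4]` step 0.05, `sigma in
[0, 2]` step 0.1, then interpolated bilinearly. One noise path is shared
across all grid cells, which couples the cells monotonically in I and
makes "rates nondecreasing in current" hold row-wise by construction
rather than only in expectation. At sigma = 0 the simulation matches
the closed form within 2% on I in [1.1, 3] (discretization bias is
~dt x rate).

**Dendritic-branch model.** 50 branches; each computes a logistic
sigmoid of the dot product between its random standard-normal 3 x 3
kernel and the depth patch ("point-wise product" read as the product
summed — the only reading under which branches are cosine-tuned to the
depths). The readout is least squares through a truncated-SVD
pseudoinverse with a stated number of singular values (14/20/40 in the
reference experiments); truncation acts as regularization when stimuli
are few. The pseudoinverse rank cannot exceed min(#stimuli, #branches),
so a 13-stimulus curve supports at most 13 singular values; the
14-singular-value configuration applies to the augmented 26-stimulus
version.

**NEF decoders.** Ridge least squares with
`lambda = 0.1 x mean(diag(R^T R))` by default (the NEF noise-term
convention, keeping decoders finite for silent populations); the
composition `w^T = phi^T Phi` is an exact identity and is tested as one.

## Augmented tuning curves and fitting

The 36-stimulus design: sphere, cube, plate, cylinder x 4 uniform sizes
(scale factors 0.55/0.70/0.85/1.0) x 4 orientations, where orientations
rotate the upright shape about the horizontal x axis by 0, 90, +45, -45
degrees (upright / lying along the view axis / tilted forward /
backward). One rotation axis keeps the pose one-dimensional, which is
why the fits encode it as the 2D direction vector (cos psi, sin psi) —
8 features total with no angle wrap-around. Symmetry removes 28 of the
64 combinations: all sphere rotations; cube 90-degree turns (horizontal
== vertical, and the -45 tilt equals the +45 tilt exactly); and the
plate/cylinder backward tilt, which is the forward tilt's mirror image
(its depth map is the forward map flipped about the horizontal axis —
the renderer-based check accepts exact equality or this flip). The
survivor count is 4 x (1 + 2 + 3 + 3) = 36.

Augmentation: `rate = baseline + (base - baseline) x size_factor x
orient_factor`, with the size factor 1 (invariant) or proportional to
scale (monotone, reaching 1 at the largest size), and a Gaussian
orientation factor (SD 45 degrees — "fairly narrow" relative to the
90-degree pose range; config-exposed) wrapped at 180 degrees. The
multiplicative-with-baseline combination is one consistent reading of
how shape, size, and orientation selectivity compose; the reference
stimuli (largest size, preferred orientation) reproduce the base rates
exactly. The shipped shape-tuning profiles in `murata_archetypes()` are
synthetic stand-ins constructed to represent the described selectivity
classes (weakly responsive; cube-preferring; strongly
cylinder-selective; broad; plate+cylinder; plate==cylinder), not
digitized data.

Fitting standardizes features internally, draws initial points
`phi ~ N(0, I)`, `b ~ U(-2, 2)`, `tau_rc ~ U(0.02, 0.2)` (random
restarts; 200 by default in tests, more for production fits), solves
each start with a bounded trust-region least-squares solver, and keeps
the best. An optional SSE early-stop ends the restart loop once the fit
is already far below the tolerance being tested; the restart cap is
unchanged. Noiseless planted neurons over the 36 stimuli are recovered
to rate-RMSE < 1e-3 spikes/s.

One caveat on "invariance = zero preferred-direction components": in
this stimulus set the scale features A1–A3 carry shape identity as well
as size (a plate's thin axis is a scale), so a size-invariant fit
shrinks the *size drive* (variation of current along the uniform-scale
direction) rather than the raw components; the tests check the
comparative form.

Levene's W is implemented directly as the one-way ANOVA F statistic on
absolute deviations from group means, `p` from `F(k-1, N-k)`;
`scipy.stats.levene(center="mean")` serves as the oracle in tests. Two
groups of 456 errors give the df pair (1, 910).

## Isomap shape space

Feature space: the four derivative channels (1024 values per shape),
native units, no standardization. Pipeline: exact k-NN graph (k = 10
default) on Euclidean distances, symmetrized by the maximum; Dijkstra
all-pairs geodesics on the sparse graph; classical MDS of the geodesic
matrix with the top-d eigenpairs (d = 8/16/32 presets). Determinism is
pinned by an eigen-sign convention (largest-magnitude entry positive).
A disconnected graph is an error naming the component sizes — silently
growing k would change the geodesic metric mid-analysis. Residual
variance is `1 - R^2` between geodesic and embedded distances.

Out-of-sample extension: geodesics from a new point are approximated
through its k nearest training anchors (Euclidean hop + stored geodesic
onward), then the Nystrom/landmark-MDS formula
`y_d = v_d^T (mu - g^2) / (2 sqrt(lambda_d))` gives coordinates; for a
training point this reproduces its coordinate exactly (shown
algebraically by the eigenvector identity, and tested). Queries whose
nearest anchor exceeds the 95th percentile of training nearest-neighbor
distances are flagged rather than refused.

Desk-scale runs (<= 5,000 points) use the exact Isomap throughout. A
landmark variant for 40,000-point runs is the same Nystrom machinery
applied from a landmark subset; the desk-scale experiments here do not
need it.

One diagnostic deserves a note: a radius-swept sphere family embeds as
a clean 1-D curve (rank correlation 1.0 with radius), but its feature
sequence contains discrete jumps wherever a new ring of grid rays first
intersects the growing sphere, so the neighborhood must be wide (k = 40
at 300 samples) to bridge them; generic shape databases vary along many
parameters at once and connect already at k = 10.

## CIP -> AIP networks

MLP: 1280 -> 600 -> 300 -> d, logistic hidden units, linear output (so
the outputs can serve as decoded currents for downstream cosine-tuned
neurons). Training is adaptive-moment gradient descent (batch 64,
learning rate 1e-3, up to 200 epochs, early stopping on a held-out
tenth with patience 10), deterministic per seed; the optimizer details
are not pinned by any published description and are config-exposed.
Inputs are z-scored per feature using training statistics (conditioning;
the raw-unit contract applies to the Isomap features, not the network);
raw mode is available. Targets: canonicalized superquadric parameters
(9 values; the single-axis 2D-direction encoding is available where the
dataset rotates about one axis) or Isomap coordinates (d = 8, matching
the superquadric count when one angle uses the 2D encoding; the
reference scatterplots show at least 7 dimensions).

The NEF alternative draws each hidden neuron's preferred direction as a
normalized random kernel over one local patch (4 x 4, one channel) of
the feature grid, samples max rates U(100, 200) spikes/s and intercepts
U(-1, 1), and fits ridge decoders. It tracks the MLP qualitatively but
needs more units for the same error, as expected for a one-shot random
basis versus trained features.

Evaluation reports per-dimension correlations/slopes and per-shape
Euclidean error; the normalized error (mean Euclidean error / RMS norm
of centered targets) makes the two target spaces comparable. Problem
sizes for the standard experiments: the shared desk-scale run uses
4,000 shapes (2,800/1,200 split, d = 8) for the error-vs-distance
comparison, and the seed-contrast experiment uses 1,200 shapes with the
full 600/300 architecture across 3 seeds. At these sizes the median
Isomap prediction error sits near 5% of the median pairwise shape
distance, and the normalized Isomap error beats the superquadric error
by a factor of roughly seven on every seed.

## Known limitations

- Depth is monocular distance, not binocular disparity; no vergence
  geometry, occlusion between objects, or texture/perspective cues.
- The tuning-curve archetypes are synthetic; no digitized
  electrophysiology enters the pipeline, so fits exercise the machinery
  rather than reproduce published error bars.
- The canonicalization tie-break at exact +/- pi/4 boundaries picks one
  of the equivalent forms lexicographically; downstream learners see
  the discontinuity there by design.
- The noisy-rate table interpolates bilinearly; rate curvature between
  sigma grid lines is not captured below the 0.1 grid step.
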