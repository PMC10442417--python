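# Methods

This note documents the models and numerical choices behind `mouselift`:
what is being fit, which knobs matter, how the synthetic study conditions
are defined, and where the method's limits are.

## Kinematic model

The mouse is a tree of 18 spherical joints: a spine/tail chain
(nose — upper/middle/lower spine — tail base — tail tip) and four
three-segment limbs (shoulder/elbow/wrist, hip/knee/ankle per side),
rooted at the pelvis (the lower-spine point, defined as the midpoint
between the hips). Each joint carries an axis-angle rotation vector —
singularity-free near the identity and exactly three parameters per
spherical joint, 54 in total. A non-root joint sits at its parent's
position plus the chain-composed rotation applied to its unit rest
direction scaled by its bone length (17 bones, mm). The rest pose lays the
spine along the x-axis (upper-spine→middle-spine = +x, which is also the
canonical pose-normalization frame), dorsal side up, limbs splayed 45°
downward. The two ear keypoints are rigid offsets in the head segment's
frame; they complete the 20-point annotation set but are never part of the
chain or the optimizer residual.

The analytic position Jacobian (`fk_jacobian`) propagates local axis-angle
perturbations through the SO(3) right Jacobian and is verified against
central differences in the test suite.

## Cameras and triangulation

Pinhole model with optional Brown–Conrady distortion (three radial, two
tangential coefficients, zero by default); world frame on the cage floor
with z up; pixel origin at the top-left pixel centre, y down. Calibration
files are YAML with the intrinsic matrix, distortion vector, rotation,
translation and image size.

Triangulation undistorts the observations, initializes with the
homogeneous DLT solution, and refines with a damped Gauss–Newton
minimization of the squared pixel reprojection error (max 50 iterations,
step tolerance 1e-10 mm; steps that would increase the objective are
rejected, so the refined RMSE never exceeds the DLT RMSE). Pairs of views
whose rays subtend less than 1° are flagged ill-conditioned. Per-keypoint
multiview reconstruction requires two views; points seen in fewer views
are returned invalid rather than failing the frame.

## Priors

**Pose prior** (5 components): poses are canonically aligned — translate
the base of the neck (upper spine) to the origin, rotate the vector to the
middle spine onto +x and scale it to unit length, then resolve the
remaining roll by putting the hip midpoint in the xz-plane on the ventral
side. The 18 joints' aligned coordinates (54 dimensions) feed a
full-covariance Gaussian mixture fit by EM (scikit-learn, k-means++ init,
best of 5 restarts, seeded). Alignment makes the prior invariant to rigid
motion and uniform scale of the input poses.

**Shape prior** (7 components): the mixture is fit on per-specimen
bone-length vectors (17 dimensions, mm). Two specific choices:

* *Covariance floor.* Generic fits use a 1e-6 eigenvalue floor, but for
  the shape prior the floor is the square of the bone-length measurement
  precision, 0.04 mm² (0.2 mm). With ~80 specimens split over 7
  full-covariance components in 17 dimensions, EM otherwise collapses
  components onto a dozen samples each and near-singular covariances; a
  degenerate prior assigns absurd penalties to new animals and, because a
  single view leaves depth to the prior, drags the reconstruction
  millimetres off truth. The pose prior keeps the tight floor — its
  coordinates are dimensionless and its tightness is precisely what pins
  monocular depth.
* *Canonical row order.* Specimens are exchangeable, so rows are sorted
  lexicographically before fitting; the fitted prior is then independent
  of how the table was sorted.

Both priors enter the energy as exact mixture negative log-likelihoods.

## The lifting energy and its optimizer

One frame's energy is the squared pixel reprojection error over usable
keypoints (confidence ≥ 0.05 by default; ears excluded) plus
λₚ·NLL(pose prior) + λₛ·NLL(shape prior). Defaults λₚ = 1e-2,
λₛ = 1e-1: the pose prior is deliberately weak — it should keep feet below
the body, not pin the pose to the mixture modes — while bone lengths are
only weakly observable in one view and need the stronger pull.

Parameterization: 54 angles, 17 *log* bone lengths (positivity by
construction), and the two normalized-image coordinates of the root's
viewing ray — the root is thereby constrained exactly to the sphere of
radius `fixed_distance` around the camera centre for the whole
optimization. The fixed distance is a rig property the user must supply;
it is what resolves the size/depth confound of a single view.

The solver is scipy's trust-region-reflective least squares with 2-point
finite-difference Jacobians and explicit parameter scaling (1 rad, 0.2 log
units, 0.05 ray units). Inside the solver each mixture penalty is
represented by the whitened residual vector of its currently dominant
component, √(λ/2)·L_j⁻¹(x − μ_j) with j the highest-responsibility
component. A single scalar √NLL row was measured to give the Gauss–Newton
model only rank-1 curvature: the solver crawled for >1400 iterations and
stalled ~1 px short of the optimum. The dominant-component form equals the
mixture NLL up to a locally constant offset, exposes the penalty's full
curvature, and converges in tens of iterations (≈1 s per frame). Reported
energies and the term-wise breakdown always use the exact mixture NLL, and
the energy trace records the best-so-far exact energy over solver
evaluations (monotone by construction).

Initialization is deterministic: rest-pose angles; root on the
back-projected ray of the lower-spine observation at the fixed distance;
body yaw from the observed 2D lower→upper spine direction; bone lengths at
the shape prior's mixture mean. If the spine points are unusable, the root
falls back to the centroid ray of the remaining points and the fit is
flagged. Sequences warm-start each frame from the previous solution;
frames that fail (e.g. everything occluded) are flagged and skipped, and
the next frame falls back to the last good solution.

Non-convergence is a reported state, not an exception; fewer than 4 usable
keypoints is an error.

## Keypoint evaluation (OKS)

Per keypoint: exp(−d²/(2k²s²)) with falloff k = 0.08 for all 20 points and
object scale s = √(area of the minimal box over the ground-truth
keypoints). The aggregate divides by all 20 keypoints regardless of
visibility (annotators mark a best guess when occluded); a visible-only
mode exists but is off by default. A threshold T is equivalent to a pixel
radius R = k·s·√(−2 ln T); `scale_from_radius` inverts this, which lets a
printed (T, R) pair from an accuracy table determine the object scale and
reproduce the radii at other thresholds.

## Gait

Foot position along the motion axis (configurable joint, ankle by
default) is detrended by subtracting a 1 s moving-average baseline. The
aggregate stride frequency is the dominant peak of the magnitude spectrum
searched above 1 Hz (excluding drift) and below Nyquist, refined by
quadratic interpolation around the peak bin; a peak below 4× the in-band
median magnitude is reported as "no gait" rather than a number. Stride
length = belt speed / frequency. Individual strides are peak-to-peak times
(prominence ≥ 0.25 trace SD, separation ≥ half the aggregate period);
lengths are durations × belt speed, and values beyond 2.3 σ of the mean
(mean and SD computed once, not iteratively) are flagged as outliers. The
mouse stride band is 3–10 Hz, so a 24 fps camera already satisfies
Nyquist; both band edges are resolved in the tests at 24 fps.

## Synthetic study conditions

The generators define the conditions every benchmark runs at; they are
fixed, not tuned per test:

* **Cohort**: 80 specimens in 4 size groups (uniform scale 0.85–1.15 of
  the canonical adult lengths), 3% within-group coefficient of variation
  per bone.
* **Poses**: gait mode swings each limb ±30° about the left-right axis,
  left/right in antiphase, distal segments a quarter-cycle behind; bone
  lengths come from a seeded cohort row, so sampled animals carry
  realistic size and shape variation (the pose prior needs that shape
  variance to estimate depth without bias). Random mode draws all angles
  uniformly in ±45°.
* **Rig**: one top-down camera 400 mm over the cage centre plus two side
  cameras at 450 mm, 90° apart; f = 800 px, 640×480.
* **Observations**: isotropic Gaussian pixel noise; occlusion marks
  ⌊fraction·20⌋ randomly chosen keypoints with confidence 0 in every view.
* **Gait traces**: amplitude·sin(2πft) + drift·t + noise at a given fps.

Benchmarks (in `mouselift.evaluation`, used by both the test suite and
`scripts/acceptance.py`): 50 single-view scenes noiseless and 50 at
σ = 2 px with 25% occlusion, lifted at the true distance; 10 multiview
scenes; 100 pose-prior ranking trials. Problem sizes keep the full run at
a few minutes on one CPU.

What the synthetic data does *not* emulate: detector-specific error
structure (real 2D networks err anisotropically and miss systematically
under self-occlusion, not i.i.d.), soft-tissue deformation (bone lengths
here are exactly constant within an animal), spine flexion during gait,
multi-animal interaction, and lens distortion in the default rig (the
model supports it; the generators leave it zero). Passing benchmarks
therefore demonstrate the estimator's correctness and its behaviour under
idealized noise, not end-to-end accuracy on video.

## Known limitations

* Monocular depth is fundamentally prior-determined: with noiseless input
  the remaining error is almost purely along the viewing ray at distal
  joints (wrists/ankles), because a 5-component Gaussian mixture is a
  piecewise-linear-Gaussian approximation of the curved pose manifold.
  Median per-joint error is ~0.3 mm over the benchmark scenes but single
  joints in unlucky stride phases can be off by several mm — consistent
  with this method family's real-data behaviour.
* The energy is non-convex; the optimizer is local. Deterministic
  initialization plus the priors make the benchmark basin-reliable, but
  pathological 2D input can converge to mirror solutions (a limb flipped
  through its viewing-ray plane) that reproject almost identically.
* Bone lengths are re-fit per frame (warm-started in sequences). Per-animal
  length estimation by aggregating over frames would be more faithful to
  anatomy but is out of scope here.
* The 2.3 σ outlier rule is a single pass by design; it reproduces a
  screening convention, not a robust estimator.
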