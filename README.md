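# mouselift

Monocular 3D pose reconstruction for laboratory mice, with the supporting
machinery to validate it: multiview triangulation for ground truth, OKS
keypoint evaluation, and treadmill gait analysis.

## The problem

Continuous home-cage monitoring rigs film each cage with a single fixed,
calibrated camera. A 2D keypoint detector yields 20 named keypoints per
frame with confidences, but many downstream measurements (gait, posture,
reach) need 3D joint positions. A single view cannot observe depth
directly, and the animal's size and its distance to the camera are
confounded. This package recovers 3D pose anyway, by fitting an explicit
kinematic model of the mouse to the 2D observations under learned
anatomical priors.

## The model

The mouse is an 18-joint kinematic tree (spine and tail chain plus four
three-segment limbs; the two ears are derived head markers, completing the
20-keypoint set). Every joint is spherical — an axis-angle rotation vector,
54 angles **a** in total — and the 17 bones have lengths **l** in mm.
Forward kinematics T(**a**, **l**) gives all joint positions; a calibrated
pinhole camera projects them. Lifting one frame minimizes

    E(a, l) = Σᵢ ‖ proj(T(a, l))ᵢ − kᵢ ‖² + λₚ pₚ(a) + λₛ pₛ(l)

over the angles, log bone lengths and the root's viewing ray, where kᵢ are
the observed pixels (keypoints under a confidence floor are dropped), and

* pₚ is the **pose prior**: the negative log-likelihood of a 5-component
  Gaussian mixture over canonically aligned poses (upper spine at the
  origin, spine direction as unit +x), fit to multiview reconstructions;
* pₛ is the **shape prior**: a 7-component Gaussian mixture over the 17
  bone lengths, fit to a per-specimen CT bone-length table;
* the root joint is constrained to a **fixed, known distance** from the
  camera centre, which resolves the monocular size/depth ambiguity.

Supporting components: DLT-initialized Gauss–Newton triangulation from ≥2
calibrated views; Object Keypoint Similarity scoring
(exp(−d²/2k²s²), k = 0.08, s = √bbox area) with the threshold ↔ pixel
radius equivalence R = k·s·√(−2 ln T); and stride extraction from foot
trajectories — aggregate stride length as belt speed over the Fourier
spectrum peak frequency, individual strides as peak-to-peak times, with
2.3 σ outlier screening.

A synthetic-data module generates everything with known ground truth:
cohort bone-length tables (4 size groups, 3% within-group CV), gait and
random poses, a three-camera rig (top-down + two side views), noisy and
occluded 2D observations, and periodic foot traces.

## Worked example

```python
import numpy as np
import mouselift as ml
from mouselift.evaluation import build_default_priors
from mouselift.synthetic import default_rig, render_scene, sample_pose

skeleton = ml.build_default_mouse_skeleton()
pose_prior, shape_prior, _ = build_default_priors(skeleton, seed=0)
camera = default_rig()[0]                      # top-down home-cage view

true_pose = sample_pose(skeleton, mode="gait", seed=11)
true_pose.root_translation = np.array([8.0, -6.0, 30.0])
scene = render_scene(skeleton, true_pose, [camera],
                     noise_sigma_px=1.0, occlusion_fraction=0.1, seed=4)
distance = float(np.linalg.norm(true_pose.root_translation - camera.center))

fit = ml.optimize_pose(scene.observations[0], camera, skeleton,
                       pose_prior, shape_prior,
                       ml.EnergyConfig(fixed_distance=distance))
kp = ml.forward_kinematics(skeleton, fit.pose)
err = np.linalg.norm(kp.positions[:18]
                     - scene.true_keypoints.positions[:18], axis=1)
print(fit.converged, round(fit.final_reprojection_rmse, 2),
      round(float(np.median(err)), 2))
```

prints

```
True 0.59 0.51
```

— the fit converged, the optimized pose reprojects to within 0.59 px of
the (noisy, partly occluded) observations, and the recovered 3D joints sit
a median of 0.51 mm from the generating ground truth. `examples/` holds
one narrative script per capability (forward kinematics, triangulation,
monocular lifting, OKS evaluation, gait strides); each prints the numbers
it computes and what they mean. A thin CLI mirrors the pipeline stages:

```bash
mouselift simulate --frames 10 --out-dir sim
mouselift lift --keypoints sim/keypoints_cam0.json \
               --calib sim/calibration_cam0.yaml --distance-mm 400 \
               --out poses.jsonl
mouselift gait --poses poses.jsonl --belt-speed-mm-s 240 --fps 30 \
               --out gait.csv
```

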