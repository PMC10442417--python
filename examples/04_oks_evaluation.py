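"""Score 2D keypoint predictions with Object Keypoint Similarity (OKS).

Each keypoint scores exp(-d^2 / (2 k^2 s^2)) with falloff k = 0.08 and
object scale s = sqrt(bounding-box area); an OKS threshold T is the same
test as requiring the prediction within R = k*s*sqrt(-2 ln T) pixels of
the truth.  The script scores noisy synthetic predictions and then shows
the threshold/radius equivalence at two object scales.
"""

import numpy as np

import mouselift as ml

rng = np.random.default_rng(0)
names = ml.build_default_mouse_skeleton().keypoint_names
truth = ml.ObservedKeypoints2D(names, rng.uniform(100, 400, (20, 2)))

results = []
for _ in range(200):
    pred = ml.ObservedKeypoints2D(names, truth.uv + rng.normal(0, 6, (20, 2)))
    results.append(ml.oks(pred, truth))

print("per-keypoint accuracy (fraction of frames above threshold):")
for t in (0.5, 0.7, 0.9):
    acc = ml.accuracy_at_threshold(results, t)
    mean_acc = np.mean(list(acc.values()))
    radius = ml.radius_for_threshold(t, scale_s=results[0].scale)
    print(f"  T={t}: mean accuracy {mean_acc:.2f} "
          f"(equivalent pixel radius {radius:.1f} px at this scale)")

print("\nthreshold <-> radius equivalence at two object scales:")
for label, r50 in (("home-cage", 11.4), ("treadmill", 25.6)):
    s = ml.scale_from_radius(0.5, 0.08, r50)
    r = {t: ml.radius_for_threshold(t, 0.08, s) for t in (0.5, 0.7, 0.9)}
    print(f"  {label:9s} scale s={s:6.1f}: "
          + "  ".join(f"T={t} -> {v:.1f} px" for t, v in r.items()))
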