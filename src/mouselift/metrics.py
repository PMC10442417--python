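"""Object Keypoint Similarity (OKS) scoring for 2D pose predictions.

Each predicted keypoint scores ``exp(-d^2 / (2 k^2 s^2))`` where ``d`` is
its pixel distance to ground truth, ``k`` the per-keypoint falloff
constant, and ``s`` the object scale — the square root of the bounding-box
area (the minimal box over the ground-truth keypoints).  The aggregate
score divides by the full keypoint count regardless of visibility, since
annotators mark a best guess for occluded points.  A threshold ``T`` on the
per-keypoint score is equivalent to requiring the prediction within a pixel
radius ``R = k * s * sqrt(-2 ln T)`` of the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import ObservedKeypoints2D

__all__ = [
    "OksConfig",
    "OksResult",
    "oks",
    "accuracy_at_threshold",
    "radius_for_threshold",
    "scale_from_radius",
]

DEFAULT_FALLOFF = 0.08  # human-keypoint median, applied to all mouse points


@dataclass
class OksConfig:
    falloff: float | np.ndarray = DEFAULT_FALLOFF
    n_keypoints: int = 20
    visible_only: bool = False

    def falloff_vector(self) -> np.ndarray:
        k = np.broadcast_to(np.asarray(self.falloff, dtype=float),
                            (self.n_keypoints,)).copy()
        if np.any(k <= 0):
            raise ValueError("falloff must be positive")
        return k


@dataclass
class OksResult:
    names: tuple[str, ...]
    per_keypoint: np.ndarray
    aggregate: float
    scale: float


def oks(pred: ObservedKeypoints2D, truth: ObservedKeypoints2D,
        bbox_area: float | None = None,
        config: OksConfig | None = None) -> OksResult:
    """Score a predicted keypoint set against ground truth.

    ``bbox_area`` defaults to the minimal box over the ground-truth points.
    With ``config.visible_only`` the aggregate averages only over keypoints
    the ground truth marks visible; by default all keypoints count.
    """
    config = config or OksConfig(n_keypoints=len(truth.names))
    if pred.names != truth.names:
        missing = set(truth.names) ^ set(pred.names)
        raise ValueError(f"keypoint name mismatch: {sorted(missing)}")
    if bbox_area is None:
        bbox_area = truth.bbox_area()
    if bbox_area <= 0:
        raise ValueError("bounding-box area must be positive")
    s = float(np.sqrt(bbox_area))
    k = config.falloff_vector()
    if k.size != len(truth.names):
        raise ValueError("falloff vector length must match keypoint count")
    d2 = np.sum((pred.uv - truth.uv) ** 2, axis=1)
    scores = np.exp(-d2 / (2.0 * k ** 2 * s ** 2))
    if config.visible_only:
        mask = truth.visible
        aggregate = float(scores[mask].mean()) if mask.any() else 0.0
    else:
        aggregate = float(scores.mean())
    return OksResult(names=truth.names, per_keypoint=scores,
                     aggregate=aggregate, scale=s)


def accuracy_at_threshold(results: Sequence[OksResult],
                          threshold: float) -> dict[str, float]:
    """Per-keypoint-name fraction of scores above an OKS threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(results) == 0:
        raise ValueError("no results to aggregate")
    names = results[0].names
    scores = np.stack([r.per_keypoint for r in results])
    frac = (scores > threshold).mean(axis=0)
    return {name: float(frac[i]) for i, name in enumerate(names)}


def radius_for_threshold(threshold: float, falloff: float = DEFAULT_FALLOFF,
                         scale_s: float = 1.0) -> float:
    """Pixel radius at which the per-keypoint OKS term equals ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return float(falloff * scale_s * np.sqrt(-2.0 * np.log(threshold)))


def scale_from_radius(threshold: float, falloff: float,
                      radius: float) -> float:
    """Object scale implied by a printed (threshold, radius) pair."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(radius / (falloff * np.sqrt(-2.0 * np.log(threshold))))
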