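"""File interchange: COCO-style keypoint annotations and pose records.

2D keypoints travel in a COCO-keypoint-style JSON file: a single ``mouse``
category listing the 20 keypoint names, one image record per frame, and one
annotation per frame with the ``keypoints`` triple list ``(x, y, c)``
flattened.  The third slot holds the detector confidence in [0, 1] (the
COCO visibility slot reinterpreted; 0 still means unusable).  Fitted poses
are written as JSON lines, one self-contained record per frame, so runs
diff cleanly.
"""

from __future__ import annotations

import json
import warnings
from typing import Sequence

import numpy as np

from .geometry import ObservedKeypoints2D
from .optimize import PoseFit
from .skeleton import (SkeletonDefinition, build_default_mouse_skeleton,
                       forward_kinematics)

__all__ = [
    "read_keypoints",
    "write_keypoints",
    "write_poses",
    "read_poses",
]

CATEGORY_NAME = "mouse"


class KeypointSchemaError(ValueError):
    """Annotation file does not match the expected keypoint schema."""


def write_keypoints(path, frames: Sequence[ObservedKeypoints2D],
                    image_size=(640, 480)) -> None:
    """Write per-frame 2D keypoints as a COCO-style annotation file."""
    if not frames:
        names: tuple[str, ...] = build_default_mouse_skeleton().keypoint_names
    else:
        names = frames[0].names
    images, annotations = [], []
    for i, frame in enumerate(frames):
        if frame.names != names:
            raise KeypointSchemaError("all frames must share keypoint names")
        images.append({"id": i, "width": int(image_size[0]),
                       "height": int(image_size[1]),
                       "file_name": f"frame_{i:06d}.png"})
        flat = []
        for (u, v), c in zip(frame.uv, frame.confidence):
            flat.extend([float(u) if np.isfinite(u) else 0.0,
                         float(v) if np.isfinite(v) else 0.0, float(c)])
        annotations.append({"id": i, "image_id": i, "category_id": 1,
                            "keypoints": flat,
                            "num_keypoints": int(frame.visible.sum())})
    doc = {
        "categories": [{"id": 1, "name": CATEGORY_NAME,
                        "keypoints": list(names), "skeleton": []}],
        "images": images,
        "annotations": annotations,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_keypoints(path, expected_names: Sequence[str] | None = None
                   ) -> list[ObservedKeypoints2D]:
    """Read a COCO-style annotation file into per-frame keypoint sets.

    Frames are ordered by image id.  The category must carry exactly the
    expected keypoint names (default: the canonical 20-point mouse set);
    a mismatch reports the missing/unexpected names.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if expected_names is None:
        expected_names = build_default_mouse_skeleton().keypoint_names
    expected = tuple(expected_names)
    cats = doc.get("categories", [])
    if len(cats) != 1:
        raise KeypointSchemaError("expected exactly one keypoint category")
    names = tuple(cats[0].get("keypoints", []))
    if names != expected:
        missing = sorted(set(expected) - set(names))
        extra = sorted(set(names) - set(expected))
        raise KeypointSchemaError(
            f"keypoint schema mismatch: missing {missing}, unexpected {extra}")
    annotations = sorted(doc.get("annotations", []),
                         key=lambda a: a["image_id"])
    if not annotations:
        warnings.warn("annotation file contains no frames", stacklevel=2)
    frames = []
    for ann in annotations:
        flat = np.asarray(ann["keypoints"], dtype=float)
        if flat.size != 3 * len(expected):
            raise KeypointSchemaError(
                f"annotation {ann.get('id')} has {flat.size // 3} keypoints, "
                f"expected {len(expected)}")
        triples = flat.reshape(-1, 3)
        conf = np.clip(triples[:, 2], 0.0, 1.0)
        frames.append(ObservedKeypoints2D(names=expected, uv=triples[:, :2],
                                          confidence=conf))
    return frames


def write_poses(path, fits: Sequence[PoseFit],
                skeleton: SkeletonDefinition) -> None:
    """Write fitted poses as JSON lines, one record per frame."""
    with open(path, "w") as fh:
        for i, fit in enumerate(fits):
            rec: dict = {"frame": i, "converged": bool(fit.converged),
                         "error": fit.error}
            if fit.pose is not None:
                kp3d = forward_kinematics(skeleton, fit.pose)
                rec.update({
                    "angles_rad": fit.pose.angles.tolist(),
                    "bone_lengths_mm": fit.pose.bone_lengths.tolist(),
                    "root_translation_mm": fit.pose.root_translation.tolist(),
                    "joints_mm": {n: kp3d.get(n).tolist()
                                  for n in kp3d.names},
                    "energy": fit.final_energy,
                    "reprojection_rmse_px": fit.final_reprojection_rmse,
                    "excluded_keypoints": list(fit.excluded_keypoints),
                })
            fh.write(json.dumps(rec) + "\n")


def read_poses(path) -> list[dict]:
    """Read a JSON-lines pose file back into per-frame dicts."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records
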