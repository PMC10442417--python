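"""Pinhole cameras, calibration files, and multiview triangulation.

World frame convention: cage floor plane with z up, millimetres.  A
camera's extrinsics map world to camera coordinates, ``x_cam = R x + t``.
Pixel coordinates have their origin at the top-left pixel centre, x right,
y down.  Lens distortion follows the Brown-Conrady model with three radial
and two tangential coefficients ``(k1, k2, p1, p2, k3)``, all zero by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .skeleton import Keypoints3D

__all__ = [
    "CameraModel",
    "ObservedKeypoints2D",
    "TriangulationResult",
    "project",
    "triangulate",
    "reconstruct_pose_multiview",
    "load_calibration",
    "save_calibration",
    "look_at",
]


class BehindCameraError(ValueError):
    """A point to be projected lies on or behind the image plane."""


class CalibrationError(ValueError):
    """Malformed or inconsistent calibration data."""


@dataclass
class CameraModel:
    """Calibrated pinhole camera with optional Brown-Conrady distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))
    image_size: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise CalibrationError("focal lengths must be positive")
        R = np.asarray(self.rotation, dtype=float)
        if R.shape == (3,):  # rotation vector
            from scipy.spatial.transform import Rotation
            R = Rotation.from_rotvec(R).as_matrix()
        if R.shape != (3, 3):
            raise CalibrationError("rotation must be 3x3 or a rotation vector")
        if (np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9
                or np.linalg.det(R) < 0):
            raise CalibrationError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        d = np.zeros(5)
        dist = np.asarray(self.distortion, dtype=float).ravel()
        d[:dist.size] = dist
        self.distortion = d

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix K [R | t] (valid for zero distortion)."""
        return self.intrinsic_matrix @ np.hstack(
            [self.rotation, self.translation[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates, -R^T t."""
        return -self.rotation.T @ self.translation

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class ObservedKeypoints2D:
    """Named 2D keypoints with confidences in [0, 1].

    A confidence of zero marks an unusable (occluded/undetected) point;
    such points may carry non-finite coordinates.
    """

    names: tuple[str, ...]
    uv: np.ndarray
    confidence: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        if self.uv.shape != (len(self.names), 2):
            raise ValueError("uv must be (n_names, 2)")
        if self.confidence is None:
            self.confidence = np.ones(len(self.names))
        else:
            self.confidence = np.asarray(self.confidence, dtype=float).ravel()
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        visible = self.confidence > 0
        if not np.all(np.isfinite(self.uv[visible])):
            raise ValueError("visible keypoints must have finite coordinates")

    @property
    def visible(self) -> np.ndarray:
        return self.confidence > 0

    def get(self, name: str) -> np.ndarray:
        return self.uv[self.names.index(name)]

    def bbox_area(self) -> float:
        """Area of the minimal axis-aligned box over visible points."""
        pts = self.uv[self.visible]
        if len(pts) == 0:
            return 0.0
        span = pts.max(axis=0) - pts.min(axis=0)
        return float(span[0] * span[1])


def _distort(xn: np.ndarray, dist: np.ndarray) -> np.ndarray:
    k1, k2, p1, p2, k3 = dist
    x, y = xn[..., 0], xn[..., 1]
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _undistort(xd: np.ndarray, dist: np.ndarray,
               iterations: int = 20) -> np.ndarray:
    """Invert Brown-Conrady distortion by fixed-point iteration."""
    if not np.any(dist):
        return xd
    xn = xd.copy()
    for _ in range(iterations):
        delta = _distort(xn, dist) - xn
        xn = xd - delta
    return xn


def project(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project world point(s) (mm) to pixel coordinates.

    Raises :class:`BehindCameraError` if any point has non-positive depth
    after the extrinsic transform.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    cam = camera.world_to_camera(pts)
    z = cam[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("point(s) at or behind the camera plane")
    xn = cam[:, :2] / z[:, None]
    xn = _distort(xn, camera.distortion)
    uv = np.empty_like(xn)
    uv[:, 0] = camera.fx * xn[:, 0] + camera.cx
    uv[:, 1] = camera.fy * xn[:, 1] + camera.cy
    return uv[0] if np.asarray(point).ndim == 1 else uv


def back_project_ray(camera: CameraModel, uv: np.ndarray) -> np.ndarray:
    """Unit world-frame direction of the viewing ray through pixel uv."""
    xn = np.array([(uv[0] - camera.cx) / camera.fx,
                   (uv[1] - camera.cy) / camera.fy])
    xn = _undistort(xn[None], camera.distortion)[0]
    d_cam = np.array([xn[0], xn[1], 1.0])
    d_world = camera.rotation.T @ d_cam
    return d_world / np.linalg.norm(d_world)


@dataclass
class TriangulationResult:
    point: np.ndarray
    rmse_px: float
    dlt_rmse_px: float
    per_view_residuals_px: np.ndarray
    ill_conditioned: bool = False


def _reprojection_residuals(point: np.ndarray,
                            observations: Sequence[np.ndarray],
                            cameras: Sequence[CameraModel]) -> np.ndarray:
    res = np.empty(2 * len(cameras))
    for i, (uv, cam) in enumerate(zip(observations, cameras)):
        res[2 * i:2 * i + 2] = project(cam, point) - uv
    return res


def triangulate(observations: Sequence[np.ndarray],
                cameras: Sequence[CameraModel],
                max_iterations: int = 50,
                step_tol_mm: float = 1e-10) -> TriangulationResult:
    """Recover a 3D point from >= 2 calibrated views.

    Direct linear transform (homogeneous least squares on undistorted
    normalized observations) initializes a Gauss-Newton refinement of the
    squared pixel reprojection error; the refinement never accepts a step
    that increases the objective, so the returned RMSE is at most the DLT
    RMSE.
    """
    if len(observations) != len(cameras):
        raise ValueError("one observation per camera required")
    if len(cameras) < 2:
        raise ValueError("triangulation needs at least 2 views")
    rows = []
    rays = []
    for uv, cam in zip(observations, cameras):
        xn = np.array([(uv[0] - cam.cx) / cam.fx,
                       (uv[1] - cam.cy) / cam.fy])
        xn = _undistort(xn[None], cam.distortion)[0]
        P = np.hstack([cam.rotation, cam.translation[:, None]])
        rows.append(xn[0] * P[2] - P[0])
        rows.append(xn[1] * P[2] - P[1])
        rays.append(cam.rotation.T @ np.array([xn[0], xn[1], 1.0]))
    A = np.stack(rows)
    _, _, vt = np.linalg.svd(A)
    hom = vt[-1]
    if abs(hom[3]) < 1e-12:
        hom = hom + 1e-12
    x = hom[:3] / hom[3]

    rays = np.stack([r / np.linalg.norm(r) for r in rays])
    max_angle = 0.0
    for i in range(len(rays)):
        for j in range(i + 1, len(rays)):
            c = np.clip(abs(rays[i] @ rays[j]), 0.0, 1.0)
            max_angle = max(max_angle, np.arccos(c))
    ill = max_angle < np.deg2rad(1.0)

    def cost(p):
        try:
            r = _reprojection_residuals(p, observations, cameras)
        except BehindCameraError:
            return None, np.inf
        return r, float(r @ r)

    res, f = cost(x)
    dlt_rmse = np.sqrt(f / len(res)) if np.isfinite(f) else np.inf
    lam = 0.0
    for _ in range(max_iterations):
        if res is None:
            break
        J = np.empty((res.size, 3))
        eps = 1e-6 * max(1.0, np.linalg.norm(x))
        for k in range(3):
            dx = np.zeros(3)
            dx[k] = eps
            rp, _ = cost(x + dx)
            if rp is None:
                rp = res
            J[:, k] = (rp - res) / eps
        H = J.T @ J
        g = J.T @ res
        step = np.linalg.solve(H + lam * np.eye(3), -g)
        if np.linalg.norm(step) < step_tol_mm:
            break
        res_new, f_new = cost(x + step)
        if f_new <= f:
            x, res, f = x + step, res_new, f_new
            lam = max(lam / 10.0, 0.0)
        else:
            lam = max(lam * 10.0, 1e-4)  # damp and retry
            continue
    per_view = np.sqrt(np.sum(
        _reprojection_residuals(x, observations, cameras).reshape(-1, 2) ** 2,
        axis=1))
    rmse = float(np.sqrt(f / (2 * len(cameras))))
    return TriangulationResult(point=x, rmse_px=rmse,
                               dlt_rmse_px=float(dlt_rmse),
                               per_view_residuals_px=per_view,
                               ill_conditioned=bool(ill))


def reconstruct_pose_multiview(
        observations: Sequence[ObservedKeypoints2D],
        cameras: Sequence[CameraModel]) -> Keypoints3D:
    """Triangulate every keypoint visible in at least two views.

    Keypoints seen in fewer than two views are returned with
    ``valid=False``; the rest are triangulated independently by name.
    """
    if len(observations) != len(cameras):
        raise ValueError("one observation set per camera required")
    names = observations[0].names
    for obs in observations[1:]:
        if obs.names != names:
            raise ValueError("all views must share the keypoint name list")
    positions = np.full((len(names), 3), np.nan)
    valid = np.zeros(len(names), dtype=bool)
    for i, name in enumerate(names):
        uvs, cams = [], []
        for obs, cam in zip(observations, cameras):
            if obs.visible[i]:
                uvs.append(obs.uv[i])
                cams.append(cam)
        if len(cams) >= 2:
            positions[i] = triangulate(uvs, cams).point
            valid[i] = True
    return Keypoints3D(names, np.nan_to_num(positions), valid)


def save_calibration(camera: CameraModel, path) -> None:
    doc = {
        "camera_matrix": [[float(v) for v in row]
                          for row in camera.intrinsic_matrix],
        "distortion": [float(v) for v in camera.distortion],
        "rotation": [[float(v) for v in row] for row in camera.rotation],
        "translation": [float(v) for v in camera.translation],
        "image_size": [int(camera.image_size[0]), int(camera.image_size[1])],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_calibration(path) -> CameraModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        K = np.asarray(doc["camera_matrix"], dtype=float)
        rotation = np.asarray(doc["rotation"], dtype=float)
        translation = np.asarray(doc["translation"], dtype=float)
    except KeyError as exc:
        raise CalibrationError(f"missing calibration field: {exc}") from exc
    if K.shape != (3, 3):
        raise CalibrationError("camera_matrix must be 3x3")
    distortion = np.asarray(doc.get("distortion", np.zeros(5)), dtype=float)
    size = tuple(doc.get("image_size", (640, 480)))
    return CameraModel(fx=float(K[0, 0]), fy=float(K[1, 1]),
                       cx=float(K[0, 2]), cy=float(K[1, 2]),
                       rotation=rotation, translation=translation,
                       distortion=distortion, image_size=size)


def look_at(center: np.ndarray, target: np.ndarray,
            up: np.ndarray = (0.0, 0.0, 1.0)) -> tuple[np.ndarray, np.ndarray]:
    """Extrinsics (R, t) for a camera at ``center`` looking at ``target``.

    Camera z points from centre to target, x rightward (perpendicular to
    the world ``up`` hint), y downward, matching the pixel convention.
    """
    center = np.asarray(center, dtype=float)
    z = np.asarray(target, dtype=float) - center
    z = z / np.linalg.norm(z)
    up = np.asarray(up, dtype=float)
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-9:  # looking straight along up: pick world x
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    t = -R @ center
    return R, t
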