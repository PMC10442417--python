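"""Gaussian-mixture pose and shape priors.

Monocular lifting is under-constrained: many joint-angle/bone-length
combinations explain the same 2D keypoints.  Two data-driven priors
regularize the fit, both entering the energy as negative log-likelihood
penalties of Gaussian mixture models:

* the *pose prior* ``p_p`` — a 5-component GMM over canonically aligned,
  unit-spine-scaled 3D poses, fit to multiview reconstructions;
* the *shape prior* ``p_s`` — a 7-component GMM over the 17 bone lengths,
  fit to a per-specimen bone-length table measured from CT scans.

Canonical pose alignment: translate the base of the neck (upper spine) to
the origin, rotate the upper-spine-to-middle-spine vector onto +x and scale
it to unit length, then fix the residual roll so the hip midpoint lies in
the xz-plane below the spine (dorsal +z).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .skeleton import Keypoints3D, build_default_mouse_skeleton

__all__ = [
    "GmmPrior",
    "NormalizedPose",
    "normalize_pose",
    "normalize_points",
    "fit_gmm",
    "neg_log_likelihood",
    "fit_pose_prior",
    "fit_shape_prior",
    "save_prior",
    "load_prior",
]

POSE_ORIGIN = "upper_spine"
POSE_AXIS = "middle_spine"
_HIPS = ("left_hip", "right_hip")


class DegeneratePoseError(ValueError):
    """Spine reference points coincide; the pose cannot be normalized."""


@dataclass
class GmmPrior:
    """A fitted Gaussian mixture used as a negative-log-likelihood penalty."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    fit_seed: int = 0
    kind: str = ""
    feature_names: tuple[str, ...] | None = None
    _chol: np.ndarray = field(default=None, repr=False)  # type: ignore
    _log_norm: np.ndarray = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        k, d = self.means.shape
        if self.weights.shape != (k,) or self.covariances.shape != (k, d, d):
            raise ValueError("inconsistent mixture shapes")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1) > 1e-9:
            raise ValueError("weights must be a probability simplex")
        # SPD check via Cholesky; precompute factors for likelihood evals
        try:
            self._chol = np.linalg.cholesky(self.covariances)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariances must be positive definite") from exc
        logdet = 2 * np.sum(
            np.log(np.diagonal(self._chol, axis1=1, axis2=2)), axis=1)
        self._log_norm = -0.5 * (d * np.log(2 * np.pi) + logdet)
        # precomputed inverse Cholesky factors: likelihood evaluations sit
        # inside the optimizer's inner loop and must stay cheap
        eye = np.eye(d)
        linv = np.stack([solve_triangular(self._chol[j], eye, lower=True)
                         for j in range(k)])
        object.__setattr__(self, "_chol_inv", linv)
        object.__setattr__(self, "_log_w", np.log(self.weights + 1e-300))

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dimension(self) -> int:
        return self.means.shape[1]

    def _component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """(n, k) per-component log densities including mixture weights."""
        diffs = x[:, None, :] - self.means[None, :, :]
        z = np.einsum("kij,nkj->nki", self._chol_inv, diffs)
        return (self._log_norm + self._log_w
                - 0.5 * np.einsum("nki,nki->nk", z, z))

    def log_density(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dimension:
            raise ValueError(
                f"expected dimension {self.dimension}, got {x.shape[1]}")
        return logsumexp(self._component_logpdf(x), axis=1)

    def nll_lower_bound(self) -> float:
        """-log of the sum of component peak densities (a valid NLL floor)."""
        return float(-logsumexp(np.log(self.weights + 1e-300)
                                + self._log_norm))

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        comp = self._component_logpdf(x)
        comp -= logsumexp(comp, axis=1, keepdims=True)
        return np.exp(comp)

    def mean(self) -> np.ndarray:
        """Mixture mean (component means weighted by mixture weights)."""
        return self.weights @ self.means


def neg_log_likelihood(prior: GmmPrior, x: np.ndarray) -> float | np.ndarray:
    """Negative log density of the mixture at ``x`` (vector or batch)."""
    x = np.asarray(x, dtype=float)
    out = -prior.log_density(x)
    return float(out[0]) if x.ndim == 1 else out


@dataclass
class NormalizedPose:
    """Joint coordinates after canonical alignment (dimensionless)."""

    names: tuple[str, ...]
    coordinates: np.ndarray

    def flatten(self) -> np.ndarray:
        return self.coordinates.ravel()


def normalize_points(points: np.ndarray, idx_origin: int, idx_axis: int,
                     idx_hips: tuple[int, int]) -> np.ndarray:
    """Array core of :func:`normalize_pose` (see module docstring)."""
    p = np.asarray(points, dtype=float)
    v = p[idx_axis] - p[idx_origin]
    scale = np.linalg.norm(v)
    if scale < 1e-9:
        raise DegeneratePoseError("spine reference points coincide")
    x_axis = v / scale
    # rotate x_axis onto (1,0,0) about their mutual perpendicular
    c = x_axis[0]
    axis = np.cross(x_axis, [1.0, 0.0, 0.0])
    s = np.linalg.norm(axis)
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else Rotation.from_rotvec(
            [0.0, np.pi, 0.0]).as_matrix()
    else:
        R1 = Rotation.from_rotvec(
            axis / s * np.arctan2(s, c)).as_matrix()
    q = (p - p[idx_origin]) @ R1.T / scale
    # resolve roll about x: hip midpoint into the xz-plane, ventral side -z
    hm = 0.5 * (q[idx_hips[0]] + q[idx_hips[1]])
    r_perp = np.hypot(hm[1], hm[2])
    if r_perp > 1e-9:
        alpha = -np.pi / 2 - np.arctan2(hm[2], hm[1])
        R2 = Rotation.from_rotvec([alpha, 0.0, 0.0]).as_matrix()
        q = q @ R2.T
    return q


def normalize_pose(points: Keypoints3D,
                   joint_names: Sequence[str] | None = None) -> NormalizedPose:
    """Canonically align and scale a 3D pose for the pose prior.

    The pose is translated so the base of the neck (``upper_spine``) sits at
    the origin, rotated so the vector to ``middle_spine`` lies along +x with
    unit length, and rolled about x so the hip midpoint lies in the xz-plane
    on the ventral (-z) side.  The result is invariant to rigid motion and
    uniform scaling of the input.
    """
    if joint_names is None:
        joint_names = build_default_mouse_skeleton().joint_names
    sub = points.subset(joint_names)
    if not np.all(sub.valid):
        raise ValueError("all chain joints must be valid for normalization")
    names = tuple(joint_names)
    coords = normalize_points(
        sub.positions,
        names.index(POSE_ORIGIN), names.index(POSE_AXIS),
        (names.index(_HIPS[0]), names.index(_HIPS[1])))
    return NormalizedPose(names, coords)


def fit_gmm(samples: np.ndarray, n_components: int, seed: int,
            n_init: int = 5, reg_covar: float = 1e-6) -> GmmPrior:
    """Fit a full-covariance GMM by EM (k-means++ init, best of ``n_init``).

    Covariance eigenvalues are floored at ``reg_covar`` so constant or
    near-constant dimensions (e.g. the pinned spine coordinates of
    normalized poses) stay well-conditioned.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} samples, got {X.shape[0]}")
    if np.any(X.var(axis=0) < reg_covar):
        warnings.warn("near-zero-variance dimensions floored at reg_covar",
                      stacklevel=2)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         reg_covar=reg_covar, n_init=n_init,
                         init_params="k-means++", max_iter=200,
                         random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    return GmmPrior(weights=gm.weights_, means=gm.means_,
                    covariances=gm.covariances_, fit_seed=int(seed))


def fit_pose_prior(poses: Sequence[Keypoints3D], seed: int,
                   n_components: int = 5,
                   joint_names: Sequence[str] | None = None) -> GmmPrior:
    """Fit the pose prior ``p_p`` on canonically normalized 3D poses.

    Each pose is aligned and scaled (see :func:`normalize_pose`) and the 18
    joint coordinates flattened into a 54-vector before the mixture fit.
    """
    if len(poses) < n_components:
        raise ValueError(f"need at least {n_components} poses")
    if joint_names is None:
        joint_names = build_default_mouse_skeleton().joint_names
    X = np.stack([normalize_pose(p, joint_names).flatten() for p in poses])
    prior = fit_gmm(X, n_components, seed)
    prior.kind = "pose"
    prior.feature_names = tuple(
        f"{n}_{ax}" for n in joint_names for ax in "xyz")
    return prior


def fit_shape_prior(length_table, seed: int,
                    n_components: int = 7,
                    bone_names: Sequence[str] | None = None,
                    reg_covar: float = 0.04) -> GmmPrior:
    """Fit the shape prior ``p_s`` on a per-specimen bone-length table (mm).

    Accepts an ``(n_specimens, n_bones)`` array or a DataFrame whose bone
    columns are selected by ``bone_names`` (default: the canonical
    skeleton's bone names, if present).

    ``reg_covar`` floors each component's covariance eigenvalues at the
    square of the bone-length measurement precision (default 0.04 mm^2,
    i.e. 0.2 mm).  With tens of specimens split over 7 full-covariance
    components in 17 dimensions, EM would otherwise collapse components
    onto near-singular covariances and the prior would assign absurd
    penalties to new animals.
    """
    if hasattr(length_table, "columns"):  # DataFrame
        if bone_names is None:
            default = build_default_mouse_skeleton().bone_names
            bone_names = [c for c in default if c in length_table.columns]
            if not bone_names:
                bone_names = [c for c in length_table.columns
                              if c != "group"]
        X = length_table.loc[:, list(bone_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(length_table, dtype=float))
    if np.any(X <= 0):
        raise ValueError("bone lengths must be strictly positive")
    # specimens are exchangeable: canonicalize row order so the fitted
    # prior does not depend on how the table happened to be sorted
    X = X[np.lexsort(X.T[::-1])]
    prior = fit_gmm(X, n_components, seed, reg_covar=reg_covar)
    prior.kind = "shape"
    if bone_names is not None:
        prior.feature_names = tuple(bone_names)
    return prior


def save_prior(prior: GmmPrior, path) -> None:
    doc = {
        "kind": prior.kind,
        "fit_seed": prior.fit_seed,
        "weights": prior.weights.tolist(),
        "means": prior.means.tolist(),
        "covariances": prior.covariances.tolist(),
        "feature_names": (list(prior.feature_names)
                          if prior.feature_names else None),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_prior(path) -> GmmPrior:
    with open(path) as fh:
        doc = json.load(fh)
    return GmmPrior(
        weights=np.array(doc["weights"]),
        means=np.array(doc["means"]),
        covariances=np.array(doc["covariances"]),
        fit_seed=int(doc.get("fit_seed", 0)),
        kind=doc.get("kind", ""),
        feature_names=(tuple(doc["feature_names"])
                       if doc.get("feature_names") else None),
    )
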