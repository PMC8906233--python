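"""Point-to-point iterative closest point (ICP) registration.

The reference algorithm: alternate k-d-tree nearest-neighbour
correspondence, least-squares rigid estimation (Kabsch / SVD), and
application of the increment, from a zero initial transform, until the
incremental update drops below 0.1 mm and 0.1 deg or 100 iterations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .base import (MAX_ITERATIONS, MIN_ROTATION_STEP, MIN_TRANSLATION_STEP,
                   BaseSurfaceRegistration, RegistrationResult)
from .geometry import RigidTransform, as_cloud

__all__ = ["ICPRegistration", "icp_register", "find_correspondences",
           "estimate_rigid"]


def find_correspondences(reference, current, *, tree: cKDTree | None = None,
                         max_distance: float | None = None):
    """Nearest reference point for every current point.

    Returns ``(cur_idx, ref_idx, distances)`` — index pairs restricted to
    matches within ``max_distance`` when a gate is set.  Ties are broken by
    the lowest reference index.
    """
    ref = as_cloud(reference, name="reference")
    cur = as_cloud(current, name="current")
    if not len(ref) or not len(cur):
        raise ValueError("both clouds must be non-empty")
    if tree is None:
        tree = cKDTree(ref)
    dists, ref_idx = tree.query(cur)
    cur_idx = np.arange(len(cur))
    if max_distance is not None:
        keep = dists <= max_distance
        cur_idx, ref_idx, dists = cur_idx[keep], ref_idx[keep], dists[keep]
    return cur_idx, ref_idx, dists


def estimate_rigid(source, target) -> RigidTransform:
    """Least-squares rigid transform mapping matched source points to targets.

    Centroid alignment plus SVD of the cross-covariance (Kabsch), with the
    reflection case corrected to a proper rotation (det +1).  Requires at
    least three non-collinear pairs.
    """
    src = as_cloud(source, name="source")
    dst = as_cloud(target, name="target")
    if len(src) != len(dst):
        raise ValueError("source and target must pair one-to-one")
    if len(src) < 3:
        raise ValueError(f"need >= 3 point pairs, got {len(src)}")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, s, vt = np.linalg.svd(h)
    # collinear (or coincident) sources leave >= 2 singular values ~ 0
    if s[1] <= max(1e-9 * max(s[0], 1.0), 0.0):
        raise ValueError("degenerate geometry: point pairs are collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    return RigidTransform.from_matrix(r, t)


class ICPRegistration(BaseSurfaceRegistration):
    """Point-to-point ICP with k-d-tree correspondences and SVD estimation.

    Parameters
    ----------
    max_iterations : int, default 100
        Iteration cap.
    min_translation_step, min_rotation_step : float, defaults 0.1 mm / 0.1 deg
        Minimum-error stopping thresholds on the incremental pose update.
    max_correspondence_distance : float or None, default None
        Optional gate (mm) rejecting pairs farther apart; off by default
        because fully overlapping post-ROI surfaces need no rejection.

    Attributes
    ----------
    reference_ : ndarray of shape (n, 3)
        The fitted reference surface.
    tree_ : scipy.spatial.cKDTree
        Nearest-neighbour index over the reference.
    pose_, result_ : set by :meth:`transform`.
    """

    def __init__(self, max_iterations: int = MAX_ITERATIONS,
                 min_translation_step: float = MIN_TRANSLATION_STEP,
                 min_rotation_step: float = MIN_ROTATION_STEP,
                 max_correspondence_distance: float | None = None):
        self.max_iterations = max_iterations
        self.min_translation_step = min_translation_step
        self.min_rotation_step = min_rotation_step
        self.max_correspondence_distance = max_correspondence_distance

    def fit(self, X, y=None):
        """Store the reference surface and build its k-d tree."""
        self.reference_ = self._validate(X, "reference")
        self.tree_ = cKDTree(self.reference_)
        self.n_features_in_ = 3
        return self

    def register(self, X) -> RegistrationResult:
        self._check_fitted_reference()
        if (self.max_iterations < 1 or self.min_translation_step <= 0
                or self.min_rotation_step <= 0):
            raise ValueError("iteration and step parameters must be positive")
        current = self._validate(X, "current")

        pose = RigidTransform.identity()
        moved = current
        trace = []
        converged = False
        residual = np.inf
        iterations = 0
        for iterations in range(1, self.max_iterations + 1):
            ci, ri, dists = find_correspondences(
                self.reference_, moved, tree=self.tree_,
                max_distance=self.max_correspondence_distance)
            if not len(ci):
                raise ValueError("no correspondences within the distance gate")
            residual = float(dists.mean())
            delta = estimate_rigid(moved[ci], self.reference_[ri])
            pose = delta.compose(pose)
            moved = pose.apply(current)
            step = delta.as_vector()
            trace.append((pose.as_vector(), residual))
            if self._step_converged(step, self.min_translation_step,
                                    self.min_rotation_step):
                converged = True
                break
        return RegistrationResult(pose=pose, iterations=iterations,
                                  converged=converged, residual=residual,
                                  trace=trace, transformed_cloud=moved)


def icp_register(reference, current, **params) -> RegistrationResult:
    """Functional one-shot ICP; keyword arguments as in :class:`ICPRegistration`."""
    return ICPRegistration(**params).fit(reference).register(current)
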