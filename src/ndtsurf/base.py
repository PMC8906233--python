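"""Shared registration result container and estimator base class."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import RigidTransform, as_cloud

__all__ = ["RegistrationResult", "BaseSurfaceRegistration"]

#: Stopping thresholds shared by both algorithms: the incremental pose
#: update must fall below 0.1 mm (translation norm) and 0.1 deg (largest
#: angle change) for convergence.
MIN_TRANSLATION_STEP = 0.1
MIN_ROTATION_STEP = 0.1
MAX_ITERATIONS = 100


@dataclass
class RegistrationResult:
    """Outcome of a rigid surface registration.

    Attributes
    ----------
    pose : RigidTransform
        The correction mapping the current surface onto the reference.
    iterations : int
        Iterations actually used.
    converged : bool
        Whether the incremental update fell below the stopping thresholds.
    residual : float
        Final quality measure: mean correspondence distance (mm) for ICP,
        negative match score for NDT.
    trace : list of (numpy.ndarray, float)
        Per-iteration (pose 6-vector after the step, residual).
    transformed_cloud : numpy.ndarray
        The current surface moved by ``pose``.
    """

    pose: RigidTransform
    iterations: int
    converged: bool
    residual: float
    trace: list = field(default_factory=list)
    transformed_cloud: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "pose": {
                "translation_mm": self.pose.translation.tolist(),
                "rotation_deg": self.pose.rotation_deg.tolist(),
            },
            "iterations": self.iterations,
            "converged": self.converged,
            "residual": self.residual,
        }


class BaseSurfaceRegistration(BaseEstimator):
    """Base class for rigid surface-registration estimators.

    The sklearn-style contract: :meth:`fit` ingests the *reference* surface
    and precomputes its search structure; :meth:`register` estimates the
    rigid correction for a *current* surface; :meth:`transform` additionally
    returns the aligned cloud.  Both registrations start from the zero
    (identity) transform.
    """

    def fit(self, X, y=None):
        raise NotImplementedError

    def register(self, X) -> RegistrationResult:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        """Register ``X`` against the fitted reference and return it aligned.

        The full :class:`RegistrationResult` is stored as ``self.result_``
        and the pose as ``self.pose_``.
        """
        result = self.register(X)
        self.result_ = result
        self.pose_ = result.pose
        return result.transformed_cloud

    def _check_fitted_reference(self):
        if not hasattr(self, "reference_"):
            raise AttributeError(
                f"{type(self).__name__} must be fitted on a reference surface "
                "before registering")

    @staticmethod
    def _validate(X, name):
        pts = as_cloud(X, name=name)
        if not len(pts):
            raise ValueError(f"{name} must be non-empty")
        return pts

    @staticmethod
    def _step_converged(delta: np.ndarray, min_t: float, min_r: float) -> bool:
        """True when a pose increment is below both stopping thresholds."""
        return bool(np.linalg.norm(delta[:3]) < min_t
                    and np.abs(delta[3:]).max(initial=0.0) < min_r)
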