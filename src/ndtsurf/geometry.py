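"""Rigid 3D poses and their action on point clouds.

Conventions used throughout the package
---------------------------------------
* Point clouds are ``(n, 3)`` float64 arrays in millimetres, room/patient
  coordinates: x = lateral (Lat.), y = longitudinal (Long.), z = vertical
  (Vert.).
* A rigid pose is a translation vector ``t`` in mm plus three Euler angles
  in degrees.  Angles are intrinsic Z-Y-X (yaw-pitch-roll): the rotation
  matrix is ``Rz(rz) @ Ry(ry) @ Rx(rx)`` and rotates about the coordinate
  origin, not the cloud centroid.
* A registration result maps the *current* surface onto the *reference*
  surface — the couch-correction sense.  A phantom physically shifted by
  ``+s`` therefore registers with translation ``-s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "apply_transform",
    "compose",
    "invert",
    "euler_to_matrix",
    "matrix_to_euler",
    "as_cloud",
]


def as_cloud(points, *, name: str = "cloud") -> np.ndarray:
    """Validate and return a point cloud as an ``(n, 3)`` float64 array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1 and arr.size == 0:
        arr = arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3); got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def _axis_rotations(angles_rad: np.ndarray):
    """Per-axis rotation matrices Rx, Ry, Rz for the given angles (radians)."""
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx, ry, rz


def euler_to_matrix(angles_deg) -> np.ndarray:
    """Rotation matrix for intrinsic Z-Y-X Euler angles given in degrees."""
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    rx, ry, rz = _axis_rotations(angles)
    return rz @ ry @ rx


def matrix_to_euler(r: np.ndarray) -> np.ndarray:
    """Recover intrinsic Z-Y-X Euler angles (degrees) from a rotation matrix.

    Away from the gimbal-lock pitch of +/-90 deg the decomposition is unique
    with pitch in (-90, 90).
    """
    r = np.asarray(r, dtype=float)
    sy = np.hypot(r[0, 0], r[1, 0])
    if sy < 1e-12:  # gimbal lock: roll and yaw degenerate, pick roll
        rx = np.arctan2(-r[1, 2], r[1, 1])
        ry = np.arctan2(-r[2, 0], sy)
        rz = 0.0
    else:
        rx = np.arctan2(r[2, 1], r[2, 2])
        ry = np.arctan2(-r[2, 0], sy)
        rz = np.arctan2(r[1, 0], r[0, 0])
    return np.rad2deg(np.array([rx, ry, rz]))


@dataclass(frozen=True)
class RigidTransform:
    """A 6DOF rigid pose: translation (mm) + Z-Y-X Euler rotation (degrees).

    Parameters
    ----------
    translation : array-like, shape (3,)
        (t_LAT, t_LNG, t_VRT) in mm.
    rotation_deg : array-like, shape (3,)
        (rx, ry, rz) in degrees, applied intrinsically in Z-Y-X order about
        the coordinate origin.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float).reshape(3)
        r = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("pose components must be finite")
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "rotation_deg", r)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        return cls(np.asarray(translation, dtype=float),
                   matrix_to_euler(rotation))

    @classmethod
    def from_vector(cls, v) -> "RigidTransform":
        """Build from a 6-vector (tx, ty, tz, rx, ry, rz) in mm / degrees."""
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(v[:3], v[3:])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation_deg])

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 rotation matrix."""
        return euler_to_matrix(self.rotation_deg)

    def apply(self, points) -> np.ndarray:
        """Map each point p to R @ p + t."""
        pts = as_cloud(points)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        ra, rb = self.matrix, other.matrix
        return RigidTransform.from_matrix(
            ra @ rb, ra @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        r = self.matrix
        return RigidTransform.from_matrix(r.T, -r.T @ self.translation)

    def is_identity(self, tol_mm: float = 1e-9, tol_deg: float = 1e-9) -> bool:
        return (np.abs(self.translation).max(initial=0.0) <= tol_mm
                and np.abs(self.rotation_deg).max(initial=0.0) <= tol_deg)

    def __repr__(self):  # compact, mm / deg
        t = ", ".join(f"{v:.4g}" for v in self.translation)
        r = ", ".join(f"{v:.4g}" for v in self.rotation_deg)
        return f"RigidTransform(t=[{t}] mm, r=[{r}] deg)"


def apply_transform(cloud, pose: RigidTransform) -> np.ndarray:
    """Apply a rigid pose to a point cloud (returns a new array)."""
    return pose.apply(cloud)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """compose(a, b).apply(p) == a.apply(b.apply(p))."""
    return a.compose(b)


def invert(pose: RigidTransform) -> RigidTransform:
    return pose.inverse()
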