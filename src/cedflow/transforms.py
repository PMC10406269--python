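"""Rigid (6-DOF) spatial transforms between imaging sessions and modalities.

A :class:`RigidTransform` maps world coordinates (RAS, millimetres) to world
coordinates.  Rotations are parameterised by Euler angles in degrees applied
about the fixed world axes in the order x, then y, then z, so the rotation
matrix is ``R = Rz @ Ry @ Rx``.  Translation is applied after rotation:
``y = R @ x + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "compose", "identity_transform"]

_ORTHO_TOL = 1e-8


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _euler_from_matrix(rot: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_rotation_matrix` (x, y, z order, degrees).

    Uses the standard Rz*Ry*Rx factorisation; at the gimbal singularity
    (|cos(ay)| ~ 0) the x angle is set to zero and the remaining rotation
    folded into z, which still reproduces the matrix.
    """
    sy = -rot[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ay = np.arcsin(sy)
    cy = np.cos(ay)
    if abs(cy) > 1e-9:
        ax = np.arctan2(rot[2, 1], rot[2, 2])
        az = np.arctan2(rot[1, 0], rot[0, 0])
    else:
        ax = 0.0
        az = np.arctan2(-rot[0, 1], rot[1, 1])
    return np.rad2deg(np.array([ax, ay, az]))


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid mapping between world frames.

    Parameters
    ----------
    rotation_deg : (3,) array-like
        Euler angles (degrees) about the world x, y, z axes, applied in
        that order.
    translation_mm : (3,) array-like
        Translation in millimetres, applied after rotation.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation_deg",
                           np.asarray(self.rotation_deg, dtype=float).reshape(3))
        object.__setattr__(self, "translation_mm",
                           np.asarray(self.translation_mm, dtype=float).reshape(3))

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world matrix."""
        m = np.eye(4)
        m[:3, :3] = _rotation_matrix(self.rotation_deg)
        m[:3, 3] = self.translation_mm
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {matrix.shape}")
        rot = matrix[:3, :3]
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation block has determinant -1 (reflection)")
        return cls(_euler_from_matrix(rot), matrix[:3, 3])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = pts @ _rotation_matrix(self.rotation_deg).T + self.translation_mm
        return out.reshape(np.shape(points_mm))

    def inverse(self) -> "RigidTransform":
        rot = _rotation_matrix(self.rotation_deg)
        inv = np.eye(4)
        inv[:3, :3] = rot.T
        inv[:3, 3] = -rot.T @ self.translation_mm
        return RigidTransform.from_matrix(inv)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation_deg"]), np.asarray(d["translation_mm"]))


def identity_transform() -> RigidTransform:
    return RigidTransform.identity()


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Composition ``outer ∘ inner``: apply ``inner`` first.

    ``compose(a, b).matrix == a.matrix @ b.matrix``.
    """
    return RigidTransform.from_matrix(outer.matrix @ inner.matrix)
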