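"""Rigid 3-D transforms parameterized by Euler angles and translations.

All transforms act on world coordinates (mm) about a fixed center, which
for this pipeline is the volume centroid. The convention is

    q = R @ (p - center) + center + t

with ``R = Rz @ Ry @ Rx`` built from extrinsic rotations in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def _wrap_degrees(deg: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    wrapped = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    wrapped[wrapped == -180.0] = 180.0
    return wrapped


@dataclass
class RigidTransform:
    """Six-parameter rigid motion: three rotations (deg), three translations (mm)."""

    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotations = _wrap_degrees(np.asarray(self.rotations, dtype=float))
        self.translations = np.asarray(self.translations, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        """Rotation matrix R = Rz @ Ry @ Rx."""
        return Rotation.from_euler("xyz", self.rotations, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translations

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.rotations, degrees=True).inv()
        # q = R(p-c)+c+t  =>  p = R^-1(q-c-t)+c = R^-1(q-c)+c - R^-1 t
        t_inv = -rot.as_matrix() @ self.translations
        return RigidTransform(
            rotations=rot.as_euler("xyz", degrees=True),
            translations=t_inv,
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        if not np.allclose(self.center, other.center):
            raise ValueError("can only compose transforms sharing a center")
        r_self = Rotation.from_euler("xyz", self.rotations, degrees=True)
        r_other = Rotation.from_euler("xyz", other.rotations, degrees=True)
        r = r_self * r_other
        t = r_self.as_matrix() @ other.translations + self.translations
        return RigidTransform(
            rotations=r.as_euler("xyz", degrees=True),
            translations=t,
            center=self.center,
        )

    @property
    def params(self) -> np.ndarray:
        """Flat (6,) parameter vector: rotations (deg) then translations (mm)."""
        return np.concatenate([self.rotations, self.translations])

    @classmethod
    def from_params(cls, params: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        params = np.asarray(params, dtype=float)
        return cls(rotations=params[:3], translations=params[3:], center=np.asarray(center))

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=np.asarray(center, dtype=float))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(
            np.all(np.abs(self.rotations) <= tol) and np.all(np.abs(self.translations) <= tol)
        )
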