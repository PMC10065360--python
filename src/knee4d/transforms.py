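"""Rigid 3-D transforms (rotation + translation, millimetres).

A :class:`RigidTransform` maps points ``x`` to ``R @ x + t``.  Rotations are
proper (det = +1) orthonormal 3x3 matrices; validity is enforced at
construction so downstream code can compose and invert freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: tolerance for orthonormality / unit-determinant checks
ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion of 3-D space, ``x -> R x + t`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max |R'R - I| = {err:.3g})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        # re-project onto SO(3) so composed transforms never drift
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        self.rotation.setflags(write=False)
        self.translation.setflags(write=False)

    # ------------------------------------------------------------------ #
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(
        cls, rotvec_deg: np.ndarray, translation: np.ndarray | None = None,
        center: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation given as an axis-angle vector in degrees, optionally
        about a center point, followed by an optional translation."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, float)
            t = t + c - R @ c
        return cls(R, t)

    # ------------------------------------------------------------------ #
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first: (self ∘ other)(x)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    # ------------------------------------------------------------------ #
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    def difference(self, other: "RigidTransform") -> tuple[float, float]:
        """(translation mm, rotation deg) magnitude of ``self⁻¹ ∘ other``."""
        d = self.inverse().compose(other)
        return float(np.linalg.norm(d.translation)), d.rotation_angle_deg()

    def almost_equal(self, other: "RigidTransform",
                     trans_tol_mm: float = 1e-9, rot_tol_deg: float = 1e-9) -> bool:
        dt, dr = self.difference(other)
        return dt <= trans_tol_mm and dr <= rot_tol_deg

    def as_flat_row(self) -> np.ndarray:
        """Row-major r11..r33 followed by tx, ty, tz (12 numbers)."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat_row(cls, row: np.ndarray) -> "RigidTransform":
        row = np.asarray(row, float).reshape(12)
        return cls(row[:9].reshape(3, 3), row[9:])
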