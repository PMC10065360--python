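"""Anatomical coordinate frames for femur, tibia and patella.

Each bone carries a right-handed orthonormal frame built from named
landmarks, with medial (+X), anterior (+Y) and proximal (+Z) positive for
a right knee:

* **femur** — origin at the exit of the medullary canal on the distal
  femur; Z along the mechanical axis toward the femoral head; X along the
  surgical epicondylar axis (lateral epicondyle → medial epicondylar
  sulcus) projected into the transverse plane; Y = Z × X.
* **tibia** — origin on the medullary canal 10 mm below the lateral
  articular surface; Z from the talocrural-joint center up to the origin;
  Y along the PCL-attachment → patellar-tendon-medial-border line
  projected perpendicular to Z; X = Y × Z.
* **patella** — origin at the midpoint of the patellar long/short axes
  offset 8 mm anterior of the articular plane along its normal; Z from
  apex to base; X is the femoral X projected perpendicular to Z;
  Y = Z × X.

The exactness hierarchy is fixed: the bone's longitudinal axis (Z) is
held exact, the secondary axis is obtained by projection, and the third
completes the right-handed triad — so axes are exactly orthonormal by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .meshes import BONES, LandmarkSet
from .transforms import ORTHO_TOL, RigidTransform

#: landmark directions closer than this to parallel are rejected
DEGENERACY_TOL = 1e-6

#: anterior offset of the patellar origin from its articular plane (mm)
PATELLA_ORIGIN_OFFSET_MM = 8.0


class DegenerateFrameError(ValueError):
    """Landmark geometry does not determine a frame (parallel/coincident)."""


@dataclass(frozen=True)
class CoordinateFrame:
    """Origin plus right-handed orthonormal axes, in global coordinates."""

    bone_label: str
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.bone_label not in BONES:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            object.__setattr__(self, name, v)
        A = self.axes
        if np.abs(A @ A.T - np.eye(3)).max() > 1e-7:
            raise ValueError("frame axes not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame axes left-handed")

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix with rows X, Y, Z."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points_global: np.ndarray) -> np.ndarray:
        """Express global points in this frame's coordinates."""
        return (np.asarray(points_global, float) - self.origin) @ self.axes.T

    def transformed(self, transform: RigidTransform) -> "CoordinateFrame":
        """Move the frame rigidly: origin maps as a point, axes rotate."""
        return CoordinateFrame(
            self.bone_label,
            transform.apply(self.origin),
            transform.rotate(self.x_axis),
            transform.rotate(self.y_axis),
            transform.rotate(self.z_axis),
        )

    # ------------------------------------------------------------------ #
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"bone": self.bone_label,
             "origin_mm": self.origin.tolist(),
             "axes_rows_xyz": self.axes.tolist()},
            indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoordinateFrame":
        d = json.loads(Path(path).read_text())
        A = np.asarray(d["axes_rows_xyz"], float)
        return cls(d["bone"], np.asarray(d["origin_mm"], float),
                   A[0], A[1], A[2])


# ---------------------------------------------------------------------- #
# helpers
# ---------------------------------------------------------------------- #

def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < DEGENERACY_TOL:
        raise DegenerateFrameError(f"{what}: direction degenerate (|v|={n:.3g})")
    return v / n


def _project_perp(v: np.ndarray, axis: np.ndarray, what: str) -> np.ndarray:
    """Component of ``v`` perpendicular to unit ``axis``, normalized."""
    p = v - np.dot(v, axis) * axis
    return _unit(p, what + " (near-parallel to primary axis)")


# ---------------------------------------------------------------------- #
# builders
# ---------------------------------------------------------------------- #

def build_femur_frame(landmarks: LandmarkSet) -> CoordinateFrame:
    """Femoral frame from hip center, canal exit and the epicondylar axis."""
    if landmarks.bone_label != "femur":
        raise ValueError("femur landmarks required")
    landmarks.require("hip_center", "canal_distal_exit",
                      "lateral_epicondyle", "medial_epicondyle_sulcus")
    origin = landmarks["canal_distal_exit"]
    z = _unit(landmarks["hip_center"] - origin, "femur Z (hip-canal axis)")
    sea = landmarks["medial_epicondyle_sulcus"] - landmarks["lateral_epicondyle"]
    x = _project_perp(_unit(sea, "femur SEA"), z, "femur X (SEA projection)")
    y = np.cross(z, x)
    return CoordinateFrame("femur", origin, x, y, z)


def build_tibia_frame(landmarks: LandmarkSet) -> CoordinateFrame:
    """Tibial frame from the canal point, talocrural center and the
    PCL → patellar-tendon anteroposterior line."""
    if landmarks.bone_label != "tibia":
        raise ValueError("tibia landmarks required")
    landmarks.require("canal_point_10mm", "talocrural_center",
                      "patellar_tendon_medial_border", "pcl_attachment")
    origin = landmarks["canal_point_10mm"]
    z = _unit(origin - landmarks["talocrural_center"], "tibia Z (shaft axis)")
    ap = (landmarks["patellar_tendon_medial_border"]
          - landmarks["pcl_attachment"])
    y = _project_perp(_unit(ap, "tibia AP line"), z, "tibia Y (AP projection)")
    x = np.cross(y, z)
    return CoordinateFrame("tibia", origin, x, y, z)


def build_patella_frame(landmarks: LandmarkSet,
                        femur_frame: CoordinateFrame) -> CoordinateFrame:
    """Patellar frame from base/apex, the articular plane and the femoral
    X axis (static pose)."""
    if landmarks.bone_label != "patella":
        raise ValueError("patella landmarks required")
    landmarks.require("base", "apex",
                      "articular_plane_point", "articular_plane_normal_point")
    z = _unit(landmarks["base"] - landmarks["apex"], "patella Z (apex-base)")
    x = _project_perp(femur_frame.x_axis, z,
                      "patella X (femoral X projection)")
    y = np.cross(z, x)

    plane_pt = landmarks["articular_plane_point"]
    normal = _unit(landmarks["articular_plane_normal_point"] - plane_pt,
                   "patella articular-plane normal")
    mid = 0.5 * (landmarks["base"] + landmarks["apex"])
    in_plane = mid - np.dot(mid - plane_pt, normal) * normal
    origin = in_plane + PATELLA_ORIGIN_OFFSET_MM * normal
    return CoordinateFrame("patella", origin, x, y, z)


def build_static_frames(landmark_sets: dict[str, LandmarkSet]
                        ) -> dict[str, CoordinateFrame]:
    """All three frames from a full landmark dictionary."""
    femur = build_femur_frame(landmark_sets["femur"])
    return {
        "femur": femur,
        "tibia": build_tibia_frame(landmark_sets["tibia"]),
        "patella": build_patella_frame(landmark_sets["patella"], femur),
    }
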