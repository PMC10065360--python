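"""Six-DOF femorotibial (FT) and patellofemoral (PF) position-posture.

Position is the femoral frame origin expressed in the reference bone's
(tibia or patella) axes.  Posture is three signed projected angles of
femoral axes onto reference-frame planes:

===================  =========================  ==================  =========
angle                 projected vector           plane (a, b)        reference
===================  =========================  ==================  =========
varus/valgus          femoral X                  reference X, Z      ref X
internal/external     femoral X                  reference X, Y      ref X
flexion/extension     femoral Y                  reference Y, Z      ref Y
===================  =========================  ==================  =========

Signs follow the atan2 convention: an angle is positive when the
projection is rotated from the reference axis toward the second plane
axis.  With medial +X, anterior +Y, proximal +Z frames on a right knee
this makes flexion, varus (medial tilt) and internal rotation positive.
Note these projected angles are not an Euler/cardan sequence: for
combined rotations they differ from any sequential decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import CoordinateFrame
from .register import transfer_frame
from .tracks import PoseTrack

JOINTS = ("FT", "PF")
DOF_NAMES = ("x_mm", "y_mm", "z_mm", "vv_deg", "ie_deg", "fe_deg")
TRANSLATION_DOFS = DOF_NAMES[:3]
ANGLE_DOFS = DOF_NAMES[3:]


class ProjectionDegenerateError(ValueError):
    """The vector to project is (numerically) perpendicular to the plane."""


def projected_angle(vector: np.ndarray, plane_axis_a: np.ndarray,
                    plane_axis_b: np.ndarray,
                    reference_axis: np.ndarray) -> float:
    """Signed angle (degrees) between the projection of ``vector`` onto
    span(a, b) and ``reference_axis``, positive toward ``plane_axis_b``.
    """
    v = np.asarray(vector, float)
    a = np.asarray(plane_axis_a, float)
    b = np.asarray(plane_axis_b, float)
    ref = np.asarray(reference_axis, float)
    ca, cb = np.dot(v, a), np.dot(v, b)
    if np.hypot(ca, cb) < 1e-9:
        raise ProjectionDegenerateError(
            "vector is perpendicular to the projection plane")
    proj = ca * a + cb * b
    normal = np.cross(a, b)
    ref = ref / np.linalg.norm(ref)
    return float(np.degrees(np.arctan2(np.dot(normal, np.cross(ref, proj)),
                                       np.dot(ref, proj))))


@dataclass(frozen=True)
class JointPose:
    """One volume's six-DOF state of the femur relative to a reference bone."""

    joint: str
    position_mm: np.ndarray          # femoral origin in reference axes
    varus_valgus_deg: float
    int_ext_rotation_deg: float
    flexion_extension_deg: float

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        object.__setattr__(self, "position_mm",
                           np.asarray(self.position_mm, float).reshape(3))
        vals = [*self.position_mm, self.varus_valgus_deg,
                self.int_ext_rotation_deg, self.flexion_extension_deg]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite joint pose")

    def as_vector(self) -> np.ndarray:
        """(x, y, z, varus/valgus, int/ext, flex/ext)."""
        return np.array([*self.position_mm, self.varus_valgus_deg,
                         self.int_ext_rotation_deg,
                         self.flexion_extension_deg])


def _component_angle(vector, a, b, ref, label, strict):
    # A femoral axis exactly perpendicular to a projection plane carries
    # no rotation within that plane; by continuity from the extended pose
    # the angle is taken as 0 unless the caller asks for a hard error.
    try:
        return projected_angle(vector, a, b, ref)
    except ProjectionDegenerateError as exc:
        if strict:
            raise ProjectionDegenerateError(f"{label}: {exc}") from None
        return 0.0


def _decompose(femur: CoordinateFrame, ref: CoordinateFrame,
               joint: str, strict: bool) -> JointPose:
    position = ref.to_local(femur.origin)
    vv = _component_angle(femur.x_axis, ref.x_axis, ref.z_axis, ref.x_axis,
                          f"{joint} varus/valgus", strict)
    ie = _component_angle(femur.x_axis, ref.x_axis, ref.y_axis, ref.x_axis,
                          f"{joint} int/ext rotation", strict)
    fe = _component_angle(femur.y_axis, ref.y_axis, ref.z_axis, ref.y_axis,
                          f"{joint} flexion/extension", strict)
    return JointPose(joint, position, vv, ie, fe)


def decompose_ft(femur_frame: CoordinateFrame,
                 tibia_frame: CoordinateFrame,
                 strict: bool = False) -> JointPose:
    """Femur relative to the tibial frame.

    ``strict=True`` raises :class:`ProjectionDegenerateError` (labeled by
    component) when a femoral axis is perpendicular to a projection plane
    instead of applying the continuity convention.
    """
    return _decompose(femur_frame, tibia_frame, "FT", strict)


def decompose_pf(femur_frame: CoordinateFrame,
                 patella_frame: CoordinateFrame,
                 strict: bool = False) -> JointPose:
    """Femur relative to the patellar frame (see :func:`decompose_ft`)."""
    return _decompose(femur_frame, patella_frame, "PF", strict)


# ---------------------------------------------------------------------- #
# series
# ---------------------------------------------------------------------- #

@dataclass
class JointKinematicsSeries:
    """Per-volume joint poses for one joint."""

    joint: str
    timestamps: np.ndarray
    poses: list[JointPose]
    source: str

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float).reshape(-1)
        if len(self.timestamps) != len(self.poses):
            raise ValueError("one pose per timestamp required")

    def __len__(self) -> int:
        return len(self.poses)

    def as_matrix(self) -> np.ndarray:
        """(n_volumes, 6) array in DOF_NAMES order."""
        return np.vstack([p.as_vector() for p in self.poses])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.as_matrix(), columns=list(DOF_NAMES))
        df.insert(0, "joint", self.joint)
        df.insert(0, "t_s", self.timestamps)
        df["source"] = self.source
        return df


def series_from_tracks(static_frames: dict[str, CoordinateFrame],
                       pose_tracks: dict[str, PoseTrack],
                       ) -> dict[str, JointKinematicsSeries]:
    """Transfer the static frames along each bone's pose track and
    decompose FT and PF poses per volume."""
    femur_t = pose_tracks["femur"]
    tibia_t = pose_tracks["tibia"]
    patella_t = pose_tracks["patella"]
    for other in (tibia_t, patella_t):
        if not np.allclose(other.timestamps, femur_t.timestamps):
            raise ValueError("pose tracks have mismatched timestamps")
    ft_poses, pf_poses = [], []
    for k in range(len(femur_t)):
        femur = transfer_frame(static_frames["femur"], femur_t[k])
        tibia = transfer_frame(static_frames["tibia"], tibia_t[k])
        patella = transfer_frame(static_frames["patella"], patella_t[k])
        ft_poses.append(decompose_ft(femur, tibia))
        pf_poses.append(decompose_pf(femur, patella))
    source = femur_t.source
    return {
        "FT": JointKinematicsSeries("FT", femur_t.timestamps, ft_poses, source),
        "PF": JointKinematicsSeries("PF", femur_t.timestamps, pf_poses, source),
    }


def save_kinematics(series: dict[str, JointKinematicsSeries],
                    path: str | Path) -> None:
    df = pd.concat([series[j].to_frame() for j in sorted(series)],
                   ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
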