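"""Triangulated bone surfaces and labelled anatomical landmarks.

Meshes are plain vertex/face arrays in millimetres with a bone label
(femur, tibia or patella).  File I/O (STL, PLY) is delegated to
:mod:`trimesh`; landmark sets round-trip through a small JSON schema
(``[{"bone": ..., "name": ..., "xyz_mm": [x, y, z]}, ...]``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .transforms import RigidTransform

BONES = ("femur", "tibia", "patella")

#: landmarks each bone's frame builder requires
REQUIRED_LANDMARKS = {
    "femur": ("hip_center", "canal_distal_exit",
              "lateral_epicondyle", "medial_epicondyle_sulcus"),
    "tibia": ("canal_point_10mm", "talocrural_center",
              "patellar_tendon_medial_border", "pcl_attachment"),
    "patella": ("base", "apex",
                "articular_plane_point", "articular_plane_normal_point"),
}


@dataclass
class Mesh:
    """Triangulated surface of one bone (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    bone_label: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.bone_label not in BONES:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        if len(self.vertices) < 4:
            raise ValueError("mesh needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    # ------------------------------------------------------------------ #
    def transformed(self, transform: RigidTransform) -> "Mesh":
        return Mesh(transform.apply(self.vertices), self.faces.copy(),
                    self.bone_label)

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), self.faces.copy(), self.bone_label)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, bone_label: str) -> "Mesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), bone_label)

    # ------------------------------------------------------------------ #
    def save(self, path: str | Path) -> None:
        """Write STL or PLY (chosen by extension)."""
        self.as_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path, bone_label: str) -> "Mesh":
        tm = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(tm, bone_label)


@dataclass
class LandmarkSet:
    """Named anatomical points on one bone, in the same coordinates as
    its mesh."""

    bone_label: str
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bone_label not in BONES:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        self.points = {k: np.asarray(v, dtype=float).reshape(3)
                       for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(
                f"landmark {name!r} missing on {self.bone_label}") from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"{self.bone_label} landmarks missing: {missing}")

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(self.bone_label,
                           {k: transform.apply(v)
                            for k, v in self.points.items()})


# ---------------------------------------------------------------------- #
# landmark JSON I/O
# ---------------------------------------------------------------------- #

def save_landmarks(landmark_sets: dict[str, LandmarkSet] | LandmarkSet,
                   path: str | Path) -> None:
    if isinstance(landmark_sets, LandmarkSet):
        landmark_sets = {landmark_sets.bone_label: landmark_sets}
    records = [
        {"bone": lm.bone_label, "name": name,
         "xyz_mm": [float(c) for c in xyz]}
        for lm in landmark_sets.values()
        for name, xyz in sorted(lm.points.items())
    ]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")


def load_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    records = json.loads(Path(path).read_text())
    out: dict[str, LandmarkSet] = {}
    for rec in records:
        lm = out.setdefault(rec["bone"], LandmarkSet(rec["bone"], {}))
        lm.points[rec["name"]] = np.asarray(rec["xyz_mm"], float)
    return out
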