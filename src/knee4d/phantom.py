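"""Synthetic knee phantom: bones, motion, artifacts, mocap reference.

This module generates everything the downstream pipeline consumes, playing
the role of the physical bone model, the CT scanner and the optical
motion-capture rig:

* parametric femur / tibia / patella surface meshes with the anatomical
  landmarks needed by the frame builders placed by construction;
* a passive flexion–extension–flexion motion script (0° → 90° → 0° →
  partial flexion over 10.5 s, sampled as 20 volumes) in which the femur
  stays fixed and the tibia (and, through a coupling ratio, the patella)
  rotates about the femoral flexion axis;
* per-volume "dynamic" meshes corrupted by speed-dependent noise that
  mimics 4D-CT motion artifacts — Gaussian jitter plus a directional
  smear along each vertex's instantaneous velocity plus face dropout, so
  corruption peaks mid-motion where speed is highest and is near baseline
  at the motion extremes;
* a motion-capture-style reference pose track with ~0.6 mm translation
  error and rotations bounded by 1°.

Bone shapes are composites of structured ellipsoids and cylinders — not
anatomical meshes — with deliberately asymmetric condyles and bumps so
every bone's surface determines its pose uniquely (no rotational
symmetry for ICP to slide along).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .meshes import BONES, LandmarkSet, Mesh
from .tracks import PoseTrack
from .transforms import RigidTransform

# expected magnitude of a 3-D isotropic Gaussian is E[chi_3] = sigma * 2*sqrt(2/pi)
_CHI3_MEAN = math.sqrt(2.0) * 1.0 / (math.sqrt(math.pi) / 2.0)

#: simulator convention: patellar flexion as a fraction of knee flexion
DEFAULT_PATELLA_COUPLING = 0.7


# ---------------------------------------------------------------------- #
# structured surface primitives
# ---------------------------------------------------------------------- #

def _grid_faces(n_u: int, n_v: int, wrap_u: bool) -> np.ndarray:
    """Quad-grid triangulation for an (n_u, n_v) vertex lattice."""
    faces = []
    u_max = n_u if wrap_u else n_u - 1
    for i in range(u_max):
        i2 = (i + 1) % n_u
        for j in range(n_v - 1):
            a, b = i * n_v + j, i2 * n_v + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    return np.asarray(faces, dtype=np.int64)


def _ellipsoid(center, semiaxes, n_u: int = 20, n_v: int = 14) -> tuple[np.ndarray, np.ndarray]:
    """UV-sphere scaled to an ellipsoid (closed; poles duplicated per row)."""
    center = np.asarray(center, float)
    a = np.asarray(semiaxes, float)
    u = np.linspace(0.0, 2 * np.pi, n_u, endpoint=False)
    v = np.linspace(0.0, np.pi, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.stack([a[0] * np.sin(vv) * np.cos(uu),
                    a[1] * np.sin(vv) * np.sin(uu),
                    a[2] * np.cos(vv)], axis=-1).reshape(-1, 3) + center
    return pts, _grid_faces(n_u, n_v, wrap_u=True)


def _cylinder(radius: float, z0: float, z1: float, n_theta: int = 20,
              ring_spacing: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """Closed axial cylinder with evenly spaced vertex rings along z."""
    n_z = max(2, int(round(abs(z1 - z0) / ring_spacing)) + 1)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(z0, z1, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    pts = np.stack([radius * np.cos(tt), radius * np.sin(tt), zz],
                   axis=-1).reshape(-1, 3)
    faces = _grid_faces(n_theta, n_z, wrap_u=True)
    # cap centers
    caps = np.array([[0.0, 0.0, z0], [0.0, 0.0, z1]])
    c0, c1 = len(pts), len(pts) + 1
    cap_faces = []
    for i in range(n_theta):
        i2 = (i + 1) % n_theta
        cap_faces.append([c0, i2 * n_z, i * n_z])
        cap_faces.append([c1, i * n_z + n_z - 1, i2 * n_z + n_z - 1])
    return (np.vstack([pts, caps]),
            np.vstack([faces, np.asarray(cap_faces, np.int64)]))


def _combine(parts: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    verts, faces, offset = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + offset)
        offset += len(v)
    return np.vstack(verts), np.vstack(faces)


# ---------------------------------------------------------------------- #
# bone generators
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class ShapeParams:
    """Overall bone dimensions, mm."""

    femur_length: float = 400.0
    femur_shaft_radius: float = 14.0
    tibia_length: float = 380.0
    tibia_shaft_radius: float = 13.0
    patella_height: float = 40.0
    surface_noise_mm: float = 0.15   # deterministic per-seed surface texture
    # tangential vertex scatter (mm): breaks the regular parametric vertex
    # lattice, like an irregular segmentation mesh; without it nearest-
    # neighbour ICP sees spurious minima at the lattice period
    tangential_jitter_mm: float = 2.5

    def validate(self) -> None:
        for name in ("femur_length", "femur_shaft_radius", "tibia_length",
                     "tibia_shaft_radius", "patella_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.surface_noise_mm < 0 or self.tangential_jitter_mm < 0:
            raise ValueError("surface noise magnitudes must be non-negative")


def generate_bone_mesh(bone_label: str,
                       shape_params: ShapeParams | None = None,
                       seed: int = 0) -> tuple[Mesh, LandmarkSet]:
    """Build one bone's surface mesh and its anatomical landmarks.

    Meshes are expressed in the bone's own anatomical coordinates
    (medial +X, anterior +Y, proximal +Z for a right knee), so that the
    frame built from the returned landmarks is the identity frame.
    """
    p = shape_params or ShapeParams()
    p.validate()
    if bone_label == "femur":
        verts, faces, lm = _femur(p)
    elif bone_label == "tibia":
        verts, faces, lm = _tibia(p)
    elif bone_label == "patella":
        verts, faces, lm = _patella(p)
    else:
        raise ValueError(f"unknown bone label {bone_label!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, BONES.index(bone_label)]))
    if p.tangential_jitter_mm > 0:
        normals = np.asarray(
            Mesh(verts, faces, bone_label).as_trimesh().vertex_normals)
        g = rng.normal(0.0, p.tangential_jitter_mm, verts.shape)
        verts = verts + g - (np.sum(g * normals, axis=1)[:, None] * normals)
    if p.surface_noise_mm > 0:
        verts = verts + rng.normal(0.0, p.surface_noise_mm, verts.shape)
    return Mesh(verts, faces, bone_label), LandmarkSet(bone_label, lm)


def _femur(p: ShapeParams):
    L = p.femur_length
    parts = [
        _cylinder(p.femur_shaft_radius, -2.0, L - 12.0),
        _ellipsoid((0, 0, L), (24, 24, 24)),                    # femoral head
        _ellipsoid((-22, -6, -18), (20, 24, 20)),               # lateral condyle
        _ellipsoid((23, -6, -18), (22, 26, 22)),                # medial condyle
        _ellipsoid((0, 16, -8), (16, 11, 14)),                  # trochlea
        _ellipsoid((-10, 10, L * 0.55), (17, 12, 20)),          # shaft flare
    ]
    verts, faces = _combine(parts)
    landmarks = {
        "canal_distal_exit": (0.0, 0.0, 0.0),
        "hip_center": (0.0, 0.0, L),
        "lateral_epicondyle": (-42.0, -6.0, -18.0),
        "medial_epicondyle_sulcus": (45.0, -6.0, -18.0),
    }
    return verts, faces, landmarks


def _tibia(p: ShapeParams):
    L = p.tibia_length
    parts = [
        _cylinder(p.tibia_shaft_radius, -(L - 10.0), 0.0),
        _ellipsoid((-18, 0, 0), (17, 22, 10)),                  # lateral plateau
        _ellipsoid((19, 0, 0), (19, 24, 10)),                   # medial plateau
        _ellipsoid((0, 15, -35), (10, 9, 14)),                  # tuberosity
        _ellipsoid((0, 0, -(L - 8.0)), (16, 14, 12)),           # distal epiphysis
        _ellipsoid((18, 0, -(L - 5.0)), (8, 7, 10)),            # medial malleolus
    ]
    verts, faces = _combine(parts)
    landmarks = {
        "canal_point_10mm": (0.0, 0.0, 0.0),
        "talocrural_center": (0.0, 0.0, -L),
        "patellar_tendon_medial_border": (0.0, 20.0, -32.0),
        "pcl_attachment": (0.0, -20.0, -3.0),
    }
    return verts, faces, landmarks


def _patella(p: ShapeParams):
    h = p.patella_height / 2.0
    parts = [
        _ellipsoid((0, 0, 0), (h, 9, h), n_u=24, n_v=18),
        _ellipsoid((h * 0.4, 4, h * 0.55), (6, 5, 6)),          # dorsal bump
    ]
    verts, faces = _combine(parts)
    landmarks = {
        "base": (0.0, 0.0, h),
        "apex": (0.0, 0.0, -h),
        "articular_plane_point": (0.0, -9.0, 0.0),
        "articular_plane_normal_point": (0.0, -8.0, 0.0),
    }
    return verts, faces, landmarks


# ---------------------------------------------------------------------- #
# scene assembly
# ---------------------------------------------------------------------- #

#: static placement of each bone's local frame in the scene (extended knee)
STATIC_OFFSETS = {
    "femur": np.zeros(3),
    "tibia": np.array([0.0, 0.0, -48.0]),
    "patella": np.array([0.0, 42.0, -10.0]),
}

#: point on the femoral flexion axis, scene coordinates
FLEXION_CENTER = np.array([0.0, 0.0, -18.0])


@dataclass
class KneePhantom:
    """Static scene: one mesh + landmark set per bone, scene coordinates."""

    meshes: dict[str, Mesh]
    landmarks: dict[str, LandmarkSet]


def make_knee_phantom(shape_params: ShapeParams | None = None,
                      seed: int = 0) -> KneePhantom:
    """Generate the three-bone knee in its extended (static CT) pose."""
    meshes, landmarks = {}, {}
    for bone in BONES:
        mesh, lm = generate_bone_mesh(bone, shape_params, seed)
        offset = RigidTransform(np.eye(3), STATIC_OFFSETS[bone])
        meshes[bone] = mesh.transformed(offset)
        landmarks[bone] = lm.transformed(offset)
    return KneePhantom(meshes, landmarks)


# ---------------------------------------------------------------------- #
# motion script
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class MotionScript:
    """Passive flexion–extension–flexion of the knee, femur fixed.

    The knee angle follows cosine-eased segments 0 → ``max_flexion_deg``
    → 0 → ``final_flexion_deg``, so angular velocity vanishes at the
    extremes and peaks mid-segment.  The tibia rotates about the femoral
    flexion axis by the knee angle; the patella follows with
    ``patella_coupling`` times the knee angle.
    """

    duration_s: float = 10.5
    n_volumes: int = 20
    max_flexion_deg: float = 90.0
    final_flexion_deg: float = 45.0
    patella_coupling: float = DEFAULT_PATELLA_COUPLING
    flexion_center: np.ndarray = field(
        default_factory=lambda: FLEXION_CENTER.copy())
    # rotation of the tibia about -X through the flexion center produces
    # positive knee flexion for a right knee (femur anterior +Y)
    flexion_axis: np.ndarray = field(
        default_factory=lambda: np.array([-1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if not (0.0 < self.max_flexion_deg <= 120.0):
            raise ValueError("max_flexion_deg must be in (0, 120]")
        if not (0.0 <= self.final_flexion_deg <= self.max_flexion_deg):
            raise ValueError("final flexion must be within [0, max]")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "flexion_center",
                           np.asarray(self.flexion_center, float))
        ax = np.asarray(self.flexion_axis, float)
        object.__setattr__(self, "flexion_axis", ax / np.linalg.norm(ax))

    # -- segment bookkeeping ------------------------------------------- #
    def _segments(self) -> list[tuple[float, float, float, float]]:
        """(t_start, t_end, angle_start, angle_end) per segment."""
        amps = [self.max_flexion_deg, self.max_flexion_deg,
                self.final_flexion_deg]
        keyframes = [0.0, self.max_flexion_deg, 0.0, self.final_flexion_deg]
        total = sum(amps)
        segs, t = [], 0.0
        for amp, a0, a1 in zip(amps, keyframes[:-1], keyframes[1:]):
            dt = self.duration_s * (amp / total) if total else 0.0
            if dt > 0:
                segs.append((t, t + dt, a0, a1))
                t += dt
        return segs

    def flexion_angle_deg(self, t: float) -> float:
        """Knee flexion angle at time ``t`` (clamped to the script span)."""
        t = min(max(t, 0.0), self.duration_s)
        for t0, t1, a0, a1 in self._segments():
            if t <= t1 or t1 == self.duration_s:
                s = (t - t0) / (t1 - t0)
                if s < 0.0:
                    s = 0.0
                return a0 + (a1 - a0) * 0.5 * (1.0 - math.cos(math.pi * s))
        return 0.0

    def flexion_rate_deg_s(self, t: float) -> float:
        """d(flexion)/dt, degrees per second."""
        t = min(max(t, 0.0), self.duration_s)
        for t0, t1, a0, a1 in self._segments():
            if t <= t1 or t1 == self.duration_s:
                s = max((t - t0) / (t1 - t0), 0.0)
                return (a1 - a0) * 0.5 * math.pi * math.sin(math.pi * s) / (t1 - t0)
        return 0.0

    # -- poses ---------------------------------------------------------- #
    def pose(self, bone_label: str, t: float) -> RigidTransform:
        """Scene-space motion of one bone at time ``t`` (identity at t=0)."""
        if bone_label == "femur":
            return RigidTransform.identity()
        angle = self.flexion_angle_deg(t)
        if bone_label == "patella":
            angle *= self.patella_coupling
        elif bone_label != "tibia":
            raise ValueError(f"unknown bone label {bone_label!r}")
        return RigidTransform.from_rotvec(self.flexion_axis * angle,
                                          center=self.flexion_center)

    def volume_times(self) -> np.ndarray:
        """Volume timestamps: centers of equal sub-intervals of the scan."""
        k = np.arange(self.n_volumes)
        return (k + 0.5) * self.duration_s / self.n_volumes

    def ground_truth_tracks(self) -> dict[str, PoseTrack]:
        times = self.volume_times()
        return {bone: PoseTrack(bone, times,
                                [self.pose(bone, t) for t in times],
                                source="ground_truth")
                for bone in BONES}


def make_motion_script(duration_s: float = 10.5, n_volumes: int = 20,
                       max_flexion_deg: float = 90.0,
                       final_flexion_deg: float = 45.0,
                       patella_coupling: float = DEFAULT_PATELLA_COUPLING,
                       ) -> MotionScript:
    """Convenience constructor for the default passive-motion script."""
    return MotionScript(duration_s=duration_s, n_volumes=n_volumes,
                        max_flexion_deg=max_flexion_deg,
                        final_flexion_deg=final_flexion_deg,
                        patella_coupling=patella_coupling)


# ---------------------------------------------------------------------- #
# motion-artifact corruption
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class ArtifactParams:
    """Speed-dependent corruption of dynamic meshes.

    Per vertex the displacement is isotropic Gaussian jitter with
    ``jitter_sigma_mm`` plus a one-dimensional Gaussian smear along the
    vertex's velocity with sigma ``smear_gain_mm_per_mm_s * |v|``; a
    random ``dropout_fraction`` of faces (with their now-unused vertices)
    is removed.  All three default to moderate values; zero everywhere
    reproduces the rigidly moved mesh exactly.
    """

    jitter_sigma_mm: float = 0.3
    smear_gain_mm_per_mm_s: float = 0.005
    dropout_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.jitter_sigma_mm < 0 or self.smear_gain_mm_per_mm_s < 0
                or self.dropout_fraction < 0):
            raise ValueError("artifact parameters must be non-negative")
        if self.dropout_fraction >= 0.5:
            raise ValueError("dropout_fraction must be < 0.5")

    @property
    def is_noise_free(self) -> bool:
        return (self.jitter_sigma_mm == 0 and self.smear_gain_mm_per_mm_s == 0
                and self.dropout_fraction == 0)


def vertex_velocities(mesh: Mesh, script: MotionScript, t: float,
                      dt: float = 1e-4) -> np.ndarray:
    """Instantaneous scene-space velocity of each vertex (mm/s), by
    central differencing of the script pose."""
    t0 = max(t - dt, 0.0)
    t1 = min(t + dt, script.duration_s)
    p0 = script.pose(mesh.bone_label, t0).apply(mesh.vertices)
    p1 = script.pose(mesh.bone_label, t1).apply(mesh.vertices)
    return (p1 - p0) / (t1 - t0)


def sample_dynamic_meshes(static_meshes: dict[str, Mesh],
                          script: MotionScript,
                          artifact_params: ArtifactParams | None = None,
                          ) -> list[dict[str, Mesh]]:
    """Rigidly move the static meshes to every volume time and corrupt
    them with the speed-dependent artifact model.

    Returns one ``{bone: Mesh}`` dict per volume.
    """
    params = artifact_params or ArtifactParams()
    volumes = []
    for k, t in enumerate(script.volume_times()):
        frame: dict[str, Mesh] = {}
        for bone, mesh in sorted(static_meshes.items()):
            pose = script.pose(bone, t)
            verts = pose.apply(mesh.vertices)
            faces = mesh.faces.copy()
            if not params.is_noise_free:
                rng = np.random.default_rng(np.random.SeedSequence(
                    [params.seed, k, BONES.index(bone)]))
                vel = vertex_velocities(mesh, script, t)
                speed = np.linalg.norm(vel, axis=1)
                direction = np.divide(vel, speed[:, None],
                                      out=np.zeros_like(vel),
                                      where=speed[:, None] > 1e-12)
                verts = (verts
                         + rng.normal(0.0, params.jitter_sigma_mm, verts.shape)
                         + direction * (params.smear_gain_mm_per_mm_s * speed
                                        * rng.normal(size=len(verts)))[:, None])
                if params.dropout_fraction > 0 and len(faces):
                    n_keep = len(faces) - int(params.dropout_fraction
                                              * len(faces))
                    keep = np.sort(rng.choice(len(faces), n_keep,
                                              replace=False))
                    faces = faces[keep]
                    used = np.unique(faces)
                    remap = -np.ones(len(verts), dtype=np.int64)
                    remap[used] = np.arange(len(used))
                    verts, faces = verts[used], remap[faces]
            frame[bone] = Mesh(verts, faces, bone)
        volumes.append(frame)
    return volumes


def corruption_per_volume(static_meshes: dict[str, Mesh],
                          script: MotionScript,
                          params: ArtifactParams) -> np.ndarray:
    """Mean vertex displacement between clean and corrupted dynamic
    meshes, per volume (dropout disabled so vertices correspond 1:1)."""
    clean_params = replace(params, dropout_fraction=0.0)
    corrupted = sample_dynamic_meshes(static_meshes, script, clean_params)
    out = np.zeros(script.n_volumes)
    for k, t in enumerate(script.volume_times()):
        disps = []
        for bone, mesh in static_meshes.items():
            exact = script.pose(bone, t).apply(mesh.vertices)
            disps.append(np.linalg.norm(
                corrupted[k][bone].vertices - exact, axis=1))
        out[k] = float(np.concatenate(disps).mean())
    return out


# ---------------------------------------------------------------------- #
# mocap reference
# ---------------------------------------------------------------------- #

def simulate_mocap_track(script: MotionScript,
                         trans_err_mm: float = 0.6,
                         rot_err_deg: float = 1.0,
                         seed: int = 0) -> dict[str, PoseTrack]:
    """Ground-truth poses perturbed like an optical-mocap record.

    Translation noise is isotropic Gaussian with the per-axis sigma set
    so the expected error magnitude equals ``trans_err_mm``; rotation
    noise is a uniformly random axis with angle drawn uniformly in
    ``[0, rot_err_deg]`` (bounded, matching a rig quoted as accurate to
    within that angle).  Timestamps coincide with the volume times.
    """
    if trans_err_mm < 0 or rot_err_deg < 0:
        raise ValueError("mocap error magnitudes must be non-negative")
    sigma = trans_err_mm / _CHI3_MEAN
    times = script.volume_times()
    tracks: dict[str, PoseTrack] = {}
    for bone in BONES:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, BONES.index(bone)]))
        poses = []
        for t in times:
            true = script.pose(bone, t)
            delta = RigidTransform.identity()
            if trans_err_mm > 0 or rot_err_deg > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rot_err_deg * rng.uniform()
                dt = rng.normal(0.0, sigma, 3) if trans_err_mm > 0 else np.zeros(3)
                delta = RigidTransform.from_rotvec(axis * angle, translation=dt)
            poses.append(true.compose(delta))
        tracks[bone] = PoseTrack(bone, times, poses, source="mocap")
    return tracks
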