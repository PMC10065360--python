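"""Rigid 3D-3D surface registration.

The static reference mesh of each bone is aligned to its appearance in
every dynamic volume with trimmed point-to-point ICP (Kabsch core,
nearest-neighbour correspondences against the target vertex cloud, the
largest-residual fraction of pairs discarded each iteration to resist
motion-artifact outliers).  The recovered transform then transfers the
static anatomical frame into the dynamic volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .frames import CoordinateFrame
from .meshes import Mesh
from .tracks import PoseTrack
from .transforms import RigidTransform


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------- #
# Kabsch
# ---------------------------------------------------------------------- #

def kabsch(source_points: np.ndarray, target_points: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Weighted least-squares rigid transform mapping source onto target.

    Minimizes ``sum_i w_i ||R s_i + t - t_i||^2`` via SVD of the weighted
    cross-covariance; a reflection in the optimum is excluded by flipping
    the smallest singular direction.
    """
    S = np.asarray(source_points, float).reshape(-1, 3)
    T = np.asarray(target_points, float).reshape(-1, 3)
    if S.shape != T.shape or len(S) < 3:
        raise ValueError("need equal point counts >= 3")
    if weights is None:
        w = np.full(len(S), 1.0 / len(S))
    else:
        w = np.asarray(weights, float).reshape(-1)
        if len(w) != len(S) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("invalid weights")
        w = w / w.sum()
    cs = w @ S
    ct = w @ T
    H = (S - cs).T @ ((T - ct) * w[:, None])
    U, sing, Vt = np.linalg.svd(H)
    if sing[1] < 1e-12 * max(sing[0], 1.0):
        raise ValueError("degenerate point configuration (collinear or "
                         "coincident)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


# ---------------------------------------------------------------------- #
# ICP
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 50
    rms_delta_tol: float = 1e-6      # mm
    sample_points: int = 2000
    trim_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.sample_points < 10:
            raise ValueError("sample_points must be >= 10")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    n_iterations: int
    rms_history: np.ndarray


def icp(source: Mesh, target: Mesh,
        init: RigidTransform | None = None,
        params: ICPParams | None = None) -> ICPResult:
    """Trimmed point-to-point ICP aligning ``source`` into ``target``.

    Source points are sampled once per call (seeded); each iteration
    matches them to nearest target vertices, discards the
    ``trim_fraction`` largest-residual pairs, and updates the transform
    with a Kabsch fit.  Stops when the accepted RMS changes by less than
    ``rms_delta_tol`` or at ``max_iterations``.
    """
    params = params or ICPParams()
    current = init or RigidTransform.identity()
    if not len(source.vertices) or not len(target.vertices):
        raise RegistrationError("empty mesh")

    rng = np.random.default_rng(params.seed)
    n = min(params.sample_points, len(source.vertices))
    idx = rng.choice(len(source.vertices), n, replace=False)
    src = source.vertices[idx]
    tree = cKDTree(target.vertices)
    n_keep = n - int(params.trim_fraction * n)
    if n_keep < 3:
        raise RegistrationError("no correspondences left after trimming")

    rms_prev = np.inf
    history = []
    for it in range(1, params.max_iterations + 1):
        moved = current.apply(src)
        dist, nn = tree.query(moved)
        keep = np.argsort(dist)[:n_keep]
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if not np.isfinite(rms):
            raise RegistrationError("non-finite ICP residual")
        history.append(rms)
        delta = kabsch(moved[keep], target.vertices[nn[keep]])
        current = delta.compose(current)
        if abs(rms_prev - rms) < params.rms_delta_tol:
            break
        rms_prev = rms
    return ICPResult(current, history[-1], len(history), np.asarray(history))


# ---------------------------------------------------------------------- #
# sequence registration & frame transfer
# ---------------------------------------------------------------------- #

@dataclass
class SequenceDiagnostics:
    """Per (bone, volume) ICP residual and iteration count."""

    bone: list[str]
    volume: list[int]
    rms_mm: list[float]
    iterations: list[int]

    def as_records(self) -> list[dict]:
        return [{"bone": b, "volume": v, "rms_mm": r, "iterations": i}
                for b, v, r, i in zip(self.bone, self.volume,
                                      self.rms_mm, self.iterations)]


def register_sequence(static_meshes: dict[str, Mesh],
                      dynamic_mesh_sets: list[dict[str, Mesh]],
                      params: ICPParams | None = None,
                      timestamps: np.ndarray | None = None,
                      init_strategy: str = "previous",
                      ) -> tuple[dict[str, PoseTrack], SequenceDiagnostics]:
    """Register each bone's static mesh into every dynamic volume.

    Initialization exploits the continuity of the acquisition: the
    default ``init_strategy="previous"`` starts volume k from the volume
    k-1 result (identity for k = 0, since the acquisition starts in the
    pose of the static scan).  ``"predict"`` extrapolates at constant
    velocity (``T_{k-1} T_{k-2}^{-1} T_{k-1}``), exact for rotation
    about a fixed axis at constant rate, but can overshoot at motion
    reversals when volumes are sparse.  Returns a per-bone pose track
    tagged ``registered`` plus per-volume diagnostics.
    """
    if init_strategy not in ("predict", "previous"):
        raise ValueError("init_strategy must be 'predict' or 'previous'")
    params = params or ICPParams()
    if not dynamic_mesh_sets:
        raise ValueError("need at least one dynamic volume")
    bones = sorted(static_meshes)
    for k, vols in enumerate(dynamic_mesh_sets):
        if sorted(vols) != bones:
            raise ValueError(f"volume {k} bone labels do not match static set")
    n_vol = len(dynamic_mesh_sets)
    times = (np.arange(n_vol, dtype=float) if timestamps is None
             else np.asarray(timestamps, float))

    diag = SequenceDiagnostics([], [], [], [])
    tracks: dict[str, PoseTrack] = {}
    for bone in bones:
        poses: list[RigidTransform] = []
        for k in range(n_vol):
            if k == 0:
                current = RigidTransform.identity()
            elif k == 1 or init_strategy == "previous":
                current = poses[-1]
            else:
                step = poses[-1].compose(poses[-2].inverse())
                current = step.compose(poses[-1])
            vol_params = ICPParams(
                max_iterations=params.max_iterations,
                rms_delta_tol=params.rms_delta_tol,
                sample_points=params.sample_points,
                trim_fraction=params.trim_fraction,
                seed=int(np.random.SeedSequence(
                    [params.seed, bones.index(bone), k]).generate_state(1)[0]
                    % (2 ** 31)),
            )
            try:
                res = icp(static_meshes[bone], dynamic_mesh_sets[k][bone],
                          init=current, params=vol_params)
            except (RegistrationError, ValueError) as exc:
                raise RegistrationError(
                    f"ICP failed for bone {bone!r} at volume {k}: {exc}"
                ) from exc
            current = res.transform
            poses.append(current)
            diag.bone.append(bone)
            diag.volume.append(k)
            diag.rms_mm.append(res.rms_mm)
            diag.iterations.append(res.n_iterations)
        tracks[bone] = PoseTrack(bone, times, poses, source="registered")
    return tracks, diag


def transfer_frame(static_frame: CoordinateFrame,
                   transform: RigidTransform) -> CoordinateFrame:
    """Carry a static-CT anatomical frame into a dynamic volume: the
    origin maps as a point, the axes rotate."""
    return static_frame.transformed(transform)
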