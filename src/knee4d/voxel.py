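"""Optional voxel path: mesh → binary volume → reconstructed surface.

Emulates the CT side of the pipeline at the data level: a bone mesh is
rasterized into an isotropic binary occupancy volume (surface shell via
trimesh voxelization, interior filled morphologically) and a surface is
recovered with marching cubes.  Volumes round-trip through the MetaImage
(.mhd/.raw) format.  Default pitch follows a thin-section CT protocol
(0.5 mm); coarser pitches keep desk-scale tests fast.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .meshes import Mesh

DEFAULT_PITCH_MM = 0.5


def voxelize(mesh: Mesh, pitch_mm: float = DEFAULT_PITCH_MM,
             pad_voxels: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Solid binary occupancy grid of a (closed) mesh.

    Returns ``(volume, origin_mm)`` where ``volume[i, j, k]`` covers the
    point ``origin + pitch * (i, j, k)``.
    """
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    vg = mesh.as_trimesh().voxelized(pitch_mm)
    shell = np.asarray(vg.matrix, dtype=bool)
    solid = ndimage.binary_fill_holes(shell)
    solid = np.pad(solid, pad_voxels)
    origin = (np.asarray(vg.translation, float)
              - pad_voxels * pitch_mm * np.ones(3))
    return solid, origin


def reconstruct_surface(volume: np.ndarray, pitch_mm: float,
                        origin_mm: np.ndarray, bone_label: str) -> Mesh:
    """Marching-cubes isosurface of a binary volume, back in mm."""
    verts, faces, _, _ = marching_cubes(volume.astype(np.float32), level=0.5,
                                        spacing=(pitch_mm,) * 3)
    return Mesh(verts + np.asarray(origin_mm, float), faces, bone_label)


# ---------------------------------------------------------------------- #
# MetaImage I/O
# ---------------------------------------------------------------------- #

def save_mhd(volume: np.ndarray, pitch_mm: float, origin_mm: np.ndarray,
             path: str | Path) -> None:
    """Write a binary volume as MetaImage header + raw (uint8)."""
    path = Path(path)
    raw_path = path.with_suffix(".raw")
    data = np.ascontiguousarray(volume.astype(np.uint8))
    # MetaImage is Fortran-ordered on disk (x fastest)
    raw_path.write_bytes(data.tobytes(order="F"))
    origin = np.asarray(origin_mm, float)
    header = "\n".join([
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        f"DimSize = {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"ElementSpacing = {pitch_mm:g} {pitch_mm:g} {pitch_mm:g}",
        f"Offset = {origin[0]:g} {origin[1]:g} {origin[2]:g}",
        "ElementType = MET_UCHAR",
        f"ElementDataFile = {raw_path.name}",
    ]) + "\n"
    path.write_text(header)


def load_mhd(path: str | Path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read a MetaImage volume written by :func:`save_mhd`."""
    path = Path(path)
    fields = {}
    for line in path.read_text().splitlines():
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    shape = tuple(int(x) for x in fields["DimSize"].split())
    pitch = float(fields["ElementSpacing"].split()[0])
    origin = np.asarray([float(x) for x in fields["Offset"].split()])
    raw = (path.parent / fields["ElementDataFile"]).read_bytes()
    volume = np.frombuffer(raw, dtype=np.uint8).reshape(shape, order="F")
    return volume.astype(bool), pitch, origin
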