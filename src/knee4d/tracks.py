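"""Time series of per-bone rigid poses (4D-CT volumes or mocap samples).

CSV layout: one row per (t_s, bone) with the rotation row-major
(r11..r33) and the translation (tx, ty, tz) in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .meshes import BONES
from .transforms import RigidTransform

SOURCE_TAGS = ("ground_truth", "mocap", "registered")

_CSV_COLS = ["t_s", "bone",
             "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
             "tx", "ty", "tz", "source"]


@dataclass
class PoseTrack:
    """Poses of one bone over time, tagged with their provenance."""

    bone_label: str
    timestamps: np.ndarray
    transforms: list[RigidTransform]
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.bone_label not in BONES:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        if self.source not in SOURCE_TAGS:
            raise ValueError(f"unknown source tag {self.source!r}")
        self.timestamps = np.asarray(self.timestamps, float).reshape(-1)
        if len(self.timestamps) != len(self.transforms):
            raise ValueError("one transform per timestamp required")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def __getitem__(self, k: int) -> RigidTransform:
        return self.transforms[k]

    def max_difference(self, other: "PoseTrack") -> tuple[float, float]:
        """Worst (translation mm, rotation deg) discrepancy per volume."""
        pairs = [a.difference(b) for a, b in zip(self.transforms,
                                                 other.transforms)]
        return (max(p[0] for p in pairs), max(p[1] for p in pairs))


# ---------------------------------------------------------------------- #
# CSV / JSON I/O
# ---------------------------------------------------------------------- #

def tracks_to_frame(tracks: dict[str, PoseTrack]) -> pd.DataFrame:
    rows = []
    for bone in sorted(tracks):
        tr = tracks[bone]
        for t, T in zip(tr.timestamps, tr.transforms):
            rows.append([t, bone, *T.as_flat_row(), tr.source])
    return pd.DataFrame(rows, columns=_CSV_COLS)


def save_tracks(tracks: dict[str, PoseTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.12g",
                                   lineterminator="\n")


def load_tracks(path: str | Path) -> dict[str, PoseTrack]:
    df = pd.read_csv(path)
    out: dict[str, PoseTrack] = {}
    for bone, grp in df.groupby("bone", sort=True):
        grp = grp.sort_values("t_s")
        transforms = [RigidTransform.from_flat_row(row)
                      for row in grp[_CSV_COLS[2:14]].to_numpy(float)]
        out[str(bone)] = PoseTrack(str(bone), grp["t_s"].to_numpy(float),
                                   transforms, grp["source"].iloc[0])
    return out
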