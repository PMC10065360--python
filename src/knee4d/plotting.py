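"""Plots of kinematics traces and per-volume differences."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .kinematics import DOF_NAMES, JOINTS, JointKinematicsSeries  # noqa: E402
from .validate import AccuracyReport  # noqa: E402


def plot_series_comparison(series_4dct: dict[str, JointKinematicsSeries],
                           series_ref: dict[str, JointKinematicsSeries],
                           path: str | Path) -> None:
    """Overlay 4D-CT-derived and reference kinematics, one panel per DOF."""
    fig, axes = plt.subplots(len(JOINTS), len(DOF_NAMES),
                             figsize=(18, 6), sharex=True)
    for r, joint in enumerate(JOINTS):
        a, b = series_4dct[joint], series_ref[joint]
        ma, mb = a.as_matrix(), b.as_matrix()
        for c, dof in enumerate(DOF_NAMES):
            ax = axes[r, c]
            ax.plot(a.timestamps, ma[:, c], label="4D-CT", color="tab:blue")
            ax.plot(b.timestamps, mb[:, c], label="reference",
                    color="tab:red", ls="--")
            ax.set_title(f"{joint} {dof}", fontsize=9)
            if c == 0:
                ax.set_ylabel("mm / deg")
    axes[0, 0].legend(fontsize=8)
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_differences(report: AccuracyReport, path: str | Path) -> None:
    """Per-volume difference traces for every DOF and acquisition."""
    fig, axes = plt.subplots(len(JOINTS), len(DOF_NAMES),
                             figsize=(18, 6), sharex=True)
    for r, joint in enumerate(JOINTS):
        for c, dof in enumerate(DOF_NAMES):
            ax = axes[r, c]
            for a, diffs in enumerate(report.per_volume[joint]):
                ax.plot(diffs[:, c], alpha=0.8, label=f"acq {a}")
            ax.axhline(0.0, color="k", lw=0.5)
            ax.set_title(f"{joint} {dof}", fontsize=9)
            if c == 0:
                ax.set_ylabel("difference (mm / deg)")
    axes[0, 0].legend(fontsize=7)
    axes[-1, 0].set_xlabel("volume index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
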