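"""Accuracy validation of pipeline kinematics against a reference track.

Mirrors the study design: the registered 4D-CT kinematics series is
paired volume-by-volume with the motion-capture reference series, the
absolute per-DOF differences are averaged over volumes, and that average
is itself averaged over repeated acquisitions.  ``run_experiment``
executes the whole synthetic replication — phantom, motion, artifacts,
mocap, registration, decomposition, report — from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frames import CoordinateFrame, build_static_frames
from .kinematics import (DOF_NAMES, JOINTS, JointKinematicsSeries,
                         save_kinematics, series_from_tracks)
from .phantom import (ArtifactParams, KneePhantom, MotionScript,
                      make_knee_phantom, sample_dynamic_meshes,
                      simulate_mocap_track, ShapeParams)
from .register import ICPParams, SequenceDiagnostics, register_sequence
from .tracks import PoseTrack, save_tracks


# ---------------------------------------------------------------------- #
# pairing
# ---------------------------------------------------------------------- #

@dataclass
class PairedSeries:
    """Volume-matched differences (series_a − series_b) for one joint."""

    joint: str
    timestamps: np.ndarray
    differences: np.ndarray            # (n_pairs, 6), DOF_NAMES order
    n_unmatched: int = 0

    def __len__(self) -> int:
        return len(self.timestamps)


def pair_series(series_a: JointKinematicsSeries,
                series_b: JointKinematicsSeries,
                time_tol_s: float | None = None) -> PairedSeries:
    """Match volumes of two series by nearest timestamp.

    Default tolerance is half the inter-volume interval of ``series_a``;
    unmatched volumes are counted and reported with a warning.
    """
    if not len(series_a) or not len(series_b):
        raise ValueError("cannot pair empty series")
    if series_a.joint != series_b.joint:
        raise ValueError("joint mismatch")
    ta, tb = series_a.timestamps, series_b.timestamps
    if time_tol_s is None:
        time_tol_s = (0.5 * float(np.median(np.diff(ta))) if len(ta) > 1
                      else np.inf)
    ma, mb = series_a.as_matrix(), series_b.as_matrix()
    rows, times = [], []
    n_unmatched = 0
    for i, t in enumerate(ta):
        j = int(np.argmin(np.abs(tb - t)))
        if abs(tb[j] - t) <= time_tol_s:
            rows.append(ma[i] - mb[j])
            times.append(t)
        else:
            n_unmatched += 1
    if not rows:
        raise ValueError("no volumes matched within the time tolerance")
    if n_unmatched:
        warnings.warn(f"{series_a.joint}: {n_unmatched} volumes had no "
                      f"reference sample within {time_tol_s:.3g} s",
                      stacklevel=2)
    return PairedSeries(series_a.joint, np.asarray(times), np.vstack(rows),
                        n_unmatched)


# ---------------------------------------------------------------------- #
# accuracy report
# ---------------------------------------------------------------------- #

@dataclass
class AccuracyReport:
    """Per-joint, per-DOF accuracy statistics over all acquisitions.

    ``mean_abs`` is the average over volumes of |difference|, then
    averaged across acquisitions (absolute values first); ``max_abs`` is
    the worst single volume anywhere; ``mean_signed`` is a secondary
    bias diagnostic.
    """

    table: pd.DataFrame                     # joint, dof, mean_abs, max_abs, mean_signed
    per_acquisition: pd.DataFrame           # joint, dof, acquisition, mean_abs
    per_volume: dict[str, list[np.ndarray]] # joint -> per-acq (n_vol, 6) diffs
    n_volumes: int
    n_acquisitions: int

    def value(self, joint: str, dof: str, stat: str = "mean_abs") -> float:
        row = self.table[(self.table.joint == joint) & (self.table.dof == dof)]
        return float(row[stat].iloc[0])

    def worst(self, dofs: tuple[str, ...], stat: str = "mean_abs") -> float:
        """Largest statistic over both joints for the given DOFs."""
        sub = self.table[self.table.dof.isin(dofs)]
        return float(sub[stat].max())

    def to_dict(self) -> dict:
        out: dict = {"n_volumes": self.n_volumes,
                     "n_acquisitions": self.n_acquisitions, "joints": {}}
        for joint in JOINTS:
            out["joints"][joint] = {
                dof: {"mean_abs": self.value(joint, dof),
                      "max_abs": self.value(joint, dof, "max_abs"),
                      "mean_signed": self.value(joint, dof, "mean_signed")}
                for dof in DOF_NAMES}
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True,
                       default=float) + "\n")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g",
                          lineterminator="\n")


def accuracy_report(paired_acquisitions: list[dict[str, PairedSeries]]
                    ) -> AccuracyReport:
    """Aggregate paired differences from one or more acquisitions."""
    if not paired_acquisitions:
        raise ValueError("no paired series")
    rows, acq_rows = [], []
    per_volume: dict[str, list[np.ndarray]] = {j: [] for j in JOINTS}
    for joint in JOINTS:
        diffs = [acq[joint].differences for acq in paired_acquisitions]
        per_volume[joint] = diffs
        per_acq_mean = np.vstack([np.abs(d).mean(axis=0) for d in diffs])
        all_diffs = np.vstack(diffs)
        for d, dof in enumerate(DOF_NAMES):
            rows.append({
                "joint": joint, "dof": dof,
                "mean_abs": float(per_acq_mean[:, d].mean()),
                "max_abs": float(np.abs(all_diffs[:, d]).max()),
                "mean_signed": float(all_diffs[:, d].mean()),
            })
            for a in range(len(diffs)):
                acq_rows.append({"joint": joint, "dof": dof, "acquisition": a,
                                 "mean_abs": float(per_acq_mean[a, d])})
    n_vol = len(paired_acquisitions[0][JOINTS[0]])
    return AccuracyReport(pd.DataFrame(rows), pd.DataFrame(acq_rows),
                          per_volume, n_vol, len(paired_acquisitions))


# ---------------------------------------------------------------------- #
# full experiment
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to replicate the study synthetically."""

    shape: ShapeParams = field(default_factory=ShapeParams)
    duration_s: float = 10.5
    n_volumes: int = 20
    max_flexion_deg: float = 90.0
    final_flexion_deg: float = 45.0
    patella_coupling: float = 0.7
    artifact: ArtifactParams = field(default_factory=ArtifactParams)
    mocap_trans_err_mm: float = 0.6
    mocap_rot_err_deg: float = 1.0
    icp: ICPParams = field(default_factory=ICPParams)
    n_acquisitions: int = 3

    def script(self) -> MotionScript:
        return MotionScript(duration_s=self.duration_s,
                            n_volumes=self.n_volumes,
                            max_flexion_deg=self.max_flexion_deg,
                            final_flexion_deg=self.final_flexion_deg,
                            patella_coupling=self.patella_coupling)

    # -- YAML ----------------------------------------------------------- #
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "shape" in kwargs:
            kwargs["shape"] = ShapeParams(**kwargs["shape"])
        if "artifact" in kwargs:
            kwargs["artifact"] = ArtifactParams(**kwargs["artifact"])
        if "icp" in kwargs:
            kwargs["icp"] = ICPParams(**kwargs["icp"])
        return cls(**kwargs)


@dataclass
class AcquisitionResult:
    """Artifacts of one simulated acquisition."""

    registered_tracks: dict[str, PoseTrack]
    mocap_tracks: dict[str, PoseTrack]
    registered_series: dict[str, JointKinematicsSeries]
    mocap_series: dict[str, JointKinematicsSeries]
    paired: dict[str, PairedSeries]
    diagnostics: SequenceDiagnostics


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    phantom: KneePhantom
    script: MotionScript
    static_frames: dict[str, CoordinateFrame]
    ground_truth_tracks: dict[str, PoseTrack]
    acquisitions: list[AcquisitionResult]
    report: AccuracyReport


def run_experiment(config: ExperimentConfig | None = None,
                   seed: int = 0,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full synthetic replication.

    Generates the phantom once (the bone model is the same physical
    object in every acquisition), then for each acquisition draws fresh
    artifact, mocap and ICP sampling seeds, registers the dynamic
    volumes, decomposes FT/PF kinematics for both the registered and the
    mocap track, and aggregates the accuracy report.  All randomness
    derives from ``seed``; outputs (if ``out_dir`` is given) are written
    deterministically.
    """
    config = config or ExperimentConfig()
    n_acq = config.n_acquisitions
    if n_acq < 1:
        raise ValueError("need at least one acquisition")
    seeds = np.random.SeedSequence(seed).generate_state(1 + 3 * n_acq) % (2 ** 31)
    phantom = make_knee_phantom(config.shape, int(seeds[0]))
    script = config.script()
    frames = build_static_frames(phantom.landmarks)
    gt_tracks = script.ground_truth_tracks()

    acquisitions: list[AcquisitionResult] = []
    for a in range(n_acq):
        art_seed, mocap_seed, icp_seed = (int(s) for s in
                                          seeds[1 + 3 * a: 4 + 3 * a])
        dynamic = sample_dynamic_meshes(
            phantom.meshes, script, replace(config.artifact, seed=art_seed))
        reg_tracks, diag = register_sequence(
            phantom.meshes, dynamic, replace(config.icp, seed=icp_seed),
            timestamps=script.volume_times())
        mocap_tracks = simulate_mocap_track(
            script, config.mocap_trans_err_mm, config.mocap_rot_err_deg,
            seed=mocap_seed)
        reg_series = series_from_tracks(frames, reg_tracks)
        mocap_series = series_from_tracks(frames, mocap_tracks)
        paired = {j: pair_series(reg_series[j], mocap_series[j])
                  for j in JOINTS}
        acquisitions.append(AcquisitionResult(
            reg_tracks, mocap_tracks, reg_series, mocap_series, paired, diag))

    report = accuracy_report([acq.paired for acq in acquisitions])
    result = ExperimentResult(config, seed, phantom, script, frames,
                              gt_tracks, acquisitions, report)
    if out_dir is not None:
        write_experiment(result, out_dir)
    return result


def write_experiment(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write every experiment artifact as CSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    save_tracks(result.ground_truth_tracks, out / "ground_truth_track.csv")
    for bone, frame in sorted(result.static_frames.items()):
        frame.to_json(out / f"frame_{bone}.json")
    for a, acq in enumerate(result.acquisitions):
        prefix = out / f"acq{a}"
        save_tracks(acq.registered_tracks, f"{prefix}_registered_track.csv")
        save_tracks(acq.mocap_tracks, f"{prefix}_mocap_track.csv")
        save_kinematics(acq.registered_series, f"{prefix}_kinematics_4dct.csv")
        save_kinematics(acq.mocap_series, f"{prefix}_kinematics_mocap.csv")
        pd.DataFrame(acq.diagnostics.as_records()).to_csv(
            f"{prefix}_icp_diagnostics.csv", index=False,
            float_format="%.12g", lineterminator="\n")
    result.report.to_json(out / "accuracy_report.json")
    result.report.to_csv(out / "accuracy_report.csv")
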