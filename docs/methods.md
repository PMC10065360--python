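# Methods

This note documents the models, conventions and numerical choices behind
`knee4d`, and what its synthetic validation does and does not show.

## Pipeline model

The package treats dynamic joint imaging as a parameter-recovery
problem. A static, artifact-free surface model of each bone carries the
anatomical coordinate frame; each dynamic volume shows the same rigid
bone, moved and corrupted. Per bone and volume the pipeline estimates
the rigid map static → dynamic by surface matching, transfers the static
frame through it, and reads joint state off the transferred frames. All
lengths are millimetres, all angles degrees.

## Anatomical frames

Frames are right-handed and orthonormal with medial +X, anterior +Y,
proximal +Z on a right knee:

| bone | origin | Z (exact) | secondary (projected) | third |
|---|---|---|---|---|
| femur | medullary-canal exit on the distal femur | origin → hip center | X: lateral epicondyle → medial epicondylar sulcus, projected ⊥ Z | Y = Z × X |
| tibia | canal point 10 mm below the lateral articular surface | talocrural center → origin | Y: PCL attachment → patellar-tendon medial border, projected ⊥ Z | X = Y × Z |
| patella | long/short-axis midpoint, 8 mm anterior of the articular plane along its normal | apex → base | X: femoral X projected ⊥ Z | Y = Z × X |

The exactness hierarchy (longitudinal axis exact, secondary projected,
third by cross product) follows the order in which each axis is
introduced anatomically; it makes the axes orthonormal by construction
rather than by a posteriori re-orthogonalization. Construction fails
with a labeled `DegenerateFrameError` when a defining line is within
1e-6 of parallel to the primary axis or two landmarks coincide.
Landmarks are inputs (JSON or phantom-emitted); automatic landmark
detection from mesh geometry is out of scope.

The patellar "Y perpendicular to X and Y" wording found in some axis
conventions is resolved as the only meaningful orthogonal completion,
Y = Z × X.

## Registration

`kabsch` solves the weighted least-squares rigid superposition by SVD of
the weighted cross-covariance, sign-correcting the smallest singular
direction so reflections are never returned; configurations whose
second singular value is below 1e-12 (collinear/coincident) are
rejected. On consistent correspondences it is exact to machine
precision (tested to 1e-9 over random transforms).

`icp` is trimmed point-to-point ICP: source points are sampled once per
call with a seeded generator (default 2000), matched to nearest target
*vertices* with a KD-tree, the 20 % largest-residual pairs are
discarded, and a Kabsch update is applied; iteration stops when the
accepted RMS changes by < 1e-6 mm or after 50 iterations. Trimming is
the minimal defense against the smear/dropout outliers of dynamic
meshes. Matching to target vertices rather than surface-projected
closest points is a deliberate fidelity/speed trade-off: at the vertex
densities used (≈ 2–4 mm spacing, with the phantom's exact vertex
correspondence in the noise-free limit) the approximation error is well
below the artifact noise.

`register_sequence` chains the volumes: volume k is initialized from
the volume k−1 result (identity for k = 0, matching the protocol in
which the motion starts in the static scan's extended pose). A
constant-velocity extrapolation init (`init_strategy="predict"`,
world-frame `T_{k-1} T_{k-2}^{-1} T_{k-1}`) is available; it is exact
for fixed-axis constant-rate motion but can overshoot at motion
reversals when volumes are sparse, so plain chaining is the default.

Chained initialization bounds the capture range: point-to-point ICP on
these shapes converges reliably when the inter-volume pose step stays
below roughly 20° of rotation. The full 20-volume protocol satisfies
this with margin (≤ ~18° per step at peak speed); scaled-down runs in
the test suite therefore pair fewer volumes with a proportionally
gentler flexion arc rather than registering under-sampled 90° motion.

## Joint decomposition

Position is the femoral frame origin expressed in the reference bone's
axes (tibia for FT, patella for PF). Posture uses three *projected*
angles, each the signed atan2 angle between a projected femoral axis and
a reference axis, positive when rotated from the reference axis toward
the second plane axis:

| angle | vector | plane | reference | positive sense |
|---|---|---|---|---|
| varus/valgus | femoral X | reference XZ | ref X | medial tilt (toward +Z) |
| int/ext rotation | femoral X | reference XY | ref X | internal (toward +Y) |
| flexion/extension | femoral Y | reference YZ | ref Y | flexion (toward +Z) |

With these conventions a pure rotation about one reference axis yields
exactly one nonzero angle equal to the commanded value. Projected
angles are **not** an Euler/cardan sequence: for combined rotations they
differ from any sequential decomposition (a unit test documents the
discrepancy rather than asserting equality), and they are invariant
under a common global rigid motion of both frames.

When a femoral axis is exactly perpendicular to a projection plane the
projected angle is undefined. `projected_angle` reports this as an
error (in-plane norm < 1e-9). The joint decompositions instead apply a
continuity convention — an axis perpendicular to the plane has no
measurable rotation within it, and the limit from the extended pose is
0° — because the all-angles-defined contract is what a closed-form
single-axis sweep through 90° requires; `strict=True` restores the
labeled error for callers that prefer to be told.

## Synthetic phantom

The phantom stands in for the physical bone model, the CT scanner and
the mocap rig; its defaults are the study conditions.

**Bones.** Composites of structured ellipsoids and cylinders at realistic
scale (femur 400 mm, tibia 380 mm, patella 40 mm) with deliberately
asymmetric condyles, a tuberosity, a malleolus and a dorsal patellar
bump so no bone has a rotational symmetry for ICP to slide along. Two
deterministic per-seed perturbations make the discretization behave
like a segmentation mesh rather than a parametric lattice: tangential
vertex scatter (σ = 2.5 mm, shape-preserving to ≈ 0.2 mm at these
curvatures) — without it the regular vertex rings of the shaft create
spurious ICP minima at the lattice period — and 0.15 mm radial surface
noise. Landmarks are placed by construction in each bone's anatomical
coordinates, so the frames built from them are the identity in the
bone's local system (a fixture-level oracle).

**Motion.** Femur fixed; tibia rotates about the femoral flexion axis
through a 0° → 90° → 0° → 45° arc over 10.5 s; the patella follows with
a 0.7 coupling ratio (a simulator convention, config-exposed). Segments
are cosine-eased with durations proportional to swept angle, so angular
velocity vanishes at the extremes and peaks mid-segment. The 20 volume
timestamps are the centers of equal sub-intervals; the pose at t = 0 is
the identity (the static pose). The final flexion amplitude of 45° is a
simulator choice — only "another flexion" is specified for the tail of
the maneuver.

**Artifacts.** Per vertex, displacement = isotropic Gaussian jitter
(σ = 0.3 mm) + a 1-D Gaussian smear along the vertex's instantaneous
velocity with σ = 0.005 s × |v| (central-differenced from the script),
plus 5 % random face dropout with unreferenced vertices removed.
Corruption is therefore maximal at the volumes of peak speed and near
baseline at the motion extremes — the qualitative signature of 4D-CT
motion artifacts. Magnitudes are tuning knobs chosen to be moderate
(peak smear ≈ 1 mm at the distal tibia); no quantitative artifact
measurements exist to calibrate against. Zero parameters reproduce the
rigid motion exactly.

**Reference track.** Ground-truth poses perturbed per volume by
translation noise with per-axis σ = 0.6 mm / E[χ₃] (so the expected
error magnitude is 0.6 mm) and a uniformly-random-axis rotation with
angle ~ U(0, 1°), bounded as a rig quoted "within 1 degree" implies.
Noise composes on the body side, so the pose-difference translation is
exactly the drawn noise vector.

## Validation statistics

Registered and reference series are paired by nearest timestamp
(default tolerance: half the inter-volume interval; unmatched volumes
are counted and warned about). Per DOF the absolute differences are
averaged over volumes first, then across acquisitions ("average of
absolute value differences"); the maximum single-volume difference and
the signed mean (bias) are carried alongside. The three acquisitions
re-use one phantom (the same physical object is scanned repeatedly) but
draw fresh artifact, mocap and ICP-sampling seeds from the experiment
seed via a seed sequence; a fixed seed makes the entire run, including
every CSV/JSON byte written, reproducible.

## What passing tests show — and don't

The phantom validates the *pipeline*: frame math, registration
convergence under speed-dependent corruption, decomposition and
reporting, under exactly known ground truth. It does not model CT
physics (reconstruction, partial-volume blur structure, gantry tilt),
segmentation error of real bone, cartilage-space compliance, or
out-of-plane coupled motion of a real knee; the artifact model is a
phenomenological stand-in. Accuracy numbers from the synthetic study
are therefore evidence of correct mechanics and of noise propagation at
the stated magnitudes, not a clinical accuracy claim. With the default
conditions the worst per-DOF mean absolute difference against the
reference is ≈ 0.5 mm / 0.5°, dominated — as in the physical
experiment's error budget — by the reference's own noise.

## Problem sizes

Default experiment: 3 acquisitions × 20 volumes × 3 bones (meshes of
≈ 0.7–2 k vertices), ICP with 2000 sampled points; this runs in well
under a minute on one CPU. Unit and property tests use the same bones
with 5–8 volume scripts of 30–40° amplitude (matching the capture-range
constraint above) and 500–800 ICP samples. The voxel round-trip is
exercised on the patella at 2 mm pitch; the default 0.5 mm pitch is the
thin-section CT protocol value and works identically at larger memory
cost.

## Known limitations

- Point-to-point ICP only; point-to-plane is not implemented.
- No automatic landmarking; real-data use requires user-supplied
  landmarks, including an operational definition of the medullary-canal
  points.
- The phantom is a right knee; mirroring conventions for a left knee
  are not provided.
- Registration of sequences whose inter-volume steps exceed the capture
  range fails toward local minima rather than erroring; the RMS
  diagnostics expose this (rms_mm far above the artifact noise floor).
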