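"""Rigid 3D-3D surface registration with trimmed ICP.

Applies a known rigid motion to the phantom femur, corrupts the moved
copy like a 4D-CT volume, and recovers the motion by registering the
clean static mesh onto it.  The recovered transform is compared with
the applied one.
"""

import numpy as np

import knee4d as k

phantom = k.make_knee_phantom(seed=1)
femur = phantom.meshes["femur"]

true = k.RigidTransform.from_rotvec([12.0, -5.0, 8.0],
                                    translation=[6.0, -4.0, 10.0])
rng = np.random.default_rng(0)
target = k.Mesh(true.apply(femur.vertices)
                + rng.normal(0.0, 0.3, femur.vertices.shape),
                femur.faces, "femur")

res = k.icp(femur, target, params=k.ICPParams(seed=1))
dt, dr = res.transform.difference(true)
print(f"ICP converged in {res.n_iterations} iterations, "
      f"RMS {res.rms_mm:.3f} mm")
print(f"recovery error vs applied motion: {dt:.4f} mm, {dr:.4f} deg")
# With 0.3 mm vertex jitter the pose is recovered to a few hundredths of
# a millimetre/degree: averaging over ~2000 correspondences suppresses
# the per-vertex noise.
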