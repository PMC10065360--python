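"""Build the femoral, tibial and patellar anatomical frames.

Each frame comes from named landmarks: origin, a longitudinal Z axis
(held exact), a projected secondary axis and a right-handed completion.
On the phantom, whose bones are generated in their own anatomical
coordinates, the axes come out as the global identity — a built-in
sanity check.
"""

import numpy as np

import knee4d as k

phantom = k.make_knee_phantom(seed=1)
frames = k.build_static_frames(phantom.landmarks)

for bone, frame in frames.items():
    print(f"{bone} frame:")
    print(f"  origin (mm): {np.round(frame.origin, 3)}")
    print(f"  axes rows X/Y/Z:\n{np.round(frame.axes, 6)}")

# Equivariance: rigidly moving the landmarks moves the frame identically.
T = k.RigidTransform.from_rotvec([0, 0, 30.0], translation=[10, 0, 5])
moved = k.build_femur_frame(phantom.landmarks["femur"].transformed(T))
expected = frames["femur"].transformed(T)
print("\nequivariance residual (should be ~1e-16):",
      np.abs(moved.axes - expected.axes).max())
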