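"""Generate the synthetic knee phantom and inspect its anatomy.

Builds the three-bone knee (femur, tibia, patella) in its extended
static-CT pose, prints mesh sizes and the anatomical landmarks each
frame builder consumes, and samples the motion script.
"""

import numpy as np

import knee4d as k

phantom = k.make_knee_phantom(seed=1)
for bone, mesh in phantom.meshes.items():
    print(f"{bone:8s} {len(mesh.vertices):5d} vertices, "
          f"{len(mesh.faces):5d} faces")
    for name, xyz in sorted(phantom.landmarks[bone].points.items()):
        print(f"         {name:30s} ({xyz[0]:7.1f}, {xyz[1]:7.1f}, "
              f"{xyz[2]:7.1f}) mm")

script = k.make_motion_script()   # 0->90->0->45 deg over 10.5 s, 20 volumes
angles = [script.flexion_angle_deg(t) for t in script.volume_times()]
print("\nknee flexion at the 20 volume times (deg):")
print(np.array2string(np.asarray(angles), precision=1))
# The femur stays fixed; the tibia rotates about the femoral flexion axis
# by these angles and the patella follows with a 0.7 coupling ratio.
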