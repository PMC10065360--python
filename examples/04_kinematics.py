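"""Six-DOF joint kinematics from a pose track.

Transfers the static anatomical frames along the ground-truth motion
and decomposes femorotibial (FT) and patellofemoral (PF) position-
posture per volume: origin offset in the reference bone's axes plus the
three projected angles (varus/valgus, internal/external rotation,
flexion/extension).
"""

import numpy as np

import knee4d as k

phantom = k.make_knee_phantom(seed=1)
frames = k.build_static_frames(phantom.landmarks)
script = k.make_motion_script()

series = k.series_from_tracks(frames, script.ground_truth_tracks())
ft = series["FT"].as_matrix()
print("volume  t(s)   FT x,y,z (mm)          vv,ie,fe (deg)")
for i, t in enumerate(series["FT"].timestamps):
    print(f"{i:4d} {t:7.2f}  ({ft[i,0]:6.1f},{ft[i,1]:6.1f},{ft[i,2]:6.1f})"
          f"   ({ft[i,3]:6.2f},{ft[i,4]:6.2f},{ft[i,5]:6.2f})")

commanded = [script.flexion_angle_deg(t) for t in script.volume_times()]
print("\nmax |FT flexion - commanded knee angle| (deg):",
      np.abs(ft[:, 5] - commanded).max())
# On the ground-truth track the FT flexion trace reproduces the script's
# commanded 0->90->0->45 degree arc to numerical precision; varus and
# rotation stay at zero because the motion is a pure flexion rotation.
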