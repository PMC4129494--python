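"""Inspect the morphogenetic schedule driving c-looping.

Each process is a diagonal growth tensor in the local (radial,
circumferential, longitudinal) frame whose parameter ramps linearly over
the two-step protocol (initial step to the HH10- reference, looping step
HH10- -> HH12).
"""

import numpy as np

from cloop import baseline_schedule, process_tensor, ramp_value

sched = baseline_schedule()
print("stage pseudo-times:", sched.stage_map)

print("\nparameter values at stage endpoints:")
for p in sched.processes:
    v10 = ramp_value(p, sched.stage_map["HH10-"], sched)
    v12 = ramp_value(p, sched.stage_map["HH12"], sched)
    print(f"  {p.name:20s} ({p.kind:19s}) HH10-: {v10:5.3f}  HH12: {v12:5.3f}"
          f"  regions: {','.join(p.regions)}")

print("\ndifferential myocardial growth at the looping end:")
for theta in (0.0, np.pi / 2, np.pi):
    d = process_tensor("differential_growth", 1.3, theta)
    print(f"  Theta = {np.degrees(theta):5.1f} deg: diag(R,T,Z) = "
          f"({d[0]:.3f}, {d[1]:.3f}, {d[2]:.3f}), det = {np.prod(d):.3f}")
print("the determinant equals the hypertrophy gradient G = 2*Theta/pi + 1:")
print("growth is weakest at the dorsal side (future inner curvature) and "
      "threefold ventrally (future outer curvature) -- this bends the tube.")
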