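"""Build the idealized HH10- heart and inspect its anatomy.

The fixture stands in for an OCT-reconstructed embryonic chick heart: a
straight heart tube (myocardial shell + cardiac-jelly annulus around a
dorsoventrally elongated lumen), conotruncus, two omphalomesenteric veins,
a dorsal-mesocardium strip and the two surrounding membranes.
"""

import numpy as np

from cloop import GeometryParams, build_idealized_heart, compute_local_frames, write_mesh

params = GeometryParams(target_edge_length=100.0)
mesh = build_idealized_heart(params)

print(f"nodes: {mesh.n_nodes}, tetrahedra: {len(mesh.tets)}, "
      f"membrane triangles: {len(mesh.tris)}")
for name in ("HT", "CT", "LOV", "ROV", "DM"):
    print(f"  region {name:4s}: {len(mesh.elem_sets[name])} elements")

frames = compute_local_frames(mesh)
dm = mesh.elem_sets["DM"]
print(f"circumferential angle on the DM strip: "
      f"max {np.degrees(frames.theta[dm].max()):.1f} deg (should be near 0: "
      f"Theta is measured from the dorsal mesocardium)")

write_mesh(mesh, "idealized_heart.inp")
print("wrote idealized_heart.inp (restricted Abaqus dialect: "
      "*NODE/*ELEMENT C3D4+M3D3/*NSET/*ELSET)")
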