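"""Exercise the tissue material law at a single material point.

All tissues share the exponential nearly-incompressible strain energy
W = (A/B)(exp(B(I1_bar-3)) - 1) + (1/D)((J^2-1)/2 - ln J); growth enters
through the multiplicative split F = F* . M, and only F* generates stress.
"""

import numpy as np

from cloop import CARDIAC_JELLY, MEMBRANE, MYOCARDIUM, cauchy_stress, elastic_part

# isochoric uniaxial stretch of 20%
lam = 1.2
F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
print("axial Cauchy stress under 20% isochoric stretch:")
for name, mat in (("myocardium", MYOCARDIUM), ("cardiac jelly", CARDIAC_JELLY),
                  ("membrane", MEMBRANE)):
    s = cauchy_stress(F, mat)
    print(f"  {name:14s}: sigma_11 = {s[0, 0]:7.2f} Pa")
print("membrane > myocardium > jelly: the stiffness ordering of the tissues")

# compatible growth is stress-free: F equal to the morphogenesis tensor
M = np.diag([1.1, 1.1, 1.43])
F_star = elastic_part(M, M)
print("\ncompatible growth F = M: |sigma| =",
      np.abs(cauchy_stress(F_star, MYOCARDIUM)).max(), "Pa (exactly zero)")
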