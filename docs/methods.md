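# Methods

## Model overview

`cloop` simulates c-looping, the first shape change of the embryonic heart:
between Hamburger–Hamilton stages HH10 and HH12 (~33–48 h of incubation in
the chick) the straight heart tube (HT) bends ventrally and twists
rightward into a c-shape.  The model treats the tissues as morphoelastic
continua: prescribed growth and active contraction define a local
zero-stress state, and elasticity enforces compatibility between
differently growing parts, between the heart and its attachments (dorsal
mesocardium, conotruncus, omphalomesenteric veins), and between the heart
and the membranes that sandwich it (splanchnopleure ventrally, foregut wall
dorsally).  The driving hypothesis encoded in the default parameter set:
ventral bending comes from differential hypertrophic myocardial growth
(largest at the future outer curvature), while torsion is directed by the
asymmetric growth of the veins (left > right) and amplified by the
compressive load of the splanchnopleure.

## Kinematics and constitutive law

The deformation gradient is decomposed multiplicatively,

    F = F* · M,

where `M` is the morphogenesis tensor (growth/contraction; defines the
stress-free state) and `F*` the elastic part.  Cauchy stress depends on
`F*` only:

    σ = (1/J*) F* · ∂W/∂E* · F*ᵀ,  E* = (F*ᵀF* − I)/2,  J* = det F*.

All tissues use the same isotropic, nearly incompressible exponential
strain-energy density

    W = (A/B)(exp[B(Ī₁ − 3)] − 1) + (1/D)((J*² − 1)/2 − ln J*),
    Ī₁ = J*^(−2/3) tr(F*ᵀF*),

with microindentation-based constants (Pa): myocardium A = 13.0, B = 0.57;
cardiac jelly A = 3.2, B = 0.39; membranes (unmeasured, taken twice as
stiff as myocardium because they carry active tension in vivo) A = 26.0,
B = 0.57.  D = 0.01 is read as a volumetric compliance in 1/Pa — the bulk
stiffness scale 1/D = 100 Pa — which is the only dimensionally consistent
reading of the energy.  The stress and the fourth-order tangent are
analytic; finite differences of W serve as the test oracle, never as the
implementation.  Membrane triangles use the same 3-D law under a plane
stress condition (through-thickness stress driven to zero by a scalar
Newton per element) with a nominal thickness of 5 μm (configurable; no
measured value exists for these membranes).

## Morphogenetic processes

Each process contributes a diagonal tensor in the local (e_R, e_Θ, e_Z)
frame; the per-element total is the (order-independent) product of all
active factors, rotated to global axes.  Parameters ramp linearly in
pseudo-time over a two-step protocol — an *initial* step that establishes
the HH10− reference (initial jelly growth and endodermal contraction only)
and a *looping* step over which every process acts.  Baseline endpoints:

| process | tensor (R, Θ, Z) | value | where |
|---|---|---|---|
| endodermal contraction | (v⁻², v, v), det = 1 | 1 → 0.9 → 0.63 | SPL, foregut, caudal OV sides (AIP) |
| cardiac-jelly growth | v·I | 1 → 1.1 → 1.43 | HT jelly |
| DM tension | (1, 1, v) | 1 → 0.8 | dorsal-mesocardium strip |
| differential growth | (v, v, G/v²), det = G(Θ) | v: 1 → 1.3 | HT myocardium |
| cell-shape change | (1, S, 1/S), det = 1 | 1 → 1.3 | HT myocardium |
| vein-fusion surrogate | (1, 1, v) | 1 → 1.5 | HT (both layers) |
| isotropic growth | v·I | 1 → 1.3 / 1.6 / 1.2 | conotruncus / left / right OV cranial sides |

`G(Θ) = 2Θ/π + 1` is the hypertrophy gradient (Θ ∈ [0, π] measured from
the DM; threefold ventral growth drives bending);
`S(Θ) = (v − 1)(Θ/π − 1)² + 1` concentrates circumferential cell elongation
dorsally.  Because the end state prescribes `det M_g = G(Θ)` while the
looping step must start from the HH10− state continuously, the gradient
itself builds up linearly: at looping fraction `f` the tensor is evaluated
at `G(fΘ) = 1 + f(G(Θ) − 1)`, which preserves `det M_g = G` of the ramped
gradient exactly and is the only reading consistent with "parameters change
linearly over time".

The vein-fusion process is a surrogate for the true addition of material
at the caudal HT: because label-tracking experiments cannot see uniform
lengthening produced by material addition, this component is removed from
all reported strains (see Measurements).

To apply the Θ-dependent processes piecewise-uniformly (which limits
stress concentrations at region borders), the HT is divided into 24
subregions — 8 longitudinal × 3 circumferential bins by default (the
layout is a modelling choice; only the count is prescribed) — and each
subregion uses its volume-averaged Θ.

OV split: growth acts on the cranial-facing half of each vein wall and
endodermal (AIP) contraction on the caudal-facing half, the split being the
sign of the cranial component of the element-centroid offset from the vein
axis.  This follows the anatomical description of the forces (growth on
the cranial sides, contraction around the AIP) rather than an
arc-length split of the vein.

## Idealized geometry

The geometry generator replaces image-based reconstruction with a
parametric HH10− heart (all lengths μm, overridable): HT length 1000,
myocardial shell outer radius 150 / thickness 20, cardiac jelly filling to
an elliptical lumen with semi-axes 60 (dorsoventral) × 20 (lateral),
conotruncus length 300 continuing the tube cranially, two vein branches
(radius 100, length 400, 60° lateral of caudal) attached to the caudal HT
face by displacement ties, a DM strip of 0.5 rad angular width on the
dorsal myocardium, and two planar membranes offset 10 μm from the ventral
(splanchnopleure) and dorsal (foregut wall) heart surface.  Membrane
margins are fixed; the splanchnopleure nodes lying over the caudal vein
surfaces are instead tied to them — the AIP attachment, which is excluded
from the contact pairs.  The sheets extend well past the heart so the tube
never reaches their fixed margins even after its ~60% elongation.  Axes:
+x embryonic
right, +y cranial, +z ventral; the DM sits at −z, so rightward rotation is
a positive lumen-ellipse angle.  These dimensions are fixture choices
consistent with published ~200 μm scale bars, not measured values.  A
slight initial left/right asymmetry (right HT wall 3% longer, implemented
as a shear of the longitudinal coordinate) seeds the experimentally
observed geometric bias.

Meshes are structured tetrahedral lattices (each hexahedral cell split
into six face-conforming tetrahedra) with triangulated membrane sheets,
mirroring a linear C3D4/M3D3 discretization.  With the default 60 μm
target edge the model has ~9k tetrahedra; the test-suite meshes are
coarser (130–170 μm).

Local frames: e_R is the weighted average of the exterior and interior
(lumen) surface normals, weighted by the distance to the opposite surface;
e_Z follows the cross-sectional centroid curve of the part projected onto
the wall plane; e_Θ = e_Z × e_R.  Surface normals are angle-weighted
vertex normals interpolated at the closest surface point; on a faceted
tube this recovers the cylindrical basis up to an error bounded by the
polygon facet angle (~3° at default resolution), which is immaterial
because every anisotropic process tensor is transversely isotropic about
e_Z (exact) except the weak cell-shape term.

## Solver

Quasi-static implicit Newton continuation replaces explicit dynamics:
runs are deterministic, need no mass scaling, and converge each pseudo-time
increment to a force tolerance of 1e−6 × (A_MY × edge²).  Ingredients:

- total-Lagrangian linear tetrahedra with analytic consistent tangent
  (including the morphogenesis pull-back `P = det(M) F* S M⁻ᵀ`); membranes
  use forward-difference 9×9 element tangents;
- boundary conditions by per-node reduction onto allowed-motion subspaces:
  conotruncus and vein ends move only along their end normals, the DM
  cranial anchor rides cranial–caudal rollers, the caudal anchor slides in
  the cranial–lateral plane, membrane margins are fixed;
- automatic rigid-body repair: the six rigid modes (and their
  combinations) are checked per connected component against the constraint
  set and minimal single-direction pins are added where needed — used by
  the dissection scenarios;
- part junctions (veins→HT, splanchnopleure→veins) as penalty displacement
  ties on barycentric master points (stiffness 30 × A_membrane × edge;
  zero force in the initial configuration);
- frictionless node-to-triangle penalty contact (heart↔membranes, lumen
  self-contact) with default penalty 100 × A_MY / wall thickness, a C¹
  smoothing band of 2 μm around zero gap, and continuous interpolated
  vertex normals; the pairing state is frozen within each Newton pass and
  refreshed in an outer fixed-point loop, which eliminates active-set
  chatter;
- a Newton step cap of half an edge length (trust-region style) and a
  backtracking line search;
- dynamic relaxation for limit points: when plain Newton fails (the
  rightward-torsion snap is a genuine bifurcation, and sliding contact on
  faceted surfaces produces micro-snaps), the increment is traversed by
  damped modified-Newton flow `u ← u − (K₀ + cI)⁻¹ r(u)` with a frozen
  factorization reused across many cheap steps; the fixed point of the
  flow is an equilibrium of the unstabilised problem.  The damping level
  adapts, persists across increments while the path stays rough, and the
  flow's best state is accepted when its residual is below 10³× the Newton
  tolerance (still ≤0.1% of the elemental force scale) — every such
  increment is flagged in the run log with its damping coefficient;
- adaptive increment bisection as the final fallback.

Default increments: 10 (initial step) + 30 (looping step, divisible by 3
so the HH10/HH11 stage times land exactly on increments).

Symmetric problems stay symmetric: with the asymmetry parameters zeroed
the mid-HT rotation remains ≈ 0; an optional seeded random kick
(`symmetry_break_amplitude`, default 0) exists to probe the bifurcation
explicitly.

## Measurements

All quantifications mirror the embryo experiments:

- **Rotation angle α**: the lumen surface is sliced by the plane normal to
  the HT centroid curve at its arc-length midpoint; the section curve is
  fitted with a direct least-squares ellipse; α is the signed angle of the
  long axis from the dorsoventral axis, positive toward the embryonic
  right, range (−90°, 90°]; near-circular sections (axis ratio < 1.05) are
  flagged unreliable.
- **Morphogenetic strains**: Lagrangian strains of each element relative
  to the HH10− configuration with the uniform fusion growth removed
  (`F_rep = F_rel · M_f⁻¹`), projected on the reference local frames and
  volume-averaged per region: longitudinal E_ZZ over {LHT, RHT, VHT, LOV,
  ROV, LAIP, RAIP}, circumferential E_ΘΘ over {HT, LOV, ROV}.
- **Stress sign maps**: σ_zz, σ_θθ in reference frames convected by the
  rotation part of F_rel, classified tension/compression/neutral with a
  dead band of 0.02 × A of the tissue.
- **Markers**: paths of the ventral-midline node line; the signed lateral
  displacement of the mid-tube marker summarises looping direction.

## Scenario catalogue

Perturbations are pure deltas on the baseline (parameters otherwise
unchanged): contraction off (M_c ≡ 1); fusion off with the DM either free
or on full-length cranial-caudal rollers (intact DM); dissections (SPL,
either or both veins, the HT, conotruncus transection, longitudinal DM
cut) as element deletion at the start of the run, with rigid-mode repair
standing in for the ad-hoc supports of bench dissections.  Outcome checks
are qualitative by design (sign and ordering, not magnitude): thresholds
are 50% of the baseline HH12 rotation for "torsion collapse"/"rotation
abolished" and 3× the baseline waviness metric for vein buckling; both are
conventions of this package, stated in `cloop.scenarios`.

## Problem sizes

The production geometry (60 μm target edge, ~9k tetrahedra) is beyond
desk-scale budgets for full looping runs; the package's own computations
use coarser settings, chosen as the package's standard problem sizes:

- verification problems (patch test, compatible growth, bilayer rod):
  structured bricks up to ~15k tetrahedra, seconds to ~1 min each;
- end-to-end looping runs in the test suite and the acceptance script:
  170–200 μm edge (~2k tetrahedra, ~650 nodes, ~400–600 membrane
  triangles), 10 initial + 12 looping increments — a baseline run takes a
  few minutes on one CPU;
- the bending-stiffness consequences of this coarseness are quantified by
  the bilayer problem and discussed below.

## Known limitations

- The geometry is idealized; quantitative agreement with any individual
  embryo (or with image-based meshes) is not expected — trends, signs and
  stage ordering are the comparison currency.
- Linear tetrahedra are bending-stiff; coarse meshes under-bend and hence
  under-rotate.  The bilayer verification problem quantifies this: at an
  element aspect ratio of ~7 (thin shell at desk-scale edge lengths) the
  computed curvature is roughly a quarter of the closed-form value, and
  reaches 97% only after refinement to aspect ~1.  In the looping model
  the myocardial shell is 20 μm thick against 130–200 μm edges, so the
  bending that powers the membrane-driven torsion develops late and the
  lumen rotation angle lags the experimental stage timeline (rightward
  direction and all stress-sign and perturbation-direction trends are
  reproduced; the HH10/HH11 magnitudes are not).
- No endocardium, no fluid pressure, no mechanosensitive feedback, no
  explicit vein-fusion mechanics (surrogate longitudinal growth only), no
  left-right DM proliferation forces.
- Membranes are tension structures without bending stiffness; wrinkling
  is regularised only by the contact smoothing and viscous stabilization.
- The viscous stabilization used to traverse the torsion snap can bias the
  selected branch by a bounded force error (≤ the logged coefficient ×
  step cap); it engages in a minority of increments and the run log
  records every occurrence.
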