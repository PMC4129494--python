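"""Perturbation catalogue: the baseline plus the classic microsurgery and
inhibitor experiments, each encoded as deltas on the baseline model with
machine-checkable qualitative outcomes.

Perturbations follow the model-perturbation protocol: parts are removed
(element deletion plus automatic restoration of statically determinate
supports) at the start of the simulation, process parameters are pinned to
1 to disable a mechanism, and the DM boundary condition variant emulates a
ruptured (free) or intact (full-length rollers) dorsal mesocardium.  All
other parameters stay at their baseline values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import morphogenesis as mg
from .geometry import HeartMesh, Tie
from .measures import (mid_marker_lateral_displacement, rotation_angle,
                       rotation_history)
from .solver import SimulationConfig, Trajectory, run_simulation

__all__ = ["ScenarioConfig", "ScenarioResult", "CATALOGUE", "make_scenario",
           "apply_scenario", "run_scenario", "buckling_metric",
           "bending_deflection", "ov_mean_radius"]

CATALOGUE = (
    "baseline",
    "no_contraction",
    "no_fusion_dm_free",
    "no_fusion_dm_rollers",
    "spl_removed",
    "spl_ct_dm_cut",
    "left_ov_removed",
    "right_ov_removed",
    "both_ovs_removed",
    "ht_removed",
)

# check registry thresholds (conventions of this model, stated here once):
# torsion collapse / abolished rotation = final |alpha| below 50% of the
# baseline HH12 value; buckling = waviness metric above 3x baseline.
TORSION_COLLAPSE_FRACTION = 0.5
BUCKLING_FACTOR = 3.0


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    schedule_overrides: dict = field(default_factory=dict)
    dm_variant: str = "baseline"
    removed_parts: tuple[str, ...] = ()
    cuts: tuple[str, ...] = ()
    expected_outcomes: tuple[str, ...] = ()


@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    alpha: "object"  # rotation-history DataFrame
    checks: dict[str, dict] = field(default_factory=dict)

    @property
    def alpha_final(self) -> float:
        ok = self.alpha.dropna(subset=["alpha_deg"])
        return float(ok.alpha_deg.iloc[-1])

    def alpha_at(self, stage: str) -> float:
        row = self.alpha[self.alpha.stage == stage]
        return float(row.alpha_deg.iloc[0]) if len(row) else float("nan")

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks.values())


def make_scenario(name: str) -> ScenarioConfig:
    """Return the registered scenario (baseline deltas only)."""
    reg = {
        "baseline": ScenarioConfig("baseline", expected_outcomes=("rightward",)),
        "no_contraction": ScenarioConfig(
            "no_contraction", schedule_overrides={"contraction": 1.0},
            expected_outcomes=("loops", "left_ov_diameter_reduced"),
        ),
        "no_fusion_dm_free": ScenarioConfig(
            "no_fusion_dm_free", schedule_overrides={"fusion": 1.0}, dm_variant="free",
            expected_outcomes=("reduced_rotation",),
        ),
        "no_fusion_dm_rollers": ScenarioConfig(
            "no_fusion_dm_rollers", schedule_overrides={"fusion": 1.0},
            dm_variant="rollers_full_length",
            expected_outcomes=("rotation_abolished", "lov_cranial_buckling"),
        ),
        "spl_removed": ScenarioConfig(
            "spl_removed", removed_parts=("SPL",),
            expected_outcomes=("torsion_collapse", "slight_right_bend"),
        ),
        "spl_ct_dm_cut": ScenarioConfig(
            "spl_ct_dm_cut", removed_parts=("SPL",),
            cuts=("CT_transverse", "DM_longitudinal"),
            expected_outcomes=("tilts_right",),
        ),
        "left_ov_removed": ScenarioConfig(
            "left_ov_removed", removed_parts=("SPL", "LOV"),
            expected_outcomes=("leftward",),
        ),
        "right_ov_removed": ScenarioConfig(
            "right_ov_removed", removed_parts=("SPL", "ROV"),
            expected_outcomes=("rightward_direction",),
        ),
        "both_ovs_removed": ScenarioConfig(
            "both_ovs_removed", removed_parts=("SPL", "LOV", "ROV"),
            expected_outcomes=("rightward_direction",),
        ),
        "ht_removed": ScenarioConfig(
            "ht_removed", removed_parts=("SPL", "HT", "CT"),
            expected_outcomes=(),
        ),
    }
    if name not in reg:
        raise KeyError(f"unknown scenario {name!r}; catalogue: {CATALOGUE}")
    return reg[name]


# ---------------------------------------------------------------------------
# mesh surgery


def remove_parts(mesh: HeartMesh, parts: tuple[str, ...],
                 cuts: tuple[str, ...] = ()) -> HeartMesh:
    """Delete the elements of the named parts (and cut seams) and rebuild a
    consistent mesh with remapped sets, surfaces and ties."""
    if not parts and not cuts:
        return mesh
    keep_tet = np.ones(len(mesh.tets), dtype=bool)
    keep_tri = np.ones(len(mesh.tris), dtype=bool)
    for part in parts:
        if part in ("SPL", "FG"):
            idx = mesh.tri_sets.get(part, np.array([], dtype=int))
            keep_tri[idx] = False
        elif part in mesh.elem_sets:
            keep_tet[mesh.elem_sets[part]] = False
        else:
            raise KeyError(f"part {part!r} not present in the mesh")
    if "CT_transverse" in cuts and "CT" in mesh.elem_sets and keep_tet[
            mesh.elem_sets["CT"]].any():
        ct = mesh.elem_sets["CT"]
        y = mesh.tet_centroids()[ct][:, 1]
        ymid = 0.5 * (y.min() + y.max())
        width = (mesh.params.target_edge_length if mesh.params else 60.0)
        keep_tet[ct[np.abs(y - ymid) < 0.6 * width]] = False

    kept_tets = mesh.tets[keep_tet]
    kept_tris = mesh.tris[keep_tri]
    used = np.zeros(mesh.n_nodes, dtype=bool)
    used[kept_tets.ravel()] = True
    used[kept_tris.ravel()] = True
    new_id = -np.ones(mesh.n_nodes, dtype=int)
    new_id[used] = np.arange(used.sum())

    tet_newid = -np.ones(len(mesh.tets), dtype=int)
    tet_newid[keep_tet] = np.arange(keep_tet.sum())
    tri_newid = -np.ones(len(mesh.tris), dtype=int)
    tri_newid[keep_tri] = np.arange(keep_tri.sum())

    def remap_nodes(ids):
        ids = np.asarray(ids, dtype=int)
        out = new_id[ids]
        return out[out >= 0]

    node_sets = {k: remap_nodes(v) for k, v in mesh.node_sets.items()}
    node_sets = {k: v for k, v in node_sets.items() if len(v)}
    elem_sets = {}
    for k, v in mesh.elem_sets.items():
        nv = tet_newid[v]
        nv = nv[nv >= 0]
        if len(nv):
            elem_sets[k] = nv
    tri_sets = {}
    for k, v in mesh.tri_sets.items():
        nv = tri_newid[v]
        nv = nv[nv >= 0]
        if len(nv):
            tri_sets[k] = nv
    surfaces = {}
    for k, tris in mesh.surfaces.items():
        ok = used[tris].all(axis=1)
        if ok.any():
            surfaces[k] = new_id[tris[ok]]
    ties = []
    for t in mesh.ties:
        ids = [t.slave, *t.masters]
        if all(used[i] for i in ids):
            ties.append(Tie(int(new_id[t.slave]),
                            tuple(int(new_id[m]) for m in t.masters), t.weights))
    return HeartMesh(
        nodes=mesh.nodes[used].copy(),
        tets=new_id[kept_tets],
        tet_tissue=mesh.tet_tissue[keep_tet],
        tris=new_id[kept_tris],
        tri_tag=mesh.tri_tag[keep_tri],
        node_sets=node_sets,
        elem_sets=elem_sets,
        tri_sets=tri_sets,
        surfaces=surfaces,
        ties=ties,
        params=mesh.params,
        part_axes=dict(mesh.part_axes),
    )


def apply_scenario(scenario: ScenarioConfig, mesh: HeartMesh,
                   schedule: mg.MorphSchedule | None = None,
                   config: SimulationConfig | None = None):
    """Layer the scenario deltas onto the baseline inputs."""
    schedule = schedule or mg.baseline_schedule()
    config = config or SimulationConfig()
    overrides = dict(scenario.schedule_overrides)
    dm_variant = scenario.dm_variant
    if "DM_longitudinal" in scenario.cuts:
        # a longitudinal DM cut severs both the tensioned strip and its
        # foregut anchors
        overrides["dm_tension"] = 1.0
        dm_variant = "free"
    if overrides:
        schedule = schedule.with_overrides(**overrides)
    if dm_variant != config.dm_variant:
        config = replace(config, dm_variant=dm_variant)
    mesh = remove_parts(mesh, scenario.removed_parts, scenario.cuts)
    return mesh, schedule, config


# ---------------------------------------------------------------------------
# derived metrics


def bending_deflection(traj: Trajectory, frame=None, axis: int = 2) -> float:
    """Peak deviation (um) of the HT centroid curve from its end-to-end
    chord, along a global axis (default dorsoventral; axis=0 for lateral)."""
    mesh = traj.mesh
    if "HT" not in mesh.elem_sets or len(mesh.elem_sets["HT"]) == 0:
        return 0.0
    frame = frame or traj.frames[-1]
    ht = mesh.elem_sets["HT"]
    ref_y = mesh.tet_centroids()[ht][:, 1]
    cur = frame.positions[mesh.tets[ht]].mean(axis=1)
    n_bins = 10
    edges = np.linspace(ref_y.min() - 1e-9, ref_y.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(ref_y, edges) - 1, 0, n_bins - 1)
    pts = np.zeros((n_bins, 3))
    cnt = np.zeros(n_bins)
    np.add.at(pts, idx, cur)
    np.add.at(cnt, idx, 1)
    keep = cnt > 0
    pts = pts[keep] / cnt[keep][:, None]
    chord_f = np.linspace(0, 1, len(pts))
    chord = pts[0] + np.outer(chord_f, pts[-1] - pts[0])
    return float(np.max((pts - chord)[:, axis]))


def _ov_strip_nodes(mesh: HeartMesh, part: str, side: str = "cranial",
                    half_angle: float = np.radians(25)):
    origin, d = mesh.part_axes[part]
    surf = mesh.surfaces.get("heart_outer")
    part_nodes = np.unique(mesh.tets[mesh.elem_sets[part]])
    ids = np.intersect1d(np.unique(surf), part_nodes)
    rel = mesh.nodes[ids] - origin
    s = rel @ d
    perp = rel - np.outer(s, d)
    cranial = np.array([0.0, 1.0, 0.0])
    cranial = cranial - (cranial @ d) * d
    cranial /= np.linalg.norm(cranial)
    nr = np.linalg.norm(perp, axis=1)
    cosang = np.einsum("ij,j->i", perp, cranial) / np.maximum(nr, 1e-12)
    ref = 1.0 if side == "cranial" else -1.0
    # widen the strip on coarse meshes until it holds enough nodes for a fit
    for ha in (half_angle, np.radians(40), np.radians(60)):
        sel = cosang * ref > np.cos(ha)
        if sel.sum() >= 8:
            break
    # signed angular offset from the strip midline, for detrending
    lateral = np.cross(d, cranial)
    sinang = np.einsum("ij,j->i", perp, lateral) / np.maximum(nr, 1e-12)
    psi = np.arctan2(sinang[sel], cosang[sel] * ref)
    return ids[sel], s[sel], psi


def buckling_metric(traj: Trajectory, part: str = "LOV", side: str = "cranial",
                    frame=None, order: int = 2) -> float:
    """Waviness (um) of the OV edge strip: peak deviation of the strip's
    *displacement* field from a low-order polynomial trend along the vein
    arc.  Smooth stretching/bending fits the trend; short-wavelength
    buckles do not."""
    mesh = traj.mesh
    if part not in mesh.elem_sets or len(mesh.elem_sets[part]) == 0:
        return 0.0
    frame = frame or traj.frames[-1]
    ids, s, psi = _ov_strip_nodes(mesh, part, side)
    if len(ids) < 8:
        return 0.0
    disp = frame.positions[ids] - traj.reference.positions[ids]
    # smooth trend over arc length AND angular position: removes stretch,
    # bending and torsion of the strip; short-wave buckles remain
    sn = (s - s.mean()) / max(np.ptp(s), 1e-9)
    A = np.column_stack([np.ones_like(sn), sn, sn**2, psi, sn * psi])
    dev = np.zeros(len(ids))
    for c in range(3):
        coef, *_ = np.linalg.lstsq(A, disp[:, c], rcond=None)
        dev += (disp[:, c] - A @ coef) ** 2
    return float(np.sqrt(dev.max()))


def ov_mean_radius(traj: Trajectory, part: str = "LOV", frame=None) -> float:
    """Mean distance of the OV outer-surface nodes from the best-fit vein
    axis in the deformed configuration (diameter proxy)."""
    mesh = traj.mesh
    if part not in mesh.elem_sets or len(mesh.elem_sets[part]) == 0:
        return float("nan")
    frame = frame or traj.frames[-1]
    surf = mesh.surfaces.get("heart_outer")
    part_nodes = np.unique(mesh.tets[mesh.elem_sets[part]])
    ids = np.intersect1d(np.unique(surf), part_nodes)
    x = frame.positions[ids]
    c = x.mean(axis=0)
    d = np.linalg.svd(x - c, full_matrices=False)[2][0]
    perp = (x - c) - np.outer((x - c) @ d, d)
    return float(np.linalg.norm(perp, axis=1).mean())


# ---------------------------------------------------------------------------
# runner


def run_scenario(scenario: ScenarioConfig | str, mesh: HeartMesh,
                 schedule: mg.MorphSchedule | None = None,
                 config: SimulationConfig | None = None,
                 baseline: ScenarioResult | None = None) -> ScenarioResult:
    """Run one scenario and evaluate its registered outcome checks."""
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    m2, sched2, cfg2 = apply_scenario(scenario, mesh, schedule, config)
    try:
        traj = run_simulation(m2, sched2, cfg2)
    except Exception as e:
        raise RuntimeError(f"scenario {scenario.name!r} failed: {e}") from e
    alpha = rotation_history(traj) if "HT" in m2.elem_sets else None
    if alpha is None:
        import pandas as pd

        alpha = pd.DataFrame(columns=["t", "stage", "alpha_deg", "axis_ratio", "reliable"])
    res = ScenarioResult(scenario.name, traj, alpha)
    for check in scenario.expected_outcomes:
        res.checks[check] = _evaluate_check(check, res, baseline)
    return res


def _evaluate_check(check: str, res: ScenarioResult,
                    baseline: ScenarioResult | None) -> dict:
    traj = res.trajectory

    def need_baseline():
        if baseline is None:
            raise ValueError(f"check {check!r} needs the baseline result")
        return baseline

    if check == "rightward":
        a12, a10 = res.alpha_at("HH12"), res.alpha_at("HH10")
        return dict(passed=bool(a12 > 0 and abs(a12) > abs(a10)),
                    value=a12, description="final alpha > 0 and increasing")
    if check == "rightward_direction":
        a12 = res.alpha_final
        return dict(passed=bool(a12 > 0), value=a12, description="final alpha > 0")
    if check == "leftward":
        a12 = res.alpha_final
        return dict(passed=bool(a12 < 0), value=a12, description="final alpha < 0")
    if check == "loops":
        a12 = res.alpha_final
        bend = bending_deflection(traj)
        return dict(passed=bool(abs(a12) > 0 and bend > 0), value=a12,
                    description="|alpha| > 0 with ventral bending present")
    if check == "reduced_rotation":
        b = need_baseline()
        return dict(passed=bool(abs(res.alpha_final) < abs(b.alpha_final)),
                    value=res.alpha_final, description="less rotation than baseline")
    if check in ("torsion_collapse", "rotation_abolished"):
        b = need_baseline()
        thr = TORSION_COLLAPSE_FRACTION * abs(b.alpha_final)
        return dict(passed=bool(abs(res.alpha_final) < thr), value=res.alpha_final,
                    description=f"|alpha| < {TORSION_COLLAPSE_FRACTION} x baseline "
                                f"({thr:.1f} deg)")
    if check == "slight_right_bend":
        lat = bending_deflection(traj, axis=0)
        return dict(passed=bool(lat > 0), value=lat,
                    description="lateral centerline deflection toward the right")
    if check == "tilts_right":
        dx = mid_marker_lateral_displacement(traj)
        return dict(passed=bool(dx > 0), value=dx,
                    description="mid-HT marker displaced rightward")
    if check == "lov_cranial_buckling":
        b = need_baseline()
        m0 = buckling_metric(b.trajectory)
        m1 = buckling_metric(traj)
        return dict(passed=bool(m1 > BUCKLING_FACTOR * m0), value=m1,
                    description=f"LOV cranial waviness > {BUCKLING_FACTOR} x baseline "
                                f"({m0:.2f} um)")
    if check == "left_ov_diameter_reduced":
        b = need_baseline()
        r0 = ov_mean_radius(b.trajectory)
        r1 = ov_mean_radius(traj)
        return dict(passed=bool(r1 < r0), value=r1,
                    description=f"LOV radius below baseline ({r0:.1f} um)")
    raise KeyError(f"unknown outcome check {check!r}")
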