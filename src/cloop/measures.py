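"""Quantification of simulated looping, mirroring the experimental assays.

Rotation is measured exactly as in the embryo experiments: the lumen is
sliced at the middle of the heart tube, the cross-section curve is fitted
with an ellipse, and the rotation angle alpha is the signed angle between
the ellipse long axis and the embryonic dorsoventral axis (positive toward
the embryonic right, range (-90, 90]).

Morphogenetic Lagrangian strains are reported relative to the HH10-
reference state with the uniform fusion elongation removed (fusion adds
material at the caudal end and is invisible to tissue-label tracking), and
are averaged over the experimentally defined regions.  Stress components
are projected on the convected local material frames and classified into
tension / compression / neutral with a dead band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constitutive as ct
from . import morphogenesis as mg
from .solver import Trajectory, TrajectoryFrame

__all__ = ["EllipseFit", "fit_ellipse", "rotation_angle", "rotation_history",
           "morphogenetic_strain", "stress_components", "stress_sign_map",
           "track_markers", "EZZ_REGIONS", "ETT_REGIONS"]

EZZ_REGIONS = ("LHT", "RHT", "VHT", "LOV", "ROV", "LAIP", "RAIP")
ETT_REGIONS = ("HT", "LOV", "ROV")


@dataclass
class EllipseFit:
    center: np.ndarray
    semi_axes: tuple[float, float]  # (major, minor)
    orientation_deg: float  # long axis from dorsoventral axis, + toward right
    reliable: bool = True


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    ``points``: (n, 2) with columns (rightward, ventral) in the section
    plane; needs at least 6 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise ValueError("need at least 6 planar points")
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    sc = max(x.std(), y.std())
    if sc < 1e-12:
        raise ValueError("degenerate point set")
    xs, ys = (x - mx) / sc, (y - my) / sc

    # Fitzgibbon-style constrained fit: minimise |D a| with 4ac - b^2 = 1
    D1 = np.column_stack([xs**2, xs * ys, ys**2])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    C = np.array([[0, 0, 2], [0, -1, 0], [2, 0, 0]], dtype=float)
    T = -np.linalg.solve(S3, S2.T)
    Mred = np.linalg.solve(C, S1 + S2 @ T)
    w, v = np.linalg.eig(Mred)
    cond = 4 * v[0] * v[2] - v[1] ** 2
    good = np.where(np.isreal(w) & (cond > 0))[0]
    if len(good) == 0:
        raise ValueError("no elliptical solution for this point set")
    a1 = np.real(v[:, good[0]])
    a2 = T @ a1
    A, B, Cc = a1
    Dd, E, F = a2

    Q = np.array([[A, B / 2], [B / 2, Cc]])
    evals, evecs = np.linalg.eigh(Q)

    # centre and semi-axes in scaled coordinates
    cen = np.linalg.solve(2 * Q, -np.array([Dd, E]))
    const = F + 0.5 * (Dd * cen[0] + E * cen[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        axes2 = -const / evals
    if np.any(axes2 <= 0):
        raise ValueError("fit degenerated to a non-ellipse")
    major_idx = int(np.argmax(axes2))
    major_dir = evecs[:, major_idx]
    semi = np.sqrt(np.sort(axes2)[::-1])  # [major, minor]

    # orientation relative to the dorsoventral (+eta) axis, toward right (+xi)
    vx, vy = major_dir
    if vy < 0 or (vy == 0 and vx < 0):
        vx, vy = -vx, -vy
    ang = np.degrees(np.arctan2(vx, vy))
    if ang <= -90:
        ang += 180
    elif ang > 90:
        ang -= 180
    ratio = semi[0] / semi[1]
    return EllipseFit(
        center=cen * sc + np.array([mx, my]),
        semi_axes=(float(semi[0] * sc), float(semi[1] * sc)),
        orientation_deg=float(ang),
        reliable=bool(ratio >= 1.05),
    )


def _ht_section_plane(traj: Trajectory, frame: TrajectoryFrame):
    """Mid-HT section: point and normal of the plane orthogonal to the HT
    centroid curve at its arc-length midpoint (current configuration)."""
    mesh = traj.mesh
    ht = mesh.elem_sets["HT"]
    ref_cent = mesh.tet_centroids()[ht]
    cur_cent = frame.positions[mesh.tets[ht]].mean(axis=1)
    vols = np.abs(mesh.tet_volumes()[ht])
    s_ref = ref_cent[:, 1]
    n_bins = max(6, int(round(np.ptp(s_ref) / (mesh.params.target_edge_length
                                               if mesh.params else 60.0))))
    edges = np.linspace(s_ref.min() - 1e-9, s_ref.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(s_ref, edges) - 1, 0, n_bins - 1)
    pts = np.zeros((n_bins, 3))
    wts = np.zeros(n_bins)
    np.add.at(pts, idx, cur_cent * vols[:, None])
    np.add.at(wts, idx, vols)
    keep = wts > 0
    pts = pts[keep] / wts[keep][:, None]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0], np.cumsum(seg)])
    s_mid = arc[-1] / 2
    k = int(np.searchsorted(arc, s_mid))
    k = min(max(k, 1), len(pts) - 1)
    f = (s_mid - arc[k - 1]) / max(arc[k] - arc[k - 1], 1e-12)
    point = (1 - f) * pts[k - 1] + f * pts[k]
    tang = pts[min(k, len(pts) - 1)] - pts[k - 1]
    tang = tang / np.linalg.norm(tang)
    return point, tang


def _slice_surface(positions, tris, point, normal):
    """Intersection points of surface triangles with a plane."""
    d = (positions - point) @ normal
    pts = []
    for tri in tris:
        dv = d[tri]
        if dv.min() > 0 or dv.max() < 0:
            continue
        xs = positions[tri]
        for a in range(3):
            b = (a + 1) % 3
            da, db = dv[a], dv[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                pts.append(xs[a] + t * (xs[b] - xs[a]))
            elif da == 0:
                pts.append(xs[a])
    return np.array(pts)


def rotation_angle(traj: Trajectory, frame: TrajectoryFrame) -> EllipseFit:
    """Alpha at the mid-HT cross section of one trajectory frame."""
    mesh = traj.mesh
    point, normal = _ht_section_plane(traj, frame)
    lum = mesh.surfaces["lumen_surface"]
    # restrict to HT lumen triangles (reference y within the tube)
    ref_c = mesh.nodes[lum].mean(axis=1)
    L = mesh.params.tube_length if mesh.params else ref_c[:, 1].max()
    ht_lum = lum[(ref_c[:, 1] > 0) & (ref_c[:, 1] < L)]
    pts3 = _slice_surface(frame.positions, ht_lum, point, normal)
    if len(pts3) < 6:
        raise ValueError(f"lumen section at t={frame.t} has too few points")
    e_right = np.array([1.0, 0, 0]) - normal[0] * normal
    e_right /= np.linalg.norm(e_right)
    e_dv = np.cross(normal, e_right)
    if e_dv[2] < 0:
        e_dv = -e_dv
    rel = pts3 - point
    pts2 = np.column_stack([rel @ e_right, rel @ e_dv])
    return fit_ellipse(pts2)


def rotation_history(traj: Trajectory) -> pd.DataFrame:
    """Alpha over all stored frames (degrees, signed + toward right)."""
    rows = []
    for fr in traj.frames:
        if fr.t < traj.schedule.t_initial_end - 1e-9:
            continue
        try:
            fit = rotation_angle(traj, fr)
            rows.append(dict(t=fr.t, stage=fr.stage, alpha_deg=fit.orientation_deg,
                             axis_ratio=fit.semi_axes[0] / fit.semi_axes[1],
                             reliable=fit.reliable))
        except ValueError:
            rows.append(dict(t=fr.t, stage=fr.stage, alpha_deg=np.nan,
                             axis_ratio=np.nan, reliable=False))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# strains


def _relative_F(traj: Trajectory, frame: TrajectoryFrame, elem_ids):
    """Deformation gradient of each element relative to the HH10- state."""
    mesh = traj.mesh
    ref = traj.reference
    X = ref.positions[mesh.tets[elem_ids]]
    x = frame.positions[mesh.tets[elem_ids]]
    DX = np.stack([X[:, a] - X[:, 0] for a in (1, 2, 3)], axis=-1)
    dx = np.stack([x[:, a] - x[:, 0] for a in (1, 2, 3)], axis=-1)
    return dx @ np.linalg.inv(DX)


def _fusion_inverse(traj: Trajectory, t: float, elem_ids):
    """Global inverse fusion tensor at time t (identity off the HT)."""
    mesh = traj.mesh
    sched = traj.schedule
    fus = [p for p in sched.processes if p.kind == "fusion"]
    n = len(elem_ids)
    out = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    if not fus:
        return out
    ht_mask = mesh.tet_mask("HT")[elem_ids]
    if not ht_mask.any():
        return out
    # fusion ramps from 1 over the looping step relative to HH10-
    v = mg.ramp_value(fus[0], t, sched)
    Q = traj.frames_field.tet_Q[elem_ids][ht_mask]
    local = np.diag([1.0, 1.0, 1.0 / v])
    out[ht_mask] = np.einsum("nik,kl,njl->nij", Q, local, Q)
    return out


def _region_elements(traj: Trajectory, region: str) -> np.ndarray:
    mesh = traj.mesh
    th = traj.frames_field.theta
    cent = mesh.tet_centroids()
    my = mesh.tet_mask("MY")
    ht_my = mesh.tet_mask("HT") & my
    if region == "HT":
        return np.where(ht_my)[0]
    if region == "VHT":
        return np.where(ht_my & (th >= 2 * np.pi / 3))[0]
    if region == "LHT":
        return np.where(ht_my & (th < 2 * np.pi / 3) & (cent[:, 0] < 0))[0]
    if region == "RHT":
        return np.where(ht_my & (th < 2 * np.pi / 3) & (cent[:, 0] >= 0))[0]
    if region in ("LOV", "ROV"):
        return np.where(mesh.tet_mask(f"{region}_cranial") & my)[0]
    if region in ("LAIP", "RAIP"):
        return np.where(mesh.tet_mask(f"{region[0]}OV_caudal") & my)[0]
    raise KeyError(f"unknown strain region {region!r}")


def morphogenetic_strain(traj: Trajectory, component: str = "EZZ",
                         stages: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Regional Lagrangian strains relative to HH10-, fusion removed.

    ``component``: "EZZ" (longitudinal, seven regions) or "ETT"
    (circumferential, three regions).  Returns a stage x region table.
    """
    if component == "EZZ":
        regions, col = EZZ_REGIONS, 2
    elif component == "ETT":
        regions, col = ETT_REGIONS, 1
    else:
        raise ValueError("component must be 'EZZ' or 'ETT'")
    if stages is None:
        stages = tuple(k for k in traj.schedule.stage_map)
    mesh = traj.mesh
    vols = np.abs(mesh.tet_volumes())
    out = {}
    for stage in stages:
        fr = traj.at_stage(stage)
        row = {}
        for region in regions:
            ids = _region_elements(traj, region)
            if len(ids) == 0:
                import warnings

                warnings.warn(f"strain region {region} has no elements")
                continue
            F_rel = _relative_F(traj, fr, ids)
            F_rep = F_rel @ _fusion_inverse(traj, fr.t, ids)
            E = 0.5 * (np.swapaxes(F_rep, -1, -2) @ F_rep - np.eye(3))
            d = traj.frames_field.tet_Q[ids][:, :, col]
            comp = np.einsum("ni,nij,nj->n", d, E, d)
            row[region] = float(np.average(comp, weights=vols[ids]))
        out[stage] = row
    df = pd.DataFrame(out).T
    df.index.name = "stage"
    return df


# ---------------------------------------------------------------------------
# stresses and markers


def _convected_frames(traj: Trajectory, frame: TrajectoryFrame):
    """Reference triads rotated by the rotation part of F relative to HH10-."""
    ids = np.arange(len(traj.mesh.tets))
    F_rel = _relative_F(traj, frame, ids)
    U, _, Vt = np.linalg.svd(F_rel)
    R = U @ Vt
    det = np.linalg.det(R)
    # guard reflections (should not occur for det F > 0)
    U[det < 0, :, -1] *= -1
    R = U @ Vt
    return R @ traj.frames_field.tet_Q


def stress_components(traj: Trajectory, frame: TrajectoryFrame) -> pd.DataFrame:
    """Per-element longitudinal and circumferential Cauchy stress (Pa)."""
    Q = _convected_frames(traj, frame)
    sig = frame.sigma
    szz = np.einsum("ni,nij,nj->n", Q[:, :, 2], sig, Q[:, :, 2])
    stt = np.einsum("ni,nij,nj->n", Q[:, :, 1], sig, Q[:, :, 1])
    return pd.DataFrame(dict(sigma_zz=szz, sigma_tt=stt))


def stress_sign_map(traj: Trajectory, frame: TrajectoryFrame,
                    dead_band_frac: float = 0.02) -> pd.DataFrame:
    """Classify each element as +1 (tension), -1 (compression) or 0
    (neutral: |sigma| < dead_band_frac * A of its tissue)."""
    df = stress_components(traj, frame)
    A = np.where(traj.mesh.tet_tissue == 0, ct.MYOCARDIUM.A, ct.CARDIAC_JELLY.A)
    for c in ("sigma_zz", "sigma_tt"):
        v = df[c].to_numpy()
        sign = np.where(np.abs(v) < dead_band_frac * A, 0, np.sign(v))
        df[c + "_sign"] = sign.astype(int)
    return df


def track_markers(traj: Trajectory, node_set: str = "ventral_midline_markers") -> pd.DataFrame:
    """Paths of the ventral-midline marker nodes over the trajectory."""
    ids = traj.mesh.node_sets[node_set]
    rows = []
    for fr in traj.frames:
        for rank, n in enumerate(ids):
            x, y, z = fr.positions[n]
            rows.append(dict(t=fr.t, stage=fr.stage, marker=rank, node=int(n),
                             x=x, y=y, z=z))
    return pd.DataFrame(rows)


def mid_marker_lateral_displacement(traj: Trajectory) -> float:
    """Signed x-motion of the marker nearest the HT midpoint (+ = rightward)."""
    ids = traj.mesh.node_sets["ventral_midline_markers"]
    ys = traj.mesh.nodes[ids, 1]
    L = traj.mesh.params.tube_length if traj.mesh.params else ys.max()
    mid = ids[np.argmin(np.abs(ys - L / 2))]
    return float(traj.frames[-1].positions[mid, 0] - traj.reference.positions[mid, 0])
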