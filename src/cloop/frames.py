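"""Local material orientations and regional partitioning.

Every solid element carries an orthonormal triad (e_R, e_Theta, e_Z): e_R is
the weighted average of the exterior and interior surface normals (weights
proportional to the opposite centroid-to-surface distances, so an element
midway through the wall gets the plain mean), e_Z follows the projection of
the cross-sectional centroid curve of its tubular part onto the local wall
plane, and e_Theta = e_Z x e_R completes a right-handed triad.  The
circumferential angle Theta in [0, pi] is measured from the dorsal
mesocardium (Theta = 0) to the ventral midline (Theta = pi), symmetric
between left and right.

Membrane elements get e_R along the surface normal with two arbitrary
orthogonal in-plane vectors (their morphogenesis is isotropic in-plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import HeartMesh, part_of_tets, _closest_point_barycentric

__all__ = ["FrameField", "RegionMap", "compute_local_frames",
           "circumferential_angle", "partition_subregions"]


@dataclass
class FrameField:
    """Per-element triads.  ``tet_Q[i]`` has columns [e_R, e_Theta, e_Z]."""

    tet_Q: np.ndarray
    theta: np.ndarray
    tri_Q: np.ndarray

    def check(self, tol: float = 1e-10) -> None:
        for Q in (self.tet_Q, self.tri_Q):
            if len(Q) == 0:
                continue
            err = np.abs(np.swapaxes(Q, -1, -2) @ Q - np.eye(3)).max()
            if err > tol:
                raise ValueError(f"triads not orthonormal (err {err:.2e})")
            det = np.linalg.det(Q)
            if np.abs(det - 1).max() > 1e3 * tol:
                raise ValueError("triads not right-handed")


@dataclass
class RegionMap:
    """Subregion ids (1..n within the HT, 0 elsewhere) and the effective
    (subregion-averaged) circumferential angle used for morphogenesis."""

    subregion: np.ndarray
    theta_eff: np.ndarray
    n_long: int
    n_circ: int


def _node_normals(nodes, tris, tri_normals):
    """Angle-weighted vertex normals (smooth-surface limit of facet normals;
    exact radial directions on prismatic tube lattices)."""
    acc = np.zeros((len(nodes), 3))
    for a in range(3):
        va = nodes[tris[:, a]]
        e1 = nodes[tris[:, (a + 1) % 3]] - va
        e2 = nodes[tris[:, (a + 2) % 3]] - va
        cosang = np.einsum("ij,ij->i", e1, e2) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(acc, tris[:, a], tri_normals * ang[:, None])
    lens = np.linalg.norm(acc, axis=1)
    lens[lens == 0] = 1.0
    return acc / lens[:, None]


def _surface_distance_and_normal(points, surf_tris, nodes, tree, tri_normals, k=6):
    """Closest distance from each point to a triangulated surface, plus the
    interpolated (vertex-normal) surface normal at the closest point."""
    tc = nodes[surf_tris].mean(axis=1)
    k = min(k, len(tc))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    vn = _node_normals(nodes, surf_tris, tri_normals)
    dists = np.empty(len(points))
    normals = np.empty((len(points), 3))
    for i, (pnt, cs) in enumerate(zip(points, cand)):
        hits = []
        for ti in np.atleast_1d(cs):
            w, d = _closest_point_barycentric(pnt, nodes[surf_tris[ti]])
            hits.append((d, ti, w))
        hits.sort(key=lambda h: h[0])
        d0 = hits[0][0]
        dists[i] = d0
        # blend the interpolated normals of all near-closest candidates:
        # on faceted tubes this suppresses the corner-capture bias of the
        # single closest point
        acc = np.zeros(3)
        for d, ti, w in hits:
            if d > 1.3 * d0 + 1e-9:
                continue
            n = w @ vn[surf_tris[ti]]
            wt = 1.0 / (d + 0.05 * d0 + 1e-9) ** 4
            acc += wt * n / max(np.linalg.norm(n), 1e-12)
        normals[i] = acc / max(np.linalg.norm(acc), 1e-12)
    return dists, normals


def _tri_normals(nodes, tris):
    e1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    e2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    n = np.cross(e1, e2)
    norms = np.linalg.norm(n, axis=1)
    bad = norms < 1e-12
    if bad.any():
        raise ValueError(f"degenerate surface triangle(s): {np.where(bad)[0].tolist()}")
    return n / norms[:, None]


def _centroid_curve_tangent(cent, vols, axis_origin, axis_dir, n_bins=None):
    """Tangent of the cross-sectional centroid curve, interpolated to each
    element (projection parameter = arc length along the part axis)."""
    s = (cent - axis_origin) @ axis_dir
    if n_bins is None:
        n_bins = max(4, int(len(cent) ** (1 / 3)))
    edges = np.linspace(s.min() - 1e-9, s.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    sums = np.zeros((n_bins, 3))
    ws = np.zeros(n_bins)
    np.add.at(sums, idx, cent * vols[:, None])
    np.add.at(ws, idx, vols)
    keep = ws > 0
    pts = sums[keep] / ws[keep][:, None]
    smid = ((edges[:-1] + edges[1:]) / 2)[keep]
    if len(pts) < 2:
        return np.broadcast_to(axis_dir, cent.shape).copy()
    tang_pts = np.gradient(pts, smid, axis=0)
    tang = np.empty_like(cent)
    for c in range(3):
        tang[:, c] = np.interp(s, smid, tang_pts[:, c])
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    return tang


def compute_local_frames(mesh: HeartMesh) -> FrameField:
    """Compute (e_R, e_Theta, e_Z) triads and Theta for every element."""
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        raise ValueError(f"degenerate tetrahedron {int(np.argmin(vols))}")
    cent = mesh.tet_centroids()
    parts = part_of_tets(mesh)

    outer = mesh.surfaces["heart_outer"]
    lumen = mesh.surfaces.get("lumen_wall", mesh.surfaces["lumen_surface"])

    # node -> part map so each element only sees its own part's surfaces
    node_part = np.empty(mesh.n_nodes, dtype="U5")
    for part in np.unique(parts):
        node_part[np.unique(mesh.tets[parts == part])] = part

    theta = np.empty(len(mesh.tets))
    radial = np.empty((len(mesh.tets), 3))
    tangent = np.empty((len(mesh.tets), 3))
    d_out = np.empty(len(mesh.tets))
    d_lum = np.empty(len(mesh.tets))
    nrm_out = np.empty((len(mesh.tets), 3))
    nrm_lum = np.empty((len(mesh.tets), 3))
    for part in np.unique(parts):
        ids = parts == part
        p_outer = outer[np.all(node_part[outer] == part, axis=1)]
        p_lumen = lumen[np.all(node_part[lumen] == part, axis=1)]
        if len(p_outer) == 0 or len(p_lumen) == 0:
            raise ValueError(f"part {part}: missing exterior or lumen surface")
        n_out = _tri_normals(mesh.nodes, p_outer)
        n_lum = _tri_normals(mesh.nodes, p_lumen)
        tree_out = cKDTree(mesh.nodes[p_outer].mean(axis=1))
        tree_lum = cKDTree(mesh.nodes[p_lumen].mean(axis=1))
        d_out[ids], nrm_out[ids] = _surface_distance_and_normal(
            cent[ids], p_outer, mesh.nodes, tree_out, n_out)
        d_lum[ids], nrm_lum[ids] = _surface_distance_and_normal(
            cent[ids], p_lumen, mesh.nodes, tree_lum, n_lum)
        origin, axis = mesh.part_axes.get(part, (None, None))
        if axis is None:
            # fallback for imported meshes: principal axis of the part
            pc = cent[ids] - cent[ids].mean(axis=0)
            axis = np.linalg.svd(pc, full_matrices=False)[2][0]
            origin = cent[ids].mean(axis=0)
        rel = cent[ids] - origin
        rad = rel - np.outer(rel @ axis, axis)
        nr = np.linalg.norm(rad, axis=1)
        if np.any(nr < 1e-9):
            raise ValueError("element centroid on the part axis; cannot orient frame")
        rad /= nr[:, None]
        radial[ids] = rad
        dorsal = np.array([0.0, 0.0, -1.0])
        dorsal = dorsal - (dorsal @ axis) * axis
        dorsal /= np.linalg.norm(dorsal)
        theta[ids] = np.arccos(np.clip(rad @ dorsal, -1.0, 1.0))
        tangent[ids] = _centroid_curve_tangent(cent[ids], vols[ids], origin, axis)

    # orient both surface normals along the outward radial direction, then
    # average weighted by the distance to the *opposite* surface
    sgn_out = np.sign(np.einsum("ij,ij->i", nrm_out, radial))
    sgn_lum = np.sign(np.einsum("ij,ij->i", nrm_lum, radial))
    nrm_out *= np.where(sgn_out == 0, 1, sgn_out)[:, None]
    nrm_lum *= np.where(sgn_lum == 0, 1, sgn_lum)[:, None]
    w_out = d_lum / (d_out + d_lum)
    e_R = w_out[:, None] * nrm_out + (1 - w_out)[:, None] * nrm_lum
    e_R /= np.linalg.norm(e_R, axis=1)[:, None]

    e_Z = tangent - np.einsum("ij,ij->i", tangent, e_R)[:, None] * e_R
    e_Z /= np.linalg.norm(e_Z, axis=1)[:, None]
    e_T = np.cross(e_Z, e_R)
    tet_Q = np.stack([e_R, e_T, e_Z], axis=-1)

    # membranes: normal + arbitrary in-plane pair
    if len(mesh.tris):
        n = _tri_normals(mesh.nodes, mesh.tris)
        ref = np.where(
            np.abs(n[:, 0:1]) < 0.9, np.array([[1.0, 0, 0]]), np.array([[0, 1.0, 0]])
        )
        t1 = np.cross(n, ref)
        t1 /= np.linalg.norm(t1, axis=1)[:, None]
        t2 = np.cross(n, t1)
        tri_Q = np.stack([n, t1, t2], axis=-1)
    else:
        tri_Q = np.zeros((0, 3, 3))

    ff = FrameField(tet_Q=tet_Q, theta=theta, tri_Q=tri_Q)
    ff.check()
    return ff


def circumferential_angle(mesh: HeartMesh, frames: FrameField) -> np.ndarray:
    """Theta in [0, pi] per tetrahedron (zero on the DM, pi ventrally)."""
    return frames.theta


def partition_subregions(
    mesh: HeartMesh, frames: FrameField, n_long: int = 8, n_circ: int = 3
) -> RegionMap:
    """Partition the HT into ``n_long x n_circ`` subregions and average Theta
    per subregion (morphogenetic parameters are applied piecewise-uniformly
    to smooth inter-region stress concentrations)."""
    nt = len(mesh.tets)
    sub = np.zeros(nt, dtype=int)
    theta_eff = frames.theta.copy()
    ht = mesh.elem_sets.get("HT", np.array([], dtype=int))
    if len(ht) == 0:
        return RegionMap(sub, theta_eff, n_long, n_circ)
    origin, axis = mesh.part_axes.get("HEART", (np.zeros(3), np.array([0.0, 1.0, 0.0])))
    cent = mesh.tet_centroids()[ht]
    s = (cent - origin) @ axis
    s_bins = np.clip(
        (np.floor((s - s.min()) / (np.ptp(s) + 1e-9) * n_long)).astype(int), 0, n_long - 1
    )
    t_bins = np.clip(
        (np.floor(frames.theta[ht] / np.pi * n_circ)).astype(int), 0, n_circ - 1
    )
    sub[ht] = s_bins * n_circ + t_bins + 1
    # subregion-averaged theta, volume weighted
    vols = mesh.tet_volumes()[ht]
    for sid in range(1, n_long * n_circ + 1):
        m = sub[ht] == sid
        if not m.any():
            import warnings

            warnings.warn(f"subregion {sid} contains no elements (coarse mesh)")
            continue
        theta_eff[ht[m]] = np.average(frames.theta[ht[m]], weights=vols[m])
    return RegionMap(sub, theta_eff, n_long, n_circ)
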