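"""Idealized HH10- chick heart geometry.

Builds a parametric stand-in for an OCT-reconstructed embryonic heart: a
straight heart tube (myocardial shell around a cardiac-jelly annulus with a
dorsoventrally elongated elliptical lumen), a conotruncus continuing the
tube cranially, two omphalomesenteric-vein branches attached at the caudal
end, a dorsal-mesocardium strip on the dorsal myocardium, and two external
membranes (splanchnopleure ventrally, foregut wall dorsally).

Global axes: +x = embryonic right, +y = cranial, +z = ventral; the dorsal
mesocardium sits at -z so that rightward rotation of the lumen long axis is
a positive angle.  All lengths in micrometres.

The solid parts are structured tube meshes (hexahedral lattices split into
six tetrahedra each, face-conforming); membranes are triangulated planar
sheets.  Parts are mechanically joined by displacement ties (slave node
follows a barycentric point of a master triangle) which carry no force in
the initial configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["GeometryParams", "HeartMesh", "Tie", "build_idealized_heart"]

TISSUES = ("MY", "CJ")
MEMBRANES = ("SPL", "FG")

# 6-tet split of a hexahedron along the main diagonal v0-v6 (local corner
# numbering: bit0 -> +radial, bit1 -> +angular, bit2 -> +longitudinal).
# Identical local patterns on a structured lattice give conforming faces.
_HEX_TETS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7],
])


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the idealized HH10- heart (micrometres, radians).

    Defaults are fixture choices consistent with the ~200 um scale bars of
    published HH10-HH12 micrographs; every value is overridable.
    """

    tube_length: float = 1000.0
    myo_outer_radius: float = 150.0
    myo_thickness: float = 20.0
    lumen_semi_axes: tuple[float, float] = (60.0, 20.0)  # (dorsoventral, lateral)
    ov_left_radius: float = 100.0
    ov_right_radius: float = 100.0
    ov_length: float = 400.0
    ov_angle: float = np.pi / 3  # tilt of each vein from the caudal axis toward lateral
    ct_length: float = 300.0
    dm_angular_width: float = 0.5
    membrane_offset: float = 10.0
    membrane_half_width: float = 450.0
    target_edge_length: float = 60.0
    right_side_elongation: float = 0.03

    def __post_init__(self):
        lengths = dict(
            tube_length=self.tube_length,
            myo_outer_radius=self.myo_outer_radius,
            myo_thickness=self.myo_thickness,
            ov_left_radius=self.ov_left_radius,
            ov_right_radius=self.ov_right_radius,
            ov_length=self.ov_length,
            ct_length=self.ct_length,
            membrane_offset=self.membrane_offset,
            target_edge_length=self.target_edge_length,
        )
        for name, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not self.myo_thickness < self.myo_outer_radius:
            raise ValueError("myocardial shell thicker than its outer radius")
        a_dv, a_lat = self.lumen_semi_axes
        if not (a_dv > 0 and a_lat > 0):
            raise ValueError("lumen semi-axes must be positive")
        r_inner = self.myo_outer_radius - self.myo_thickness
        if max(a_dv, a_lat) >= r_inner:
            raise ValueError(
                f"lumen (semi-axes {self.lumen_semi_axes}) does not fit inside the "
                f"cardiac-jelly annulus (inner myocardial radius {r_inner})"
            )
        if not 0 < self.dm_angular_width < np.pi / 2:
            raise ValueError("dm_angular_width must lie in (0, pi/2)")
        if self.right_side_elongation < 0:
            raise ValueError("right_side_elongation must be >= 0")


@dataclass(frozen=True)
class Tie:
    """Slave node follows the barycentric point of a master triangle."""

    slave: int
    masters: tuple[int, int, int]
    weights: tuple[float, float, float]


@dataclass
class HeartMesh:
    """Nodes, tetrahedral tissue elements, membrane triangles, named sets.

    ``tet_tissue``/``tri_tag`` index into TISSUES / MEMBRANES.  ``node_sets``
    and ``elem_sets`` (tet indices) / ``tri_sets`` (triangle indices) hold the
    anatomical regions.  ``surfaces`` are named triangulated surfaces over
    existing nodes (lumen, heart exterior) used for contact and slicing.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_tissue: np.ndarray
    tris: np.ndarray
    tri_tag: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    elem_sets: dict[str, np.ndarray] = field(default_factory=dict)
    tri_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    ties: list[Tie] = field(default_factory=list)
    params: GeometryParams | None = None
    part_axes: dict[str, tuple] = field(default_factory=dict)

    # -- convenience -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tet_mask(self, name: str) -> np.ndarray:
        m = np.zeros(len(self.tets), dtype=bool)
        if name in self.elem_sets:
            m[self.elem_sets[name]] = True
        return m

    def tri_mask(self, name: str) -> np.ndarray:
        m = np.zeros(len(self.tris), dtype=bool)
        if name in self.tri_sets:
            m[self.tri_sets[name]] = True
        return m

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
            x[:, 3] - x[:, 0],
        ) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def tri_centroids(self) -> np.ndarray:
        return self.nodes[self.tris].mean(axis=1)

    def validate(self) -> None:
        for conn in (self.tets, self.tris):
            if len(conn) and (conn.min() < 0 or conn.max() >= self.n_nodes):
                raise ValueError("element references an invalid node")
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} tetrahedra with non-positive volume")


# ---------------------------------------------------------------------------
# structured tube part


def _ellipse_radius(phi: np.ndarray, a_dv: float, a_lat: float) -> np.ndarray:
    """Polar radius of the lumen ellipse along direction (sin phi, -cos phi)
    in the (lateral, dorsoventral) plane; phi measured from dorsal."""
    return 1.0 / np.sqrt((np.sin(phi) / a_lat) ** 2 + (np.cos(phi) / a_dv) ** 2)


def _tube_part(
    axis_origin: np.ndarray,
    axis_dir: np.ndarray,
    length: float,
    lumen_radius_fn,
    r_inner: float,
    r_outer: float,
    n_ang: int,
    n_len: int,
    n_cj: int,
    n_my: int,
):
    """Structured tube lattice around an axis.

    Angular coordinate phi is measured from the dorsal (-z projected) side.
    Returns nodes (flat), tets, tissue codes and the index lattice
    ``nid[i_len, j_ang, k_rad]`` for set extraction.
    """
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    # dorsal reference perpendicular to the axis
    dorsal = np.array([0.0, 0.0, -1.0])
    dorsal = dorsal - (dorsal @ axis_dir) * axis_dir
    dorsal /= np.linalg.norm(dorsal)
    lateral = np.cross(dorsal, axis_dir)  # completes right-handed (dorsal, lateral, axis)

    phis = 2 * np.pi * np.arange(n_ang) / n_ang
    r_lum = lumen_radius_fn(phis)
    # radial stations: lumen ring, CJ layers to r_inner, MY layers to r_outer
    n_rad = n_cj + n_my + 1
    radii = np.empty((n_ang, n_rad))
    for k in range(n_cj + 1):
        radii[:, k] = r_lum + (r_inner - r_lum) * k / n_cj
    for k in range(1, n_my + 1):
        radii[:, n_cj + k] = r_inner + (r_outer - r_inner) * k / n_my

    ss = length * np.arange(n_len + 1) / n_len
    nodes = np.empty((n_len + 1, n_ang, n_rad, 3))
    ring_dir = (
        np.cos(phis)[:, None] * dorsal[None, :] + np.sin(phis)[:, None] * lateral[None, :]
    )  # (n_ang, 3)
    for i, s in enumerate(ss):
        centre = axis_origin + s * axis_dir
        nodes[i] = centre + radii[:, :, None] * ring_dir[:, None, :]
    nid = np.arange(nodes.size // 3).reshape(n_len + 1, n_ang, n_rad)

    tets = []
    tissue = []
    for i in range(n_len):
        for j in range(n_ang):
            jp = (j + 1) % n_ang
            for k in range(n_rad - 1):
                corners = np.array([
                    nid[i, j, k], nid[i, j, k + 1],
                    nid[i, jp, k], nid[i, jp, k + 1],
                    nid[i + 1, j, k], nid[i + 1, j, k + 1],
                    nid[i + 1, jp, k], nid[i + 1, jp, k + 1],
                ])
                tets.append(corners[_HEX_TETS])
                tissue.extend([0 if k >= n_cj else 1] * 6)  # 0=MY, 1=CJ
    tets = np.concatenate(tets)
    tissue = np.array(tissue, dtype=np.uint8)
    return nodes.reshape(-1, 3), tets, tissue, nid


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    vol = np.einsum(
        "ij,ij->i", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), x[:, 3] - x[:, 0]
    )
    flip = vol < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _quad_tris(a, b, c, d):
    """Two triangles for quad a-b-c-d (consistent diagonal a-c)."""
    return [[a, b, c], [a, c, d]]


def _lattice_surface(nid, k, flip=False):
    """Triangulate the k-th radial shell of a tube lattice (closed around)."""
    n_len, n_ang = nid.shape[0] - 1, nid.shape[1]
    tris = []
    for i in range(n_len):
        for j in range(n_ang):
            jp = (j + 1) % n_ang
            quad = (nid[i, j, k], nid[i, jp, k], nid[i + 1, jp, k], nid[i + 1, j, k])
            if flip:
                quad = quad[::-1]
            tris += _quad_tris(*quad)
    return np.array(tris)


def _end_face_tris(nid, i):
    """Triangulate the annular end face at longitudinal station i."""
    n_ang, n_rad = nid.shape[1], nid.shape[2]
    tris = []
    for j in range(n_ang):
        jp = (j + 1) % n_ang
        for k in range(n_rad - 1):
            tris += _quad_tris(nid[i, j, k], nid[i, jp, k], nid[i, jp, k + 1], nid[i, j, k + 1])
    return np.array(tris)


# ---------------------------------------------------------------------------
# membranes


def _sheet(z, x_lim, y_lim, spacing: float, spacing_x: float | None = None):
    """Membrane sheet; ``z`` is a constant or a profile function z(x, y)
    (used to drape the splanchnopleure over the ventral heart contour)."""
    sx = spacing_x or spacing
    nx = max(4, int(round((x_lim[1] - x_lim[0]) / sx)))
    ny = max(4, int(round((y_lim[1] - y_lim[0]) / spacing)))
    xs = np.linspace(x_lim[0], x_lim[1], nx + 1)
    ys = np.linspace(y_lim[0], y_lim[1], ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = z(X, Y) if callable(z) else np.full_like(X, z)
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    nid = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
    tris = []
    for i in range(nx):
        for j in range(ny):
            tris += _quad_tris(nid[i, j], nid[i + 1, j], nid[i + 1, j + 1], nid[i, j + 1])
    return nodes, np.array(tris), nid


# ---------------------------------------------------------------------------
# tie helpers


def _tie_to_surface(slaves, slave_xyz, surf_tris, nodes, max_dist=None):
    """Tie each slave node to the closest point of a triangulated surface."""
    tc = nodes[surf_tris].mean(axis=1)
    tree = cKDTree(tc)
    ties = []
    for s, x in zip(slaves, slave_xyz):
        _, cand = tree.query(x, k=min(8, len(tc)))
        cand = np.atleast_1d(cand)
        best = None
        for ti in cand:
            tri = surf_tris[ti]
            w, d = _closest_point_barycentric(x, nodes[tri])
            if best is None or d < best[0]:
                best = (d, tri, w)
        d, tri, w = best
        if max_dist is not None and d > max_dist:
            continue
        ties.append(Tie(int(s), tuple(int(t) for t in tri), tuple(float(v) for v in w)))
    return ties


def _closest_point_barycentric(p, tri_xyz):
    """Barycentric weights of the point of triangle tri_xyz closest to p."""
    a, b, c = tri_xyz
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        w = np.array([1.0, 0.0, 0.0])
    else:
        bp = p - b
        d3, d4 = ab @ bp, ac @ bp
        if d3 >= 0 and d4 <= d3:
            w = np.array([0.0, 1.0, 0.0])
        else:
            vc = d1 * d4 - d3 * d2
            if vc <= 0 and d1 >= 0 and d3 <= 0:
                v = d1 / (d1 - d3)
                w = np.array([1 - v, v, 0.0])
            else:
                cp = p - c
                d5, d6 = ab @ cp, ac @ cp
                if d6 >= 0 and d5 <= d6:
                    w = np.array([0.0, 0.0, 1.0])
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0 and d2 >= 0 and d6 <= 0:
                        v = d2 / (d2 - d6)
                        w = np.array([1 - v, 0.0, v])
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
                            v = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            w = np.array([0.0, 1 - v, v])
                        else:
                            denom = va + vb + vc
                            v, u = vb / denom, vc / denom
                            w = np.array([1 - v - u, u, v])
    q = w @ tri_xyz
    return w, float(np.linalg.norm(p - q))


# ---------------------------------------------------------------------------
# main builder


def build_idealized_heart(params: GeometryParams | None = None) -> HeartMesh:
    """Generate the idealized HH10- heart with all named anatomical sets."""
    p = params or GeometryParams()
    edge = p.target_edge_length
    r_out = p.myo_outer_radius
    r_in = r_out - p.myo_thickness
    a_dv, a_lat = p.lumen_semi_axes

    n_ang = max(8, int(round(2 * np.pi * r_out / edge)) // 2 * 2)  # even, L/R symmetric
    n_len_ht = max(6, int(round(p.tube_length / edge)))
    n_len_ct = max(2, int(round(p.ct_length / edge)))
    n_cj, n_my = 2, 1

    # ---- heart tube + conotruncus (single conforming lattice along +y)
    total_len = p.tube_length + p.ct_length
    n_len = n_len_ht + n_len_ct
    ht_nodes, ht_tets, ht_tissue, ht_nid = _tube_part(
        np.zeros(3), np.array([0.0, 1.0, 0.0]), total_len,
        lambda phi: _ellipse_radius(phi, a_dv, a_lat),
        r_in, r_out, n_ang, n_len, n_cj, n_my,
    )
    # rescale longitudinal stations so a station sits exactly at y = tube_length
    ys = np.unique(ht_nodes[:, 1])
    ht_stations = np.concatenate([
        np.linspace(0, p.tube_length, n_len_ht + 1),
        p.tube_length + np.linspace(0, p.ct_length, n_len_ct + 1)[1:],
    ])
    remap = dict(zip(np.round(ys, 9), ht_stations))
    ht_nodes[:, 1] = [remap[y] for y in np.round(ht_nodes[:, 1], 9)]

    parts = {"heart": (ht_nodes, ht_tets, ht_tissue, ht_nid)}

    # ---- omphalomesenteric veins
    psi = p.ov_angle
    dirs = {
        "LOV": np.array([-np.sin(psi), -np.cos(psi), 0.0]),
        "ROV": np.array([np.sin(psi), -np.cos(psi), 0.0]),
    }
    ov_origin_off = {}
    ov_meta = {}
    for name, radius in (("LOV", p.ov_left_radius), ("ROV", p.ov_right_radius)):
        d = dirs[name]
        r_in_ov = radius - p.myo_thickness
        lum = 0.3 * radius
        n_ang_ov = max(8, int(round(2 * np.pi * radius / edge)) // 2 * 2)
        n_len_ov = max(3, int(round(p.ov_length / edge)))
        origin = np.array([np.sign(d[0]) * 0.45 * r_out, 0.0, 0.0])
        nodes, tets, tissue, nid = _tube_part(
            origin, d, p.ov_length, lambda phi: np.full_like(phi, lum),
            r_in_ov, radius, n_ang_ov, n_len_ov, n_cj, n_my,
        )
        parts[name] = (nodes, tets, tissue, nid)
        ov_origin_off[name] = origin
        ov_meta[name] = (origin, d)

    # ---- assemble solids with global node numbering
    all_nodes, all_tets, all_tissue = [], [], []
    offsets = {}
    off = 0
    for name, (nodes, tets, tissue, _) in parts.items():
        offsets[name] = off
        all_nodes.append(nodes)
        all_tets.append(tets + off)
        all_tissue.append(tissue)
        off += len(nodes)
    nodes = np.concatenate(all_nodes)
    tets = np.concatenate(all_tets)
    tissue = np.concatenate(all_tissue)

    # slight initial L/R asymmetry: shear that lengthens the right HT wall
    if p.right_side_elongation > 0:
        eps = p.right_side_elongation
        y_eff = np.clip(nodes[:, 1], 0.0, p.tube_length)
        nodes[:, 1] += eps * y_eff * nodes[:, 0] / (2 * r_out)

    tets = _fix_orientation(nodes, tets)

    # ---- part / tissue element sets
    ne_heart = len(parts["heart"][1])
    ne_lov = len(parts["LOV"][1])
    part_of_tet = np.empty(len(tets), dtype="U5")
    part_of_tet[:ne_heart] = "HEART"
    part_of_tet[ne_heart:ne_heart + ne_lov] = "LOV"
    part_of_tet[ne_heart + ne_lov:] = "ROV"

    cent = nodes[tets].mean(axis=1)
    elem_sets: dict[str, np.ndarray] = {}
    heart_ids = np.where(part_of_tet == "HEART")[0]
    elem_sets["HT"] = heart_ids[cent[heart_ids, 1] <= p.tube_length + 1e-9]
    elem_sets["CT"] = heart_ids[cent[heart_ids, 1] > p.tube_length + 1e-9]
    elem_sets["LOV"] = np.where(part_of_tet == "LOV")[0]
    elem_sets["ROV"] = np.where(part_of_tet == "ROV")[0]
    elem_sets["MY"] = np.where(tissue == 0)[0]
    elem_sets["CJ"] = np.where(tissue == 1)[0]

    # DM strip: dorsal myocardial elements of the HT
    phi_ht = np.arctan2(cent[:, 0], -cent[:, 2])  # angle from dorsal, signed toward right
    in_ht_my = np.zeros(len(tets), dtype=bool)
    in_ht_my[elem_sets["HT"]] = True
    in_ht_my &= tissue == 0
    dm_mask = in_ht_my & (np.abs(phi_ht) <= p.dm_angular_width / 2)
    elem_sets["DM"] = np.where(dm_mask)[0]

    # OV cranial/caudal sides: sign of the cranial (+y) offset from the vein axis
    for name in ("LOV", "ROV"):
        origin, d = ov_meta[name]
        ids = elem_sets[name]
        rel = cent[ids] - origin
        rel_ax = rel - np.outer(rel @ d, d)
        cranial = rel_ax[:, 1] > 0
        elem_sets[f"{name}_cranial"] = ids[cranial]
        elem_sets[f"{name}_caudal"] = ids[~cranial]
    elem_sets["AIP"] = np.concatenate([elem_sets["LOV_caudal"], elem_sets["ROV_caudal"]])

    # ---- surfaces (triangulations over solid nodes)
    k_out = n_cj + n_my

    def _orient(tris_arr, origin, axis, outward):
        """Flip windings so normals point radially outward (or inward)."""
        tc = nodes[tris_arr].mean(axis=1)
        nrm = np.cross(
            nodes[tris_arr[:, 1]] - nodes[tris_arr[:, 0]],
            nodes[tris_arr[:, 2]] - nodes[tris_arr[:, 0]],
        )
        rel = tc - origin
        rad = rel - np.outer(rel @ axis, axis)
        dot = np.einsum("ij,ij->i", nrm, rad)
        wrong = (dot < 0) if outward else (dot > 0)
        tris_arr[wrong] = tris_arr[wrong][:, ::-1]
        return tris_arr

    part_axis_of = {
        "heart": (np.zeros(3), np.array([0.0, 1.0, 0.0])),
        "LOV": ov_meta["LOV"],
        "ROV": ov_meta["ROV"],
    }
    lumen_tris, lumen_walls, outer_tris = [], [], []
    end_info = {}
    for name, (pn, pt, pti, nid) in parts.items():
        o = offsets[name]
        origin, axis = part_axis_of[name]
        wall = _orient(_lattice_surface(nid, 0) + o, origin, axis, outward=False)
        lumen_walls.append(wall)
        # cap the lumen tube at both part ends (fan over the convex end ring)
        caps = []
        for i_end, inward in ((0, axis), (-1, -axis)):
            ring = nid[i_end, :, 0] + o
            fan = np.array([[ring[0], ring[j], ring[j + 1]]
                            for j in range(1, len(ring) - 1)])
            nrm = np.cross(
                nodes[fan[0, 1]] - nodes[fan[0, 0]],
                nodes[fan[0, 2]] - nodes[fan[0, 0]],
            )
            if nrm @ inward < 0:
                fan = fan[:, ::-1]
            caps.append(fan)
        lumen_tris.append(np.concatenate([wall, *caps]))
        outer_tris.append(
            _orient(_lattice_surface(nid, nid.shape[2] - 1) + o, origin, axis, outward=True)
        )
        end_info[name] = nid
    lumen_tris = np.concatenate(lumen_tris)
    outer_tris = np.concatenate(outer_tris)

    # lumen_surface is closed (walls + end caps); the wall-only variant is
    # what frames and self-contact should see
    surfaces = {
        "lumen_surface": lumen_tris,
        "lumen_wall": np.concatenate(lumen_walls),
        "heart_outer": outer_tris,
    }

    node_sets: dict[str, np.ndarray] = {}
    node_sets["lumen_surface"] = np.unique(lumen_tris)
    node_sets["heart_outer"] = np.unique(outer_tris)

    hid = end_info["heart"]
    node_sets["CT_end"] = hid[-1].ravel() + offsets["heart"]
    node_sets["HT_caudal_end"] = hid[0].ravel() + offsets["heart"]
    for name in ("LOV", "ROV"):
        node_sets[f"{name}_end"] = end_info[name][-1].ravel() + offsets[name]

    # DM anchor nodes: dorsal strip nodes at the cranial / caudal ends of the HT
    i_ht_top = n_len_ht
    phis = 2 * np.pi * np.arange(n_ang) / n_ang
    phi_signed = np.where(phis > np.pi, phis - 2 * np.pi, phis)
    dm_cols = np.where(np.abs(phi_signed) <= p.dm_angular_width / 2 + np.pi / n_ang + 1e-12)[0]
    node_sets["DM_cranial_end"] = (hid[i_ht_top][dm_cols].ravel() + offsets["heart"])
    node_sets["DM_caudal_end"] = (hid[0][dm_cols].ravel() + offsets["heart"])

    # ventral midline markers: outer-surface nodes nearest phi = pi along the HT
    j_ventral = int(np.argmin(np.abs(phis - np.pi)))
    node_sets["ventral_midline_markers"] = (
        hid[: i_ht_top + 1, j_ventral, k_out] + offsets["heart"]
    )

    # ---- membranes
    z_spl = r_out + p.membrane_offset
    z_fg = -(r_out + p.membrane_offset)
    # sheets must cover the heart throughout looping: the tube lengthens by
    # up to ~60% (fusion x conotruncus growth) and the veins push caudally
    caudal_reach = p.ov_length * np.cos(psi) + max(p.ov_left_radius, p.ov_right_radius)
    y_lim = (-caudal_reach - 0.3 * p.tube_length, total_len + 0.65 * p.tube_length)
    x_lim = (-p.membrane_half_width, p.membrane_half_width)
    mem_spacing = 1.2 * edge

    spl_nodes, spl_tris, spl_nid = _sheet(z_spl, x_lim, y_lim, mem_spacing)
    fg_nodes, fg_tris, fg_nid = _sheet(z_fg, x_lim, y_lim, mem_spacing)
    spl_off = len(nodes)
    fg_off = spl_off + len(spl_nodes)
    nodes = np.concatenate([nodes, spl_nodes, fg_nodes])
    tris = np.concatenate([spl_tris + spl_off, fg_tris + fg_off])
    tri_tag = np.concatenate([
        np.zeros(len(spl_tris), dtype=np.uint8),  # 0 = SPL
        np.ones(len(fg_tris), dtype=np.uint8),  # 1 = FG
    ])
    tri_sets = {
        "SPL": np.arange(len(spl_tris)),
        "FG": np.arange(len(spl_tris), len(spl_tris) + len(fg_tris)),
    }

    # membrane margins: FG fully fixed; SPL fixed except its caudal edge,
    # which attaches to the caudal side of the veins (AIP)
    def _margin(nid_grid, off, skip_caudal):
        edge_ids = set(nid_grid[0, :]) | set(nid_grid[-1, :]) | set(nid_grid[:, -1])
        if not skip_caudal:
            edge_ids |= set(nid_grid[:, 0])
        return np.array(sorted(edge_ids)) + off

    node_sets["SPL_margin"] = _margin(spl_nid, spl_off, skip_caudal=True)
    node_sets["FG_margin"] = _margin(fg_nid, fg_off, skip_caudal=False)

    # ---- ties: OV proximal faces onto the HT caudal end face
    ties: list[Tie] = []
    caudal_face_tris = _end_face_tris(hid, 0) + offsets["heart"]
    for name in ("LOV", "ROV"):
        prox = end_info[name][0].ravel() + offsets[name]
        ties += _tie_to_surface(prox, nodes[prox], caudal_face_tris, nodes)

    # ---- ties: SPL caudal edge wraps onto the caudal OV surface (AIP band)
    ov_outer = []
    for name in ("LOV", "ROV"):
        nid = end_info[name]
        ov_outer.append(_lattice_surface(nid, nid.shape[2] - 1) + offsets[name])
    ov_outer = np.concatenate(ov_outer)
    # caudal-facing OV surface triangles only
    oc = nodes[ov_outer].mean(axis=1)
    caudal_tris = ov_outer[oc[:, 1] < 0]
    # candidate attachment nodes: draped-sheet nodes over the vein region
    spl_ids = np.arange(spl_off, spl_off + len(spl_nodes))
    caudal_candidates = spl_ids[
        (nodes[spl_ids, 1] < 0) & ~np.isin(spl_ids, node_sets["SPL_margin"])
    ]
    aip_ties = _tie_to_surface(
        caudal_candidates, nodes[caudal_candidates], caudal_tris, nodes,
        max_dist=1.5 * max(p.ov_left_radius, p.ov_right_radius),
    )
    ties += aip_ties
    tied_edge = np.array(sorted({t.slave for t in aip_ties}), dtype=int)
    # the sheet's own caudal edge row is plain margin
    node_sets["SPL_margin"] = np.union1d(node_sets["SPL_margin"],
                                         spl_nid[:, 0] + spl_off)
    aip_band = set(tied_edge.tolist())
    for t in aip_ties:
        aip_band.update(t.masters)
    node_sets["AIP_band"] = np.array(sorted(aip_band), dtype=int)

    mesh = HeartMesh(
        nodes=nodes,
        tets=tets,
        tet_tissue=tissue,
        tris=tris,
        tri_tag=tri_tag,
        node_sets=node_sets,
        elem_sets=elem_sets,
        tri_sets=tri_sets,
        surfaces=surfaces,
        ties=ties,
        params=p,
        part_axes={
            "HEART": (np.zeros(3), np.array([0.0, 1.0, 0.0])),
            "LOV": tuple(ov_meta["LOV"]),
            "ROV": tuple(ov_meta["ROV"]),
        },
    )
    mesh.validate()
    return mesh


def part_of_tets(mesh: HeartMesh) -> np.ndarray:
    """Per-tet part label (HEART covers HT+CT)."""
    out = np.empty(len(mesh.tets), dtype="U5")
    out[:] = "HEART"
    out[mesh.tet_mask("LOV")] = "LOV"
    out[mesh.tet_mask("ROV")] = "ROV"
    return out


def region_masks(mesh: HeartMesh) -> dict[str, np.ndarray]:
    """Boolean masks over the combined element list [tets..., tris...] for
    the morphogenesis region selectors."""
    nt, ns = len(mesh.tets), len(mesh.tris)
    n = nt + ns

    def from_tets(name):
        m = np.zeros(n, dtype=bool)
        if name in mesh.elem_sets:
            m[mesh.elem_sets[name]] = True
        return m

    masks = {k: from_tets(k) for k in (
        "HT", "LOV", "ROV", "CT", "MY", "CJ", "DM",
        "LOV_cranial", "ROV_cranial", "LOV_caudal", "ROV_caudal",
    )}
    masks["AIP"] = masks["LOV_caudal"] | masks["ROV_caudal"]
    for name in MEMBRANES:
        m = np.zeros(n, dtype=bool)
        idx = mesh.tri_sets.get(name, np.array([], dtype=int))
        m[nt + idx] = True
        masks[name] = m
    return masks
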