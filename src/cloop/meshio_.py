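"""Mesh interchange: VTK legacy / VTU for visualization, a restricted
Abaqus-INP dialect (*NODE, *ELEMENT type=C3D4/M3D3, *NSET, *ELSET) for
interchange.  Writers emit plain ASCII; the INP reader reports parse errors
with line numbers and reconstructs all named sets."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import MEMBRANES, TISSUES, HeartMesh

__all__ = ["write_mesh", "read_mesh", "write_vtu", "write_vtu_series", "MeshParseError"]


class MeshParseError(ValueError):
    def __init__(self, path, line_no, msg):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


def write_mesh(mesh: HeartMesh, path, format: str | None = None, cell_data=None,
               point_data=None) -> None:
    """Write a mesh as 'inp', 'vtu' or 'vtk' (guessed from the suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "inp":
        _write_inp(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path, cell_data=cell_data, point_data=point_data)
    elif fmt == "vtk":
        _write_vtk_legacy(mesh, path, cell_data=cell_data)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path, format: str | None = None) -> HeartMesh:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "inp":
        return _read_inp(path)
    if fmt == "vtu":
        return _read_vtu(path)
    raise ValueError(f"reading format {fmt!r} is not supported")


# ---------------------------------------------------------------------------
# Abaqus-INP dialect


def _write_inp(mesh: HeartMesh, path: Path) -> None:
    lines = ["*HEADING", "cloop idealized heart mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.17g}, {y:.17g}, {z:.17g}")
    lines.append("*ELEMENT, TYPE=C3D4, ELSET=SOLID")
    for e, conn in enumerate(mesh.tets, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(c) + 1) for c in conn))
    off = len(mesh.tets)
    lines.append("*ELEMENT, TYPE=M3D3, ELSET=SHELL")
    for e, conn in enumerate(mesh.tris, start=1 + off):
        lines.append(f"{e}, " + ", ".join(str(int(c) + 1) for c in conn))

    def emit_ids(ids, base):
        ids = np.asarray(ids, dtype=int) + base
        for k in range(0, len(ids), 12):
            lines.append(", ".join(str(i) for i in ids[k:k + 12]))

    for tag_i, tag in enumerate(TISSUES):
        lines.append(f"*ELSET, ELSET=TISSUE_{tag}")
        emit_ids(np.where(mesh.tet_tissue == tag_i)[0], 1)
    for tag_i, tag in enumerate(MEMBRANES):
        lines.append(f"*ELSET, ELSET=MEMBRANE_{tag}")
        emit_ids(np.where(mesh.tri_tag == tag_i)[0], 1 + off)
    for name, ids in mesh.elem_sets.items():
        lines.append(f"*ELSET, ELSET={name}")
        emit_ids(ids, 1)
    for name, ids in mesh.tri_sets.items():
        lines.append(f"*ELSET, ELSET=TRI_{name}")
        emit_ids(ids, 1 + off)
    for name, ids in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        emit_ids(ids, 1)
    path.write_text("\n".join(lines) + "\n")


def _read_inp(path: Path) -> HeartMesh:
    nodes, node_ids = [], []
    tets, tet_ids = [], []
    tris, tri_ids = [], []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    mode = None
    current = None
    elem_type = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw, *opts = [p.strip() for p in line.split(",")]
            kw = kw.upper()
            opt = {k.strip().upper(): v.strip() for k, _, v in
                   (o.partition("=") for o in opts)}
            if kw == "*NODE":
                mode = "node"
            elif kw == "*ELEMENT":
                elem_type = opt.get("TYPE", "").upper()
                if elem_type not in ("C3D4", "M3D3"):
                    raise MeshParseError(path, ln, f"unsupported element type {elem_type!r}")
                mode = "elem"
            elif kw == "*ELSET":
                if "ELSET" not in opt:
                    raise MeshParseError(path, ln, "*ELSET without ELSET= name")
                current = elsets.setdefault(opt["ELSET"], [])
                mode = "set"
            elif kw == "*NSET":
                if "NSET" not in opt:
                    raise MeshParseError(path, ln, "*NSET without NSET= name")
                current = nsets.setdefault(opt["NSET"], [])
                mode = "set"
            elif kw == "*HEADING":
                mode = "skip"
            else:
                raise MeshParseError(path, ln, f"unsupported keyword {kw}")
            continue
        try:
            vals = [v for v in (p.strip() for p in line.split(",")) if v]
            if mode == "node":
                node_ids.append(int(vals[0]))
                nodes.append([float(v) for v in vals[1:4]])
            elif mode == "elem":
                eid = int(vals[0])
                conn = [int(v) for v in vals[1:]]
                if elem_type == "C3D4":
                    if len(conn) != 4:
                        raise ValueError("C3D4 needs 4 nodes")
                    tet_ids.append(eid)
                    tets.append(conn)
                else:
                    if len(conn) != 3:
                        raise ValueError("M3D3 needs 3 nodes")
                    tri_ids.append(eid)
                    tris.append(conn)
            elif mode == "set":
                current.extend(int(v) for v in vals)
            elif mode == "skip":
                pass
            else:
                raise ValueError("data before any keyword")
        except MeshParseError:
            raise
        except Exception as e:
            raise MeshParseError(path, ln, str(e)) from e

    if not nodes:
        raise MeshParseError(path, 0, "no *NODE block found")
    nid_map = {nid: i for i, nid in enumerate(node_ids)}
    nodes = np.asarray(nodes)
    tets = np.array([[nid_map[c] for c in conn] for conn in tets], dtype=int).reshape(-1, 4)
    tris = np.array([[nid_map[c] for c in conn] for conn in tris], dtype=int).reshape(-1, 3)
    tet_map = {eid: i for i, eid in enumerate(tet_ids)}
    tri_map = {eid: i for i, eid in enumerate(tri_ids)}

    tissue = np.zeros(len(tets), dtype=np.uint8)
    for tag_i, tag in enumerate(TISSUES):
        ids = elsets.pop(f"TISSUE_{tag}", [])
        tissue[[tet_map[e] for e in ids]] = tag_i
    tri_tag = np.zeros(len(tris), dtype=np.uint8)
    for tag_i, tag in enumerate(MEMBRANES):
        ids = elsets.pop(f"MEMBRANE_{tag}", [])
        tri_tag[[tri_map[e] for e in ids]] = tag_i
    elsets.pop("SOLID", None)
    elsets.pop("SHELL", None)

    elem_sets, tri_sets = {}, {}
    for name, ids in elsets.items():
        if name.startswith("TRI_"):
            tri_sets[name[4:]] = np.array(sorted(tri_map[e] for e in ids), dtype=int)
        else:
            try:
                elem_sets[name] = np.array(sorted(tet_map[e] for e in ids), dtype=int)
            except KeyError as e:
                raise MeshParseError(path, 0, f"ELSET {name} references unknown element {e}")
    node_sets = {
        name: np.array(sorted(nid_map[n] for n in ids), dtype=int)
        for name, ids in nsets.items()
    }
    return HeartMesh(
        nodes=nodes, tets=tets, tet_tissue=tissue, tris=tris, tri_tag=tri_tag,
        node_sets=node_sets, elem_sets=elem_sets, tri_sets=tri_sets,
    )


# ---------------------------------------------------------------------------
# VTK / VTU


def _cells_and_types(mesh: HeartMesh):
    cells = [c for c in mesh.tets] + [c for c in mesh.tris]
    types = [10] * len(mesh.tets) + [5] * len(mesh.tris)
    return cells, types


def write_vtu(mesh: HeartMesh, path, cell_data=None, point_data=None,
              positions=None) -> None:
    """ASCII VTU UnstructuredGrid; cell data covers [tets..., tris...]."""
    cells, types = _cells_and_types(mesh)
    xyz = mesh.nodes if positions is None else positions
    cell_data = dict(cell_data or {})
    base = np.concatenate([
        mesh.tet_tissue.astype(int),
        10 + mesh.tri_tag.astype(int),
    ])
    cell_data.setdefault("tissue", base)

    off = np.cumsum([len(c) for c in cells])
    conn = np.concatenate(cells) if cells else np.array([], dtype=int)

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(len(xyz)),
                          NumberOfCells=str(len(cells)))

    def data_array(parent, name, arr, ncomp=None):
        arr = np.asarray(arr)
        attrs = dict(Name=name, format="ascii")
        if np.issubdtype(arr.dtype, np.integer):
            attrs["type"] = "Int64"
        else:
            attrs["type"] = "Float64"
        if ncomp:
            attrs["NumberOfComponents"] = str(ncomp)
        el = ET.SubElement(parent, "DataArray", **attrs)
        flat = arr.reshape(-1)
        el.text = " ".join(
            f"{v:.17g}" if attrs["type"] == "Float64" else str(int(v)) for v in flat
        )

    pts = ET.SubElement(piece, "Points")
    data_array(pts, "Points", xyz, ncomp=3)
    cl = ET.SubElement(piece, "Cells")
    data_array(cl, "connectivity", conn)
    data_array(cl, "offsets", off)
    data_array(cl, "types", np.asarray(types, dtype=int))
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            data_array(pd_el, name, arr, ncomp=arr.shape[1] if arr.ndim > 1 else None)
    cd_el = ET.SubElement(piece, "CellData")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        data_array(cd_el, name, arr, ncomp=arr.shape[1] if arr.ndim > 1 else None)
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtu(path: Path) -> HeartMesh:
    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")

    def get(name):
        for da in piece.iter("DataArray"):
            if da.get("Name") == name:
                return np.fromstring(da.text, sep=" ")
        raise MeshParseError(path, 0, f"missing DataArray {name!r}")

    xyz = get("Points").reshape(-1, 3)
    conn = get("connectivity").astype(int)
    off = get("offsets").astype(int)
    types = get("types").astype(int)
    tets, tris = [], []
    start = 0
    for o, t in zip(off, types):
        cell = conn[start:o]
        start = o
        if t == 10:
            tets.append(cell)
        elif t == 5:
            tris.append(cell)
    tets = np.array(tets, dtype=int).reshape(-1, 4)
    tris = np.array(tris, dtype=int).reshape(-1, 3)
    try:
        tissue_all = get("tissue").astype(int)
        tissue = tissue_all[: len(tets)].astype(np.uint8)
        tri_tag = (tissue_all[len(tets):] - 10).astype(np.uint8)
    except MeshParseError:
        tissue = np.zeros(len(tets), dtype=np.uint8)
        tri_tag = np.zeros(len(tris), dtype=np.uint8)
    return HeartMesh(nodes=xyz, tets=tets, tet_tissue=tissue, tris=tris,
                     tri_tag=tri_tag)


def _write_vtk_legacy(mesh: HeartMesh, path: Path, cell_data=None) -> None:
    cells, types = _cells_and_types(mesh)
    out = ["# vtk DataFile Version 3.0", "cloop heart mesh", "ASCII",
           "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    out += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes]
    total = sum(len(c) + 1 for c in cells)
    out.append(f"CELLS {len(cells)} {total}")
    out += [f"{len(c)} " + " ".join(str(int(v)) for v in c) for c in cells]
    out.append(f"CELL_TYPES {len(cells)}")
    out += [str(t) for t in types]
    cell_data = dict(cell_data or {})
    cell_data.setdefault("tissue", np.concatenate([
        mesh.tet_tissue.astype(int), 10 + mesh.tri_tag.astype(int)
    ]))
    out.append(f"CELL_DATA {len(cells)}")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            out.append(f"SCALARS {name} {kind} 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{v:.17g}" if kind == "double" else str(int(v)) for v in arr]
    path = Path(path)
    path.write_text("\n".join(out) + "\n")


def write_vtu_series(traj, outdir, prefix="frame") -> list[Path]:
    """One VTU per stored trajectory frame with stress fields attached."""
    from .measures import stress_sign_map, stress_components

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    nt, ns = len(traj.mesh.tets), len(traj.mesh.tris)
    for k, fr in enumerate(traj.frames):
        sc = stress_components(traj, fr)
        pad = np.zeros(ns)
        cd = {
            "sigma_zz": np.concatenate([sc.sigma_zz.to_numpy(), pad]),
            "sigma_tt": np.concatenate([sc.sigma_tt.to_numpy(), pad]),
            "theta": np.concatenate([traj.frames_field.theta, pad]),
            "subregion": np.concatenate([
                traj.region_map.subregion, np.zeros(ns, dtype=int)
            ]).astype(int),
        }
        p = outdir / f"{prefix}_{k:03d}.vtu"
        write_vtu(traj.mesh, p, cell_data=cd, positions=fr.positions)
        paths.append(p)
    return paths
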