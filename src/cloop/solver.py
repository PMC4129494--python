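"""Quasi-static nonlinear finite-element engine for growth-driven looping.

Total-Lagrangian formulation on linear tetrahedra (tissue) and constant-
strain membrane triangles (splanchnopleure / foregut) with plane stress
through the membrane thickness.  Morphogenesis enters through the per-
element tensor M(t): the first Piola-Kirchhoff stress relative to the
undeformed reference is

    P = det(M) * F_star . S(C_star) . M^{-T},      F_star = F . M^{-1}

so a body free to follow a compatible M ends stress-free at F = M.

Loading is the pseudo-time ramp of M; each increment is equilibrated by
Newton iteration with an analytic consistent tangent for the solids, a
finite-difference element tangent for the membranes, penalty displacement
ties between parts, and frictionless node-to-triangle penalty contact.
Boundary conditions are imposed by per-node reduction onto allowed motion
subspaces.  Non-converged increments are adaptively subdivided.

An implicit quasi-static solver is used instead of explicit dynamics:
runs are deterministic and require no mass-scaling tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import constitutive as ct
from . import morphogenesis as mg
from .frames import FrameField, RegionMap, compute_local_frames, partition_subregions
from .geometry import (GeometryParams, HeartMesh, region_masks,
                       _closest_point_barycentric)

log = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "TrajectoryFrame", "Trajectory", "run_simulation",
           "build_constraints", "rigid_mode_check", "repair_rigid_modes",
           "assemble_residual"]


@dataclass
class SimulationConfig:
    """Numerical controls for the quasi-static solve (units: Pa, um)."""

    n_increments_initial: int = 10
    n_increments_looping: int = 30
    newton_tol: float = 1e-6
    max_newton_iters: int = 15
    max_cuts: int = 8
    contact_penalty: float | None = None  # Pa/um; default 100*A_MY/myo_thickness
    tie_penalty: float | None = None  # Pa*um per tie; default 30*A_SPL*edge
    max_step: float | None = None  # um; Newton step cap, default 0.5*edge
    stabilization: float = 0.0  # extra diagonal stiffness (Pa*um), equilibrium-neutral
    membrane_thickness: float = 5.0  # um
    output_every: int = 5
    seed: int = 0
    symmetry_break_amplitude: float = 0.0  # um, random kick at looping onset
    dm_variant: str = "baseline"  # baseline | free | rollers_full_length
    lumen_self_contact: bool = True

    def __post_init__(self):
        if self.n_increments_initial < 10 or self.n_increments_looping < 10:
            raise ValueError("need at least 10 increments per step")
        if self.n_increments_looping % 3:
            raise ValueError("looping increments must be divisible by 3 so the "
                             "HH10/HH11 stage times fall on increments")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


@dataclass
class TrajectoryFrame:
    t: float
    stage: str | None
    positions: np.ndarray
    M: np.ndarray
    F: np.ndarray
    F_star: np.ndarray
    sigma: np.ndarray


@dataclass
class Trajectory:
    mesh: HeartMesh
    frames_field: FrameField
    region_map: RegionMap
    schedule: mg.MorphSchedule
    config: SimulationConfig
    frames: list[TrajectoryFrame] = field(default_factory=list)
    log_rows: list[dict] = field(default_factory=list)

    @property
    def reference(self) -> TrajectoryFrame:
        """The HH10- state: reference for all reported strains."""
        t_ref = self.schedule.t_initial_end
        return min(self.frames, key=lambda f: abs(f.t - t_ref))

    def at_stage(self, stage: str) -> TrajectoryFrame:
        t = self.schedule.stage_map[stage]
        f = min(self.frames, key=lambda fr: abs(fr.t - t))
        if abs(f.t - t) > 1e-6 * max(1.0, t):
            raise KeyError(f"no trajectory frame stored at stage {stage} (t={t})")
        return f


# ---------------------------------------------------------------------------
# constraints


def build_constraints(mesh: HeartMesh, dm_variant: str = "baseline") -> list[np.ndarray | None]:
    """Per-node allowed-motion basis (3xk orthonormal columns; None = free).

    The conotruncus and vein ends translate only along their end-face
    normals; the DM cranial anchor rides cranial-caudal rollers, the caudal
    anchor slides in the cranial-lateral plane; membrane margins are fixed.
    """
    allowed: list[np.ndarray | None] = [None] * mesh.n_nodes

    def restrict(node_ids, basis):
        basis = np.atleast_2d(np.asarray(basis, dtype=float))
        B = basis.T if basis.shape[0] != 3 else basis  # columns = allowed dirs
        if B.ndim == 1:
            B = B[:, None]
        for n in np.atleast_1d(node_ids):
            cur = allowed[n]
            if cur is None:
                allowed[n] = B
            else:
                # intersection of subspaces via nullspace of stacked complements
                P1 = cur @ cur.T
                P2 = B @ B.T
                w, v = np.linalg.eigh(P1 @ P2 @ P1)
                keep = w > 1 - 1e-9
                allowed[n] = v[:, keep] if keep.any() else np.zeros((3, 0))

    ey = np.array([[0.0], [1.0], [0.0]])
    exy = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    ns = mesh.node_sets
    if "CT_end" in ns:
        restrict(ns["CT_end"], ey)
    for name in ("LOV", "ROV"):
        key = f"{name}_end"
        if key in ns and name in mesh.part_axes:
            d = np.asarray(mesh.part_axes[name][1], dtype=float)[:, None]
            restrict(ns[key], d)
    if dm_variant == "baseline":
        if "DM_cranial_end" in ns:
            restrict(ns["DM_cranial_end"], ey)
        if "DM_caudal_end" in ns:
            restrict(ns["DM_caudal_end"], exy)
    elif dm_variant == "rollers_full_length":
        dm_nodes = np.unique(mesh.tets[mesh.elem_sets["DM"]]) if "DM" in mesh.elem_sets else []
        restrict(dm_nodes, ey)
    elif dm_variant != "free":
        raise ValueError(f"unknown dm_variant {dm_variant!r}")
    for name in ("SPL_margin", "FG_margin"):
        if name in ns:
            for n in ns[name]:
                allowed[n] = np.zeros((3, 0))
    return allowed


def constraint_matrix(allowed) -> sp.csr_matrix:
    """Sparse basis T with u = T q over the reduced coordinates q."""
    rows, cols, vals = [], [], []
    q = 0
    for n, B in enumerate(allowed):
        if B is None:
            for i in range(3):
                rows.append(3 * n + i)
                cols.append(q)
                vals.append(1.0)
                q += 1
        else:
            for j in range(B.shape[1]):
                for i in range(3):
                    if B[i, j] != 0.0:
                        rows.append(3 * n + i)
                        cols.append(q)
                        vals.append(B[i, j])
                q += 1
    n_nodes = len(allowed)
    return sp.csr_matrix((vals, (rows, cols)), shape=(3 * n_nodes, q))


def _rigid_modes(X: np.ndarray) -> np.ndarray:
    """Six rigid-body modes (unit-normalised) over node coordinates X."""
    c = X.mean(axis=0)
    r = X - c
    modes = []
    for i in range(3):
        m = np.zeros_like(X)
        m[:, i] = 1.0
        modes.append(m)
    for ax in np.eye(3):
        modes.append(np.cross(ax, r))
    return np.array([m / np.linalg.norm(m) for m in modes])


def rigid_mode_check(mesh: HeartMesh, allowed, node_subset=None) -> list[np.ndarray]:
    """Return a basis of the rigid-body modes (including combinations) not
    blocked by the nodal constraints."""
    nodes = np.arange(mesh.n_nodes) if node_subset is None else np.asarray(node_subset)
    X = mesh.nodes[nodes]
    modes = _rigid_modes(X)  # (6, n, 3)
    rows = []
    for local, n in enumerate(nodes):
        B = allowed[n]
        if B is None:
            continue
        # constrained directions = orthogonal complement of the allowed basis
        P = np.eye(3) - (B @ B.T if B.size else np.zeros((3, 3)))
        w, v = np.linalg.eigh(P)
        for j in range(3):
            if w[j] > 0.5:
                d = v[:, j]
                rows.append([d @ modes[k][local] for k in range(6)])
    if not rows:
        return list(modes)
    A = np.array(rows)
    _, s, vt = np.linalg.svd(A, full_matrices=True)
    s = np.concatenate([s, np.zeros(6 - len(s))]) if len(s) < 6 else s
    free = []
    for k in range(6):
        if k >= len(s) or s[k] < 1e-8:
            combo = np.einsum("k,kni->ni", vt[k], modes)
            free.append(combo / np.linalg.norm(combo))
    return free


def _components(mesh: HeartMesh) -> list[np.ndarray]:
    """Connected components of the node graph (solids + membranes + ties)."""
    import scipy.sparse.csgraph as csgraph

    n = mesh.n_nodes
    rows, cols = [], []
    for conn in (mesh.tets, mesh.tris):
        for e in range(conn.shape[1] - 1):
            rows.extend(conn[:, e])
            cols.extend(conn[:, e + 1])
    for tie in mesh.ties:
        rows.append(tie.slave)
        cols.append(tie.masters[0])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = csgraph.connected_components(adj + adj.T, directed=False)
    return [np.where(labels == c)[0] for c in range(ncomp)]


def repair_rigid_modes(mesh: HeartMesh, allowed) -> list[tuple[int, np.ndarray]]:
    """Add minimal single-direction pins until no component has a free
    rigid-body mode.  Returns the (node, direction) pins added."""
    pins = []
    for comp in _components(mesh):
        for _ in range(12):
            free = rigid_mode_check(mesh, allowed, comp)
            if not free:
                break
            mode = free[0]
            # pick the node where the mode is largest in a still-allowed direction
            best = (0.0, None, None)
            for local, n in enumerate(comp):
                B = allowed[n]
                v = mode[local]
                if B is None:
                    mag = np.linalg.norm(v)
                    d = v / mag if mag > 0 else None
                else:
                    if B.shape[1] == 0:
                        continue
                    proj = B.T @ v
                    mag = np.linalg.norm(proj)
                    d = B @ proj / mag if mag > 0 else None
                if mag > best[0]:
                    best = (mag, n, d)
            _, n, d = best
            if n is None:
                break
            B = allowed[n] if allowed[n] is not None else np.eye(3)
            # remove direction d from node n's allowed space
            Bp = B - np.outer(d, d @ B)
            u, s, _ = np.linalg.svd(Bp, full_matrices=False)
            allowed[n] = u[:, s > 1e-9]
            pins.append((n, d))
    return pins


# ---------------------------------------------------------------------------
# element groups


class _TetGroup:
    """All tetrahedra of one material, with precomputed shape gradients."""

    def __init__(self, nodes, tets, mat):
        self.tets = tets
        self.mat = mat
        X = nodes[tets]
        D = np.stack([X[:, a] - X[:, 0] for a in (1, 2, 3)], axis=-1)  # (n,3,3)
        self.vol0 = np.linalg.det(D) / 6.0
        Dinv = np.linalg.inv(D)
        # gradient of shape functions: rows of Dinv for nodes 1..3, node0 = -sum
        g = Dinv  # (n,3,3): g[:,a-1,:] = grad N_a
        g0 = -g.sum(axis=1, keepdims=True)
        self.grad = np.concatenate([g0, g], axis=1)  # (n,4,3)
        idx = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)
        self.dof = idx
        self.rows = np.repeat(idx, 12, axis=1).ravel()
        self.cols = np.tile(idx, (1, 12)).ravel()

    def deformation(self, u):
        ue = u.reshape(-1, 3)[self.tets]  # (n,4,3)
        F = np.eye(3) + np.einsum("nai,naj->nij", ue, self.grad)
        return F

    def piola(self, F, Minv, detM):
        Fst = F @ Minv
        S = ct.pk2_stress(Fst, self.mat)
        P = detM[:, None, None] * Fst @ S @ np.swapaxes(Minv, -1, -2)
        return P, Fst, S

    def force(self, u, Minv, detM):
        F = self.deformation(u)
        J = np.linalg.det(F @ Minv)
        if np.any(J <= 0):
            raise _ElementInversion(int(np.argmin(J)))
        P, _, _ = self.piola(F, Minv, detM)
        f = np.einsum("n,nij,naj->nai", self.vol0, P, self.grad)
        out = np.zeros((u.size // 3, 3))
        np.add.at(out, self.tets.ravel(), f.reshape(-1, 3))
        return out.ravel()

    def stiffness_values(self, u, Minv, detM):
        F = self.deformation(u)
        Fst = F @ Minv
        S = ct.pk2_stress(Fst, self.mat)
        dSdC = ct.material_tangent(Fst, self.mat)
        MiT = np.swapaxes(Minv, -1, -2)
        # A_iJkL = detM [ delta_ik (Minv S Minv^T)_{LJ}
        #                + F*_iP dS_PQRS (Minv_LR F*_kS + Minv_LS F*_kR) Minv_JQ ]
        MSMt = Minv @ S @ MiT  # (n,3,3); note (Minv S M^-T)_{LJ}
        geo = np.einsum("ik,nlj->nijkl", np.eye(3), MSMt)
        dC = np.einsum("npqrs,nlr,nks->npqkl", dSdC, Minv, Fst) + np.einsum(
            "npqrs,nls,nkr->npqkl", dSdC, Minv, Fst
        )
        matl = np.einsum("nip,npqkl,njq->nijkl", Fst, dC, Minv)
        A = detM[:, None, None, None, None] * (geo + matl)
        Ke = np.einsum("n,nijkl,naj,nbl->naibk", self.vol0, A, self.grad, self.grad)
        return Ke.reshape(len(self.tets), 12, 12).ravel()


class _ElementInversion(Exception):
    def __init__(self, elem):
        self.elem = elem
        super().__init__(f"element inversion at element {elem}")


class _TriGroup:
    """Constant-strain membrane triangles under plane stress."""

    def __init__(self, nodes, tris, mat, thickness):
        self.tris = tris
        self.mat = mat
        self.t0 = thickness
        X = nodes[tris]
        self.X = X.copy()
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        n = np.cross(e1, e2)
        a2 = np.linalg.norm(n, axis=1)
        self.area0 = a2 / 2.0
        if np.any(self.area0 < 1e-12):
            raise ValueError("degenerate membrane triangle")
        E1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
        nn = n / a2[:, None]
        E2 = np.cross(nn, E1)
        DX = np.stack(
            [
                np.stack([np.einsum("ij,ij->i", e1, E1), np.einsum("ij,ij->i", e2, E1)], -1),
                np.stack([np.einsum("ij,ij->i", e1, E2), np.einsum("ij,ij->i", e2, E2)], -1),
            ],
            axis=-2,
        )  # (n,2,2)
        self.DXinv = np.linalg.inv(DX)
        idx = (3 * tris[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tris), 9)
        self.dof = idx
        self.rows = np.repeat(idx, 9, axis=1).ravel()
        self.cols = np.tile(idx, (1, 9)).ravel()

    def _edges(self, u):
        x = self.X + u.reshape(-1, 3)[self.tris]
        return x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]

    def force_edges(self, d1, d2, g2, mR):
        """Force conjugates to the edge vectors; g2 = in-plane growth factor,
        mR = thickness morph factor (per element)."""
        Binv = self.DXinv / g2[:, None, None]
        G = np.stack(
            [
                np.stack([np.einsum("ij,ij->i", d1, d1), np.einsum("ij,ij->i", d1, d2)], -1),
                np.stack([np.einsum("ij,ij->i", d1, d2), np.einsum("ij,ij->i", d2, d2)], -1),
            ],
            axis=-2,
        )
        C2 = np.swapaxes(Binv, -1, -2) @ G @ Binv
        c33 = ct.plane_stress_thickness(C2, self.mat, tol=1e-10)
        S2 = _plane_stress_S2(C2, c33, self.mat)
        scale = self.area0 * g2**2 * self.t0 * mR  # intermediate volume
        H = 0.5 * scale[:, None, None] * (Binv @ S2 @ np.swapaxes(Binv, -1, -2))
        f1 = 2 * (H[:, 0, 0, None] * d1 + H[:, 0, 1, None] * d2)
        f2 = 2 * (H[:, 1, 1, None] * d2 + H[:, 0, 1, None] * d1)
        return f1, f2

    def force(self, u, g2, mR):
        d1, d2 = self._edges(u)
        f1, f2 = self.force_edges(d1, d2, g2, mR)
        out = np.zeros((u.size // 3, 3))
        np.add.at(out, self.tris[:, 0], -(f1 + f2))
        np.add.at(out, self.tris[:, 1], f1)
        np.add.at(out, self.tris[:, 2], f2)
        return out.ravel()

    def stiffness_values(self, u, g2, mR, h=1e-4):
        """Element 9x9 tangents by forward differences of the edge forces."""
        d1, d2 = self._edges(u)
        n = len(self.tris)
        base = np.concatenate(self.force_edges(d1, d2, g2, mR), axis=1)  # (n,6)

        Ke = np.zeros((n, 9, 9))
        # d(edge forces)/d(edge dofs): 6x6, then map to 9x9 nodal
        dF = np.zeros((n, 6, 6))
        for which in range(2):
            for c in range(3):
                dd1 = d1.copy()
                dd2 = d2.copy()
                (dd1 if which == 0 else dd2)[:, c] += h
                f = np.concatenate(self.force_edges(dd1, dd2, g2, mR), axis=1)
                dF[:, :, 3 * which + c] = (f - base) / h
        dF = 0.5 * (dF + np.swapaxes(dF, -1, -2))  # symmetrise (hyperelastic)
        # edge dofs e = B x with x = (x1,x2,x3): d1 = x2-x1, d2 = x3-x1
        B = np.zeros((6, 9))
        B[:3, 3:6] = np.eye(3)
        B[:3, 0:3] = -np.eye(3)
        B[3:, 6:9] = np.eye(3)
        B[3:, 0:3] = -np.eye(3)
        Ke = np.einsum("ae,nef,fb->nab", B.T, dF, B)
        return Ke.ravel()


def _plane_stress_S2(C2, c33, mat):
    """In-plane 2nd PK stress of the 3-D law at the plane-stress thickness."""
    i1 = np.trace(C2, axis1=-2, axis2=-1) + c33
    J2 = np.linalg.det(C2) * c33
    J = np.sqrt(J2)
    Jm23 = J ** (-2.0 / 3.0)
    C2inv = np.linalg.inv(C2)
    expo = np.exp(mat.B * (Jm23 * i1 - 3.0))
    I2 = np.eye(2)
    s_iso = (
        2.0 * mat.A * (expo * Jm23)[..., None, None]
        * (I2 - (i1 / 3.0)[..., None, None] * C2inv)
    )
    s_vol = ((J2 - 1.0) / mat.D)[..., None, None] * C2inv
    return s_iso + s_vol


# ---------------------------------------------------------------------------
# contact


@dataclass
class ContactPair:
    name: str
    slaves: np.ndarray  # node ids
    master_tris: np.ndarray  # (m,3) node ids
    penalty: float  # Pa/um
    trib_area: np.ndarray  # per slave, um^2
    one_sided_normal: np.ndarray | None = None  # fixed orientation hint
    orient_toward_axis: bool = False  # flip normals toward the y-axis line
    self_exclude_normals: np.ndarray | None = None  # per-slave reference normals
    max_gap: float = np.inf
    smoothing: float = 2.0  # um; C1 regularisation band around zero gap

    def snapshot(self, x):
        """Freeze the pairing state (partner triangle, weights, normal) at the
        current positions.  During a Newton iteration the state stays fixed so
        the linearised problem (and its line search) is smooth.

        Normals are interpolated vertex normals of the master surface, so the
        contact force field is continuous across facet boundaries even on a
        deformed membrane (no partner-switch force jumps)."""
        from .frames import _node_normals

        mtris = self.master_tris
        tc = x[mtris].mean(axis=1)
        tree = cKDTree(tc)
        e1 = x[mtris[:, 1]] - x[mtris[:, 0]]
        e2 = x[mtris[:, 2]] - x[mtris[:, 0]]
        nrm = np.cross(e1, e2)
        nrm /= np.linalg.norm(nrm, axis=1)[:, None]
        if self.orient_toward_axis:
            tc2 = x[mtris].mean(axis=1)
            toward = -tc2.copy()
            toward[:, 1] = 0.0
            flip = np.einsum("ij,ij->i", nrm, toward) < 0
            nrm[flip] *= -1
        elif self.one_sided_normal is not None:
            flip = nrm @ self.one_sided_normal < 0
            nrm[flip] *= -1
        vn = _node_normals(x, mtris, nrm)
        k = min(6, len(tc))
        _, cand = tree.query(x[self.slaves], k=k)
        cand = np.atleast_2d(cand)
        state = []
        for s_i, s in enumerate(self.slaves):
            xs = x[s]
            best = None
            for ti in np.atleast_1d(cand[s_i]):
                tri = mtris[ti]
                if s in tri:
                    continue
                if self.self_exclude_normals is not None:
                    if self.self_exclude_normals[s_i] @ nrm[ti] > -0.2:
                        continue
                w, d = _closest_point_barycentric(xs, x[tri])
                if best is None or d < best[0]:
                    best = (d, ti, w)
            if best is None:
                continue
            d, ti, w = best
            n = w @ vn[mtris[ti]]
            nl = np.linalg.norm(n)
            n = nrm[ti] if nl < 1e-9 else n / nl
            g = (xs - w @ x[mtris[ti]]) @ n
            # keep pairs within reach of the smoothing band (with margin so
            # the pair can engage during the Newton iteration)
            if g >= 4 * self.smoothing or -g > self.max_gap:
                continue
            state.append((s_i, s, mtris[ti], w, n))
        if not state:
            return None
        return dict(
            kA=self.penalty * self.trib_area[[t[0] for t in state]],
            slave=np.array([t[1] for t in state]),
            tris=np.array([t[2] for t in state]),
            w=np.array([t[3] for t in state]),
            n=np.array([t[4] for t in state]),
        )

    def forces(self, x, K_blocks=None, state=None):
        """Penalty forces (and optional stiffness triplets) at positions x.

        ``state`` is a frozen snapshot (arrays); force evaluation is fully
        vectorised so the Newton line search stays cheap."""
        if state is None:
            state = self.snapshot(x)
        f = np.zeros_like(x)
        if state is None:
            return f
        gs = self.smoothing
        slave, tris, w, n, kA = (state["slave"], state["tris"], state["w"],
                                 state["n"], state["kA"])
        q = np.einsum("ma,mai->mi", w, x[tris])
        g = np.einsum("mi,mi->m", x[slave] - q, n)
        act = (g < gs) & (-g <= self.max_gap)
        if not act.any():
            return f
        g = g[act]
        kA = kA[act]
        nn = n[act]
        h = gs - g
        quad = h < 2 * gs
        fm = np.where(quad, kA * h * h / (4 * gs), kA * (h - gs))
        dfdg = np.where(quad, kA * h / (2 * gs), kA)
        # residual convention: r = dE/dx, so the slave entry is -fm*n
        # (the physical push-back force on the node is +fm*n)
        fs = -fm[:, None] * nn
        np.add.at(f, slave[act], fs)
        for a in range(3):
            np.add.at(f, tris[act, a], -w[act, a, None] * fs)
        if K_blocks is not None:
            nodes = np.column_stack([slave[act], tris[act]])  # (m,4)
            wts = np.column_stack([np.ones(act.sum()), -w[act]])  # (m,4)
            nnT = dfdg[:, None, None] * np.einsum("mi,mj->mij", nn, nn)
            K_blocks.append((nodes, wts, nnT))
        return f


def _build_contact(mesh: HeartMesh, cfg: SimulationConfig, penalty: float):
    pairs = []
    outer = mesh.surfaces.get("heart_outer")
    # the AIP band is tied (adhered), not in frictionless contact: exclude
    # tied nodes from the slave set and tied membrane triangles from the
    # master set, otherwise ties and penalty contact fight at zero gap
    aip = set(mesh.node_sets.get("AIP_band", np.array([], dtype=int)).tolist())
    for t in mesh.ties:
        aip.add(t.slave)
        aip.update(t.masters)
    if outer is not None and len(outer):
        slaves = np.array([n for n in np.unique(outer) if n not in aip], dtype=int)
        area = _trib_areas(mesh, outer, slaves)
        for mem, hint in (("SPL", np.array([0, 0, -1.0])), ("FG", np.array([0, 0, 1.0]))):
            idx = mesh.tri_sets.get(mem)
            if idx is None or len(idx) == 0:
                continue
            mtris = mesh.tris[idx]
            keep = ~np.array([any(n in aip for n in tri) for tri in mtris])
            if not keep.any():
                continue
            pairs.append(ContactPair(
                name=f"heart-{mem}", slaves=slaves, master_tris=mtris[keep],
                penalty=penalty, trib_area=area, orient_toward_axis=True,
                max_gap=5 * mesh.params.myo_thickness if mesh.params else 100.0,
            ))
    lumen = mesh.surfaces.get("lumen_wall", mesh.surfaces.get("lumen_surface"))
    if cfg.lumen_self_contact and lumen is not None and len(lumen):
        slaves = np.unique(lumen)
        area = _trib_areas(mesh, lumen, slaves)
        # reference outward-into-lumen normal per slave node, for excluding
        # same-wall triangles from the self-contact search
        normals = np.zeros((mesh.n_nodes, 3))
        e1 = mesh.nodes[lumen[:, 1]] - mesh.nodes[lumen[:, 0]]
        e2 = mesh.nodes[lumen[:, 2]] - mesh.nodes[lumen[:, 0]]
        nr = np.cross(e1, e2)
        for t, n in zip(lumen, nr):
            for a in t:
                normals[a] += n
        lens = np.linalg.norm(normals[slaves], axis=1)
        lens[lens == 0] = 1.0
        node_n = normals[slaves] / lens[:, None]
        pairs.append(ContactPair(
            name="lumen-self", slaves=slaves, master_tris=lumen,
            penalty=penalty, trib_area=area, self_exclude_normals=node_n,
            max_gap=30.0,
        ))
    return pairs


def _trib_areas(mesh, tris, slaves):
    e1 = mesh.nodes[tris[:, 1]] - mesh.nodes[tris[:, 0]]
    e2 = mesh.nodes[tris[:, 2]] - mesh.nodes[tris[:, 0]]
    a = np.linalg.norm(np.cross(e1, e2), axis=1) / 2
    acc = np.zeros(mesh.n_nodes)
    for t, ar in zip(tris, a):
        acc[t] += ar / 3
    return acc[slaves]


# ---------------------------------------------------------------------------
# ties


def _tie_matrix(mesh: HeartMesh, k_tie: float) -> sp.csr_matrix | None:
    if not mesh.ties:
        return None
    n = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for tie in mesh.ties:
        nodes = [tie.slave, *tie.masters]
        wts = [1.0, *(-np.asarray(tie.weights))]
        for a, wa in zip(nodes, wts):
            for b, wb in zip(nodes, wts):
                for i in range(3):
                    rows.append(3 * a + i)
                    cols.append(3 * b + i)
                    vals.append(k_tie * wa * wb)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# morphogenesis plumbing


def _element_morph(t, schedule, masks, theta_eff, frames, nt):
    """Per-element M (tets: global 3x3) and membrane in-plane factors."""
    diag = mg.total_morphogenesis(t, schedule, masks, theta_eff, Q=None)
    Q = frames.tet_Q
    Mt = np.einsum("nik,nk,njk->nij", Q, diag[:nt], Q)
    mem = diag[nt:]
    g2 = mem[:, 1]  # in-plane isotropic (Theta == Z for membranes)
    mR = mem[:, 0]
    return Mt, g2, mR


def assemble_residual(u, groups, tri_groups, morphs, tie_K, contact_pairs, X,
                      want_K=False, contact_states=None):
    """Global residual (internal + tie + contact forces) and optional stiffness."""
    n = u.size
    r = np.zeros(n)
    vals_list, rows_list, cols_list = [], [], []
    (Mt, Minv, detM), (g2, mR) = morphs
    for grp in groups:
        sel = grp.sel
        r += grp.force(u, Minv[sel], detM[sel])
        if want_K:
            vals_list.append(grp.stiffness_values(u, Minv[sel], detM[sel]))
            rows_list.append(grp.rows)
            cols_list.append(grp.cols)
    for grp in tri_groups:
        sel = grp.sel
        r += grp.force(u, g2[sel], mR[sel])
        if want_K:
            vals_list.append(grp.stiffness_values(u, g2[sel], mR[sel]))
            rows_list.append(grp.rows)
            cols_list.append(grp.cols)
    if tie_K is not None:
        r += tie_K @ u
    x = X + u.reshape(-1, 3)
    K_blocks = [] if want_K else None
    for ip, pair in enumerate(contact_pairs):
        st = contact_states[ip] if contact_states is not None else None
        r += pair.forces(x, K_blocks, state=st).ravel()
    K = None
    if want_K:
        for nodes, wts, nnT in K_blocks:
            m = len(nodes)
            vals = np.einsum("ma,mb,mij->maibj", wts, wts, nnT).reshape(m, 12, 12)
            dof = (3 * nodes[:, :, None] + np.arange(3)).reshape(m, 12)
            rows_list.append(np.repeat(dof, 12, axis=1).ravel())
            cols_list.append(np.tile(dof, (1, 12)).ravel())
            vals_list.append(vals.ravel())
        K = sp.coo_matrix(
            (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
            shape=(n, n),
        ).tocsr()
        if tie_K is not None:
            K = K + tie_K
    return r, K


# ---------------------------------------------------------------------------
# driver


def run_simulation(
    mesh: HeartMesh,
    schedule: mg.MorphSchedule | None = None,
    config: SimulationConfig | None = None,
    masks: dict | None = None,
    frames: FrameField | None = None,
    region_map: RegionMap | None = None,
    materials: dict[str, ct.MaterialParams] | None = None,
    constraints: list | None = None,
) -> Trajectory:
    """Run the two-step looping protocol and return the trajectory."""
    schedule = schedule or mg.baseline_schedule()
    cfg = config or SimulationConfig()
    materials = materials or {}
    mat_my = materials.get("MY", ct.MYOCARDIUM)
    mat_cj = materials.get("CJ", ct.CARDIAC_JELLY)
    mat_mem = materials.get("MEMBRANE", ct.MEMBRANE)
    frames = frames or compute_local_frames(mesh)
    region_map = region_map or partition_subregions(mesh, frames)
    masks = masks or region_masks(mesh)

    nt, ns = len(mesh.tets), len(mesh.tris)
    theta_eff = np.concatenate([region_map.theta_eff, np.zeros(ns)])

    p = mesh.params or GeometryParams()
    penalty = cfg.contact_penalty
    if penalty is None:
        penalty = 100.0 * ct.MYOCARDIUM.A / p.myo_thickness
    k_tie = cfg.tie_penalty
    if k_tie is None:
        k_tie = 30.0 * mat_mem.A * p.target_edge_length
    if cfg.max_step is None:
        cfg = replace(cfg, max_step=0.5 * p.target_edge_length)

    my_ids = np.where(mesh.tet_tissue == 0)[0]
    cj_ids = np.where(mesh.tet_tissue == 1)[0]
    groups = []
    for ids, mat in ((my_ids, mat_my), (cj_ids, mat_cj)):
        if len(ids):
            g = _TetGroup(mesh.nodes, mesh.tets[ids], mat)
            g.sel = ids
            groups.append(g)
    tri_groups = []
    if ns:
        g = _TriGroup(mesh.nodes, mesh.tris, mat_mem, cfg.membrane_thickness)
        g.sel = np.arange(ns)
        tri_groups.append(g)

    if constraints is None:
        allowed = build_constraints(mesh, cfg.dm_variant)
        pins = repair_rigid_modes(mesh, allowed)
        if pins:
            log.info("added %d support pin(s) to remove rigid-body modes", len(pins))
    else:
        allowed = constraints
    T = constraint_matrix(allowed)

    tie_K = _tie_matrix(mesh, k_tie)
    contact_pairs = _build_contact(mesh, cfg, penalty)

    X = mesh.nodes
    u = np.zeros(3 * mesh.n_nodes)
    traj = Trajectory(mesh, frames, region_map, schedule, cfg)

    t0, tl = schedule.step_durations
    times = np.concatenate([
        np.linspace(0, t0, cfg.n_increments_initial + 1),
        t0 + np.linspace(0, tl, cfg.n_increments_looping + 1)[1:],
    ])
    stage_lookup = {round(v, 9): k for k, v in schedule.stage_map.items()}

    rng = np.random.default_rng(cfg.seed)
    stab_ctx = {"visc": 0.0}

    def store(t, u):
        Mt, _, _ = _element_morph(t, schedule, masks, theta_eff, frames, nt)
        Minv = np.linalg.inv(Mt)
        F = np.eye(3)[None].repeat(nt, axis=0)
        sig = np.zeros((nt, 3, 3))
        Fst = F.copy()
        for grp in groups:
            Fg = grp.deformation(u)
            Fs = Fg @ Minv[grp.sel]
            F[grp.sel] = Fg
            Fst[grp.sel] = Fs
            sig[grp.sel] = ct.cauchy_stress(Fs, grp.mat)
        traj.frames.append(TrajectoryFrame(
            t=t, stage=stage_lookup.get(round(t, 9)),
            positions=(X + u.reshape(-1, 3)).copy(),
            M=Mt, F=F, F_star=Fst, sigma=sig,
        ))

    store(0.0, u)
    force_scale = max(ct.MYOCARDIUM.A * p.target_edge_length**2, 1e-6)

    i = 1
    kicked = False
    while i < len(times):
        t_prev = times[i - 1] if i > 0 else 0.0
        t_target = times[i]
        if not kicked and t_target > t0 and cfg.symmetry_break_amplitude > 0:
            u = u + cfg.symmetry_break_amplitude * (
                T @ rng.standard_normal(T.shape[1])
            )
            kicked = True
        ok, u = _advance(
            u, t_prev, t_target, schedule, masks, theta_eff, frames, nt,
            groups, tri_groups, tie_K, contact_pairs, X, T, cfg, force_scale,
            traj.log_rows, ctx=stab_ctx,
            is_stage=round(t_target, 9) in stage_lookup,
        )
        if not ok:
            raise RuntimeError(
                f"failed to converge advancing t={t_prev:.4f}->{t_target:.4f} "
                f"after {cfg.max_cuts} subdivisions"
            )
        is_stage = round(t_target, 9) in stage_lookup
        if is_stage or (i % cfg.output_every == 0) or i == len(times) - 1:
            store(t_target, u)
        i += 1
    return traj


def _advance(u, t_from, t_to, schedule, masks, theta_eff, frames, nt, groups,
             tri_groups, tie_K, contact_pairs, X, T, cfg, force_scale, log_rows,
             depth=0, ctx=None, is_stage=False):
    """Advance from t_from to t_to.  If plain Newton fails (limit point /
    snap-through, e.g. the rightward-torsion bifurcation), traverse the jump
    by dynamic relaxation: iterated viscous solves whose fixed point is a
    genuine equilibrium of the unstabilised problem."""
    if ctx is None:
        ctx = {"visc": 0.0}
    Mt, g2, mR = _element_morph(t_to, schedule, masks, theta_eff, frames, nt)
    Minv = np.linalg.inv(Mt)
    detM = np.linalg.det(Mt)
    morphs = ((Mt, Minv, detM), (g2, mR))

    def solve(u0, visc, u_anchor=None):
        return _newton(u0, morphs, groups, tri_groups, tie_K, contact_pairs,
                       X, T, cfg, force_scale, visc=visc,
                       u0=u0 if u_anchor is None else u_anchor)

    base = 1e-3 * force_scale / max(cfg.max_step or 60.0, 1e-9)

    u_new, converged, iters, res = solve(u, 0.0)
    if converged:
        ctx["visc"] = max(0.0, ctx["visc"] / 4.0)
        if ctx["visc"] < base / 4:
            ctx["visc"] = 0.0
        log.info("t=%.4f iters=%d res=%.2e cuts=%d", t_to, iters, res, depth)
        log_rows.append(dict(t=t_to, iters=iters, residual=res, cuts=depth,
                             stabilized=0.0))
        return True, u_new

    # Dynamic relaxation with a frozen factorization: damped modified-
    # Newton steps u <- u - (K0 + cI)^-1 r(u), refactorised per segment.
    # Each step costs one residual evaluation plus a triangular solve, so
    # snap-through events (the rightward-torsion bifurcation, membrane
    # wrap) are traversed at explicit-solver-like cost while the fixed
    # point remains a genuine equilibrium of the unstabilised problem.
    tol = cfg.newton_tol * force_scale
    accept = 1e3 * tol
    cap = cfg.max_step or 60.0

    def assemble(uu, states, want_K):
        try:
            return assemble_residual(uu, groups, tri_groups, morphs, tie_K,
                                     contact_pairs, X, want_K=want_K,
                                     contact_states=states)
        except (_ElementInversion, ValueError):
            return None, None

    def snap(uu):
        x = X + uu.reshape(-1, 3)
        return [p.snapshot(x) for p in contact_pairs]

    level = max(ctx["visc"], base * 10)
    uk = u.copy()
    total = iters
    best = (np.inf, u)
    n_segments = 60 if is_stage else 30
    for seg in range(n_segments):
        states = snap(uk)
        r, K = assemble(uk, states, True)
        if r is None:
            level *= 10
            uk = best[1].copy()
            continue
        Kq = (T.T @ K @ T).tocsc()
        Kq = Kq + level * sp.identity(Kq.shape[0], format="csc")
        try:
            lu = spla.splu(Kq)
        except RuntimeError:
            level *= 10
            continue
        moved = 0.0
        stalled = False
        for j in range(40):
            rq = T.T @ r
            nrm = np.abs(rq).max()
            if nrm < best[0]:
                best = (nrm, uk.copy())
            if nrm < accept:
                stalled = True
                break
            dq = lu.solve(rq)
            dmax = np.abs(dq).max()
            if dmax > cap:
                dq *= cap / dmax
            u_try = uk - T @ dq
            r_try, _ = assemble(u_try, states, False)
            total += 1
            if r_try is None or np.abs(T.T @ r_try).max() > 3 * nrm + 10 * tol:
                level *= 4
                stalled = True
                break
            moved = max(moved, dmax)
            uk, r = u_try, r_try
        if stalled and np.abs(T.T @ r).max() < accept:
            break
        if not stalled and moved < 1e-4 * cap:
            break
        if not stalled and level > base:
            level = max(level / 2, base)
    # polish / verify at the flow terminus
    u_fin, conv_f, it3, res_f = solve(best[1], 0.0)
    total += it3
    if conv_f:
        ctx["visc"] = level
        log.info("t=%.4f relaxed(c=%.2g) iters=%d res=%.2e", t_to, level,
                 total, res_f)
        log_rows.append(dict(t=t_to, iters=total, residual=res_f, cuts=depth,
                             stabilized=level))
        return True, u_fin
    if best[0] < 1e4 * tol:
        # accept the flow's best state: small bounded force imbalance,
        # relaxed further by subsequent increments
        ctx["visc"] = level
        log.info("t=%.4f flow-accepted(c=%.2g) iters=%d res=%.2e", t_to, level,
                 total, best[0])
        log_rows.append(dict(t=t_to, iters=total, residual=best[0], cuts=depth,
                             stabilized=level))
        return True, best[1]
    if depth >= cfg.max_cuts:
        return False, u
    t_mid = 0.5 * (t_from + t_to)
    ok, u = _advance(u, t_from, t_mid, schedule, masks, theta_eff, frames, nt,
                     groups, tri_groups, tie_K, contact_pairs, X, T, cfg,
                     force_scale, log_rows, depth + 1, ctx, False)
    if not ok:
        return False, u
    return _advance(u, t_mid, t_to, schedule, masks, theta_eff, frames, nt,
                    groups, tri_groups, tie_K, contact_pairs, X, T, cfg,
                    force_scale, log_rows, depth + 1, ctx, is_stage)


def _newton(u, morphs, groups, tri_groups, tie_K, contact_pairs, X, T, cfg,
            force_scale, visc=0.0, u0=None, iters_cap=None, outers_cap=None):
    u = u.copy()
    if u0 is None:
        u0 = u.copy()

    def residual(uu, want_K, states):
        try:
            r, K = assemble_residual(uu, groups, tri_groups, morphs, tie_K,
                                     contact_pairs, X, want_K=want_K,
                                     contact_states=states)
        except (_ElementInversion, ValueError):
            return None, None
        if visc > 0.0:
            r = r + visc * (uu - u0)
            if want_K:
                K = K + visc * sp.identity(K.shape[0], format="csr")
        return r, K

    tol = cfg.newton_tol * force_scale
    inner_cap = iters_cap or cfg.max_newton_iters
    n_outers = outers_cap or 5
    total_it = 0
    res = np.inf
    # outer fixed point over the frozen contact pairing: each inner solve
    # minimises one smooth (C1) frozen-state problem, then the pairing is
    # refreshed; this avoids active-set chatter between Newton iterations
    for outer in range(n_outers):
        x = X + u.reshape(-1, 3)
        states = [p.snapshot(x) for p in contact_pairs]
        r, _ = residual(u, False, states)
        if r is None:
            return u, False, total_it, np.inf
        res = np.abs(T.T @ r).max()
        if res < tol:
            return u, True, total_it, res
        if total_it >= 4 * cfg.max_newton_iters:
            return u, False, total_it, res
        res0 = None
        for it in range(cfg.max_newton_iters):
            total_it += 1
            r, K = residual(u, True, states)
            if r is None:
                return u, False, total_it, np.inf
            rq = T.T @ r
            res = np.abs(rq).max() if rq.size else 0.0
            if res0 is None:
                res0 = res
            if res < 0.5 * tol:
                break
            if res > 1e2 * max(res0, force_scale):
                return u, False, total_it, res  # diverging; give up early
            Kq = (T.T @ K @ T).tocsc()
            if cfg.stabilization > 0:
                Kq = Kq + cfg.stabilization * sp.identity(Kq.shape[0], format="csc")
            try:
                dq = spla.spsolve(Kq, rq)
            except RuntimeError:
                return u, False, total_it, res
            if not np.all(np.isfinite(dq)):
                return u, False, total_it, res
            # trust-region-style cap: near instabilities (membrane wrinkling,
            # conotruncus buckling) the tangent can be near-singular and the
            # raw Newton step enormous; capping keeps the continuation on track
            cap = cfg.max_step or np.inf
            dmax = np.abs(dq).max() if dq.size else 0.0
            if dmax > cap:
                dq = dq * (cap / dmax)
            # backtracking line search on the frozen-state residual norm
            step = 1.0
            best = None
            for _ in range(8):
                u_try = u - step * (T @ dq)
                r_try, _ = residual(u_try, False, states)
                if r_try is not None:
                    nrm = np.abs(T.T @ r_try).max()
                    if best is None or nrm < best[0]:
                        best = (nrm, u_try)
                    if nrm < (1 - 1e-4 * step) * res:
                        break
                step *= 0.5
            if best is None:
                return u, False, total_it, res
            u = best[1]
    x = X + u.reshape(-1, 3)
    states = [p.snapshot(x) for p in contact_pairs]
    r, _ = residual(u, False, states)
    if r is None:
        return u, False, total_it, np.inf
    fres = np.abs(T.T @ r).max()
    # a marginal contact pair switching partner triangles between snapshots
    # can leave a small fixed residual; accept if the frozen-state problem
    # converged and the mismatch is far below the physical force scale
    ok = fres < tol or (res < 0.5 * tol and fres < 1e3 * tol)
    return u, ok, total_it, fres
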