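"""Material-point kernel for growing embryonic cardiac tissue.

The tissues (myocardium, cardiac jelly, splanchnopleure/foregut membranes)
are modelled as isotropic, nearly incompressible pseudoelastic solids with
the exponential strain-energy density

    W = (A/B) * (exp(B*(I1_bar - 3)) - 1) + (1/D) * ((J*^2 - 1)/2 - ln J*)

where ``I1_bar = J*^(-2/3) tr(F*^T F*)`` is the modified first invariant and
``J* = det F*`` the elastic volume ratio.  Growth and active contraction are
prescribed through the morphogenesis tensor ``M`` via the multiplicative
decomposition ``F = F* . M``: only the elastic part ``F*`` generates stress,

    sigma = (1/J*) F* . dW/dE* . F*^T,    E* = (F*^T F* - I)/2.

Units are consistent (Pa for stress moduli, micrometres for lengths).  All
functions broadcast over leading axes so whole element arrays can be pushed
through at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "MYOCARDIUM",
    "CARDIAC_JELLY",
    "MEMBRANE",
    "elastic_part",
    "strain_energy",
    "pk2_stress",
    "cauchy_stress",
    "material_tangent",
    "cauchy_tangent",
    "plane_stress_thickness",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class MaterialParams:
    """Exponential-law constants.

    A : small-strain shear scale (Pa); B : strain-stiffening exponent
    (dimensionless); D : volumetric compliance (1/Pa), i.e. bulk modulus
    scale 1/D.
    """

    A: float
    B: float
    D: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0 and self.D > 0):
            raise ValueError(f"material constants must be positive, got {self}")


# Microindentation-based constants for early chick heart tissue; the
# membranes (splanchnopleure and foregut) are unmeasured and taken twice as
# stiff as myocardium because they are under active tension in vivo.
MYOCARDIUM = MaterialParams(A=13.0, B=0.57, D=0.01)
CARDIAC_JELLY = MaterialParams(A=3.2, B=0.39, D=0.01)
MEMBRANE = MaterialParams(A=26.0, B=0.57, D=0.01)


def elastic_part(F: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Elastic deformation gradient ``F* = F . M^-1``.

    ``M`` defines the local zero-stress state; compatible growth (``F = M``)
    therefore gives ``F* = I`` and zero stress.
    """
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    detM = np.linalg.det(M)
    if np.any(detM <= 0):
        raise ValueError("morphogenesis tensor must have positive determinant")
    return F @ np.linalg.inv(M)


def _invariants(F_star: np.ndarray):
    """Return (C, J, I1, I1_bar) for elastic gradient(s) F_star."""
    F_star = np.asarray(F_star, dtype=float)
    C = np.swapaxes(F_star, -1, -2) @ F_star
    J = np.linalg.det(F_star)
    if np.any(J <= 0):
        raise ValueError("elastic volume ratio J* must be positive")
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I1_bar = J ** (-2.0 / 3.0) * I1
    return C, J, I1, I1_bar


def strain_energy(F_star: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Strain-energy density W(F*) in Pa (energy per unit intermediate volume)."""
    _, J, _, I1_bar = _invariants(F_star)
    iso = mat.A / mat.B * (np.exp(mat.B * (I1_bar - 3.0)) - 1.0)
    vol = (1.0 / mat.D) * ((J**2 - 1.0) / 2.0 - np.log(J))
    return iso + vol


def pk2_stress(F_star: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress ``S = dW/dE*`` in the intermediate frame."""
    C, J, I1, I1_bar = _invariants(F_star)
    Cinv = np.linalg.inv(C)
    Jm23 = J ** (-2.0 / 3.0)
    expo = np.exp(mat.B * (I1_bar - 3.0))
    # S_iso = 2 A e^{B(I1b-3)} J^{-2/3} (I - I1/3 C^-1); S_vol = (J^2-1)/D C^-1
    s_iso = (
        2.0
        * mat.A
        * expo[..., None, None]
        * Jm23[..., None, None]
        * (_I3 - (I1 / 3.0)[..., None, None] * Cinv)
    )
    s_vol = ((J**2 - 1.0) / mat.D)[..., None, None] * Cinv
    return s_iso + s_vol


def cauchy_stress(F_star: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Cauchy stress ``sigma = (1/J*) F* S F*^T`` (Pa)."""
    F_star = np.asarray(F_star, dtype=float)
    S = pk2_stress(F_star, mat)
    J = np.linalg.det(F_star)
    sig = F_star @ S @ np.swapaxes(F_star, -1, -2) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def material_tangent(F_star: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Fourth-order material tangent ``dS/dC`` (minor-symmetrised).

    Returned with index order ``[..., I, J, K, L]`` such that
    ``dS_IJ = (dS/dC)_IJKL dC_KL``.
    """
    C, J, I1, I1_bar = _invariants(F_star)
    Cinv = np.linalg.inv(C)
    Jm23 = J ** (-2.0 / 3.0)
    expo = np.exp(mat.B * (I1_bar - 3.0))

    # Gm = d(I1_bar)/dC
    Gm = Jm23[..., None, None] * (_I3 - (I1 / 3.0)[..., None, None] * Cinv)
    # dCinv_IJKL = -(Cinv_IK Cinv_JL + Cinv_IL Cinv_JK)/2
    dCinv = -0.5 * (
        np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
        + np.einsum("...il,...jk->...ijkl", Cinv, Cinv)
    )
    # dGm/dC
    dGm = (
        -(1.0 / 3.0)
        * Jm23[..., None, None, None, None]
        * np.einsum("...kl,ij->...ijkl", Cinv, _I3)
        - (1.0 / 3.0) * np.einsum("...kl,...ij->...ijkl", Gm, Cinv)
        - (1.0 / 3.0)
        * (Jm23 * I1)[..., None, None, None, None]
        * dCinv
    )
    a_iso = 2.0 * mat.A * expo
    dS_iso = a_iso[..., None, None, None, None] * (
        mat.B * np.einsum("...ij,...kl->...ijkl", Gm, Gm) + dGm
    )
    dS_vol = (1.0 / mat.D) * (
        (J**2)[..., None, None, None, None]
        * np.einsum("...kl,...ij->...ijkl", Cinv, Cinv)
        + (J**2 - 1.0)[..., None, None, None, None] * dCinv
    )
    return dS_iso + dS_vol


def cauchy_tangent(F_star: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """Analytic ``d sigma / d F*`` with index order ``[..., i, j, k, L]``.

    Verifiable against central differences of :func:`cauchy_stress`; used as
    the user-material callback contract ``(F, M, params) -> (sigma, tangent)``.
    """
    F_star = np.asarray(F_star, dtype=float)
    S = pk2_stress(F_star, mat)
    dSdC = material_tangent(F_star, mat)
    J = np.linalg.det(F_star)
    Finv = np.linalg.inv(F_star)
    sig = cauchy_stress(F_star, mat)

    # dC_RS/dF_kL = delta_SL F_kR + delta_RL F_kS
    dS_dF = np.einsum("...ijrs,...kr->...ijks", dSdC, F_star) + np.einsum(
        "...ijrs,...ks->...ijkr", dSdC, F_star
    )  # both terms arranged so the last axis is L: [..., i, j, k, L]

    Jinv = 1.0 / J
    out = (
        # -sigma * F^-1_Lk
        -np.einsum("...ij,...lk->...ijkl", sig, Finv)
        # (1/J) [ delta_ik S_LQ F_jQ + F_iP S_PL delta_jk ]
        + Jinv[..., None, None, None, None]
        * (
            np.einsum("ik,...lq,...jq->...ijkl", _I3, S, F_star)
            + np.einsum("...ip,...pl,jk->...ijkl", F_star, S, _I3)
        )
        # (1/J) F_iP F_jQ dS_PQ/dF_kL
        + Jinv[..., None, None, None, None]
        * np.einsum("...ip,...jq,...pqkl->...ijkl", F_star, F_star, dS_dF)
    )
    return out


def plane_stress_thickness(C2: np.ndarray, mat: MaterialParams, tol: float = 1e-12,
                           max_iter: int = 60) -> np.ndarray:
    """Thickness stretch squared ``c33`` enforcing S_33 = 0 for membranes.

    ``C2``: in-plane right Cauchy-Green 2x2 blocks (leading axes broadcast).
    The full C is ``blockdiag(C2, c33)``; the through-thickness normal stress
    of the 3-D law is driven to zero by scalar Newton iteration.
    """
    C2 = np.asarray(C2, dtype=float)
    lead = C2.shape[:-2]
    i1p = np.trace(C2, axis1=-2, axis2=-1)
    det2 = np.linalg.det(C2)
    if np.any(det2 <= 0):
        raise ValueError("degenerate in-plane deformation (det C2 <= 0)")
    c = np.ones(lead) if lead else np.array(1.0)

    def s33(c33):
        J2 = det2 * c33
        J = np.sqrt(J2)
        I1 = i1p + c33
        Jm23 = J ** (-2.0 / 3.0)
        expo = np.exp(mat.B * (Jm23 * I1 - 3.0))
        s_iso = 2.0 * mat.A * expo * Jm23 * (1.0 - I1 / (3.0 * c33))
        s_vol = (J2 - 1.0) / (mat.D * c33)
        return s_iso + s_vol

    for _ in range(max_iter):
        f = s33(c)
        h = np.maximum(1e-8, 1e-6 * np.abs(c))
        df = (s33(c + h) - s33(c - h)) / (2.0 * h)
        step = f / df
        step = np.clip(step, -0.4 * c, 0.4 * c)
        c = c - step
        if np.all(np.abs(f) < tol * (1.0 / mat.D)):
            break
    return c
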