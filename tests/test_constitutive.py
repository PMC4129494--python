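"""Material-point kernel checks: energy, stress, tangent, plane stress."""

import numpy as np
import pytest

from cloop import constitutive as ct

MATS = {"MY": ct.MYOCARDIUM, "CJ": ct.CARDIAC_JELLY, "SPL": ct.MEMBRANE}


def random_gradients(n, scale=0.15, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.4:
            out.append(F)
    return np.array(out)


def fd_cauchy(F, mat, h=1e-6):
    """Independent oracle: sigma = (1/J) (dW/dF) F^T by central differences."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dF = np.zeros((3, 3))
            dF[i, j] = h
            P[i, j] = (ct.strain_energy(F + dF, mat) - ct.strain_energy(F - dF, mat)) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestElasticPart:
    def test_stress_free_growth(self):
        M = np.diag([1.2, 0.9, 1.5])
        assert np.allclose(ct.elastic_part(M, M), np.eye(3), atol=1e-14)

    def test_identity_growth(self):
        F = np.eye(3) + 0.1 * np.arange(9).reshape(3, 3) / 10
        assert np.allclose(ct.elastic_part(F, np.eye(3)), F)

    def test_reconstruction_residual(self):
        rng = np.random.default_rng(1)
        F = np.eye(3) + 0.2 * rng.standard_normal((4, 3, 3))
        M = np.eye(3) + 0.2 * rng.standard_normal((4, 3, 3))
        M = M @ np.swapaxes(M, -1, -2) / 2 + np.eye(3)  # well-conditioned, det>0
        Fs = ct.elastic_part(F, M)
        res = np.linalg.norm(Fs @ M - F, axis=(-2, -1)) / np.linalg.norm(F, axis=(-2, -1))
        assert res.max() < 1e-12

    def test_singular_M_rejected(self):
        with pytest.raises(ValueError):
            ct.elastic_part(np.eye(3), np.diag([1.0, 0.0, 1.0]))


class TestEnergy:
    @pytest.mark.parametrize("mat", MATS.values(), ids=MATS.keys())
    def test_zero_at_identity(self, mat):
        assert ct.strain_energy(np.eye(3), mat) == pytest.approx(0.0, abs=1e-14)

    def test_pure_dilatation_closed_form(self):
        # lam=1.1 per axis: isochoric term vanishes, volumetric term closed form
        lam = 1.1
        J = lam**3
        mat = ct.MaterialParams(A=13.0, B=0.57, D=0.01)
        W = ct.strain_energy(lam * np.eye(3), mat)
        expected = (1 / 0.01) * ((J**2 - 1) / 2 - np.log(J))
        assert W == pytest.approx(expected, rel=1e-12)

    def test_isochoric_extension_symbolic(self):
        # independent symbolic oracle (sympy) for an isochoric uniaxial stretch
        import sympy as sp

        lam = sp.Rational(13, 10)
        A, B = sp.Rational(13, 1), sp.Rational(57, 100)
        I1 = lam**2 + 2 / lam  # J*=1 so I1_bar = I1
        W_sym = float(A / B * (sp.exp(B * (I1 - 3)) - 1))
        F = np.diag([1.3, 1 / np.sqrt(1.3), 1 / np.sqrt(1.3)])
        assert ct.strain_energy(F, ct.MYOCARDIUM) == pytest.approx(W_sym, rel=1e-10)

    def test_nonpositive_J_rejected(self):
        with pytest.raises(ValueError):
            ct.strain_energy(np.diag([1.0, -1.0, 1.0]), ct.MYOCARDIUM)

    def test_stiffness_ordering(self):
        # same isochoric stretch: membrane stiffer than myocardium stiffer than jelly
        F = np.diag([1.2, 1 / np.sqrt(1.2), 1 / np.sqrt(1.2)])
        W = {k: ct.strain_energy(F, m) for k, m in MATS.items()}
        assert W["SPL"] > W["MY"] > W["CJ"]


class TestCauchyStress:
    @pytest.mark.parametrize("mat", MATS.values(), ids=MATS.keys())
    def test_zero_at_identity(self, mat):
        assert np.abs(ct.cauchy_stress(np.eye(3), mat)).max() == 0.0

    @pytest.mark.parametrize("mat", MATS.values(), ids=MATS.keys())
    def test_finite_difference_consistency(self, mat):
        Fs = random_gradients(100, seed=2)
        sig = ct.cauchy_stress(Fs, mat)
        for F, s in zip(Fs, sig):
            s_fd = fd_cauchy(F, mat)
            assert np.abs(s - s_fd).max() <= 1e-6 * max(1.0, np.abs(s).max())

    def test_pure_dilatation_hydrostatic(self):
        lam = 1.1
        J = lam**3
        mat = ct.MYOCARDIUM
        sig = ct.cauchy_stress(lam * np.eye(3), mat)
        p = (1 / mat.D) * (J - 1 / J)
        assert np.allclose(sig, p * np.eye(3), rtol=1e-12)

    def test_objectivity(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        F = random_gradients(10, seed=4)
        for q, Fi in zip(Rotation.random(10, rng).as_matrix(), F):
            s1 = ct.cauchy_stress(q @ Fi, ct.MYOCARDIUM)
            s2 = q @ ct.cauchy_stress(Fi, ct.MYOCARDIUM) @ q.T
            assert np.abs(s1 - s2).max() < 1e-10 * max(1.0, np.abs(s2).max())

    def test_isochoric_deviatoric_split(self):
        # det=1 deformation: stress trace comes only from the (small) coupling
        # of the A,B term through the push-forward; the 1/D term contributes 0
        F = np.diag([1.3, 1 / 1.3, 1.0])
        mat = ct.MaterialParams(A=13.0, B=0.57, D=1e9)  # kill volumetric term
        sig = ct.cauchy_stress(F, mat)
        assert abs(np.trace(sig)) < 1e-9 * np.abs(sig).max()


class TestTangent:
    def test_minor_symmetries_at_identity(self):
        T = ct.material_tangent(np.eye(3), ct.MYOCARDIUM)
        assert np.allclose(T, np.swapaxes(T, 0, 1), atol=1e-12)
        assert np.allclose(T, np.swapaxes(T, 2, 3), atol=1e-12)
        assert np.allclose(T, np.transpose(T, (2, 3, 0, 1)), atol=1e-10)

    def test_cauchy_tangent_fd_consistency(self):
        Fs = random_gradients(20, seed=5)
        h = 1e-6
        for F in Fs:
            A4 = ct.cauchy_tangent(F, ct.MYOCARDIUM)
            scale = np.abs(A4).max()
            for k in range(3):
                for L in range(3):
                    dF = np.zeros((3, 3))
                    dF[k, L] = h
                    d = (ct.cauchy_stress(F + dF, ct.MYOCARDIUM)
                         - ct.cauchy_stress(F - dF, ct.MYOCARDIUM)) / (2 * h)
                    assert np.abs(A4[:, :, k, L] - d).max() < 1e-5 * scale

    def test_volumetric_stiffness_scales_inverse_D(self):
        F = 1.05 * np.eye(3)
        p1 = ct.cauchy_stress(F, ct.MaterialParams(13.0, 0.57, 0.01))[0, 0]
        p2 = ct.cauchy_stress(F, ct.MaterialParams(13.0, 0.57, 0.001))[0, 0]
        assert p2 / p1 == pytest.approx(10.0, rel=1e-3)


class TestPlaneStress:
    def test_unstretched_is_unit_thickness(self):
        c33 = ct.plane_stress_thickness(np.eye(2), ct.MEMBRANE)
        assert c33 == pytest.approx(1.0, abs=1e-9)

    def test_s33_driven_to_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            L = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
            C2 = L.T @ L
            c33 = ct.plane_stress_thickness(C2, ct.MEMBRANE)
            F = np.zeros((3, 3))
            F[:2, :2] = np.linalg.cholesky(C2).T
            F[2, 2] = np.sqrt(c33)
            sig = ct.cauchy_stress(F, ct.MEMBRANE)
            assert abs(sig[2, 2]) < 1e-6 * max(1.0, np.abs(sig).max())

    def test_biaxial_stretch_thins_membrane(self):
        c33 = ct.plane_stress_thickness(1.2 * np.eye(2), ct.MEMBRANE)
        assert c33 < 1.0
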