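"""Growth-tensor construction, parameter ramps, and tensor composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cloop import morphogenesis as mg


def diag_det(d):
    return np.prod(d, axis=-1)


class TestProcessTensor:
    def test_contraction_is_isovolumetric_at_end_value(self):
        d = mg.process_tensor("contraction", 0.63)
        assert np.allclose(d, [0.63**-2, 0.63, 0.63])
        assert diag_det(d) == pytest.approx(1.0, rel=1e-14)

    @given(st.floats(0.3, 1.0))
    @settings(deadline=None)
    def test_contraction_det_one_for_all_values(self, v):
        assert diag_det(mg.process_tensor("contraction", v)) == pytest.approx(1.0, rel=1e-12)

    def test_differential_growth_ventral_midline(self):
        # at theta=pi the hypertrophy gradient G = 3
        d = mg.process_tensor("differential_growth", 1.3, np.pi)
        assert np.allclose(d, [1.3, 1.3, 3.0 / 1.3**2])
        assert diag_det(d) == pytest.approx(3.0, rel=1e-14)

    @given(st.floats(1.0, 2.0), st.floats(0.0, np.pi))
    @settings(deadline=None)
    def test_differential_growth_det_is_G(self, v, theta):
        d = mg.process_tensor("differential_growth", v, theta)
        assert diag_det(d) == pytest.approx(2 * theta / np.pi + 1, rel=1e-12)

    def test_cell_shape_endpoints(self):
        assert np.allclose(mg.process_tensor("cell_shape", 1.3, 0.0), [1, 1.3, 1 / 1.3])
        assert np.allclose(mg.process_tensor("cell_shape", 1.3, np.pi), [1, 1, 1])

    @given(st.floats(1.0, 2.0), st.floats(0.0, np.pi))
    @settings(deadline=None)
    def test_cell_shape_det_one(self, v, theta):
        assert diag_det(mg.process_tensor("cell_shape", v, theta)) == pytest.approx(1.0, rel=1e-12)

    def test_axial_and_isotropic_forms(self):
        assert np.allclose(mg.process_tensor("fusion", 1.5), [1, 1, 1.5])
        assert np.allclose(mg.process_tensor("dm_tension", 0.8), [1, 1, 0.8])
        assert np.allclose(mg.process_tensor("cj_growth", 1.43), [1.43] * 3)
        assert np.allclose(mg.process_tensor("isotropic_growth", 1.3), [1.3] * 3)

    def test_conotruncus_growth_det_rounds_to_two(self):
        assert round(float(diag_det(mg.process_tensor("isotropic_growth", 1.3)))) == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mg.process_tensor("contraction", -0.5)
        with pytest.raises(ValueError):
            mg.process_tensor("differential_growth", 1.3, 4.0)
        with pytest.raises(ValueError):
            mg.process_tensor("not_a_kind", 1.0)


class TestRamps:
    @pytest.fixture()
    def sched(self):
        return mg.baseline_schedule()

    def proc(self, sched, name):
        return next(p for p in sched.processes if p.name == name)

    def test_contraction_endpoints(self, sched):
        c = self.proc(sched, "contraction")
        assert mg.ramp_value(c, sched.t_initial_end, sched) == pytest.approx(0.9)
        assert mg.ramp_value(c, sched.t_end, sched) == pytest.approx(0.63)

    def test_cj_growth_endpoints(self, sched):
        c = self.proc(sched, "cj_growth")
        assert mg.ramp_value(c, sched.t_initial_end, sched) == pytest.approx(1.1)
        assert mg.ramp_value(c, sched.t_end, sched) == pytest.approx(1.43)

    def test_every_ramp_starts_at_its_step_start_value(self, sched):
        for p in sched.processes:
            assert mg.ramp_value(p, 0.0, sched) == pytest.approx(1.0)
            if p.step == "looping":
                assert mg.ramp_value(p, sched.t_initial_end, sched) == pytest.approx(1.0)
            assert mg.ramp_value(p, sched.t_end, sched) == pytest.approx(p.param_final)

    def test_linear_in_time(self, sched):
        p = self.proc(sched, "differential_growth")
        t0, tl = sched.step_durations
        v = mg.ramp_value(p, t0 + 0.25 * tl, sched)
        assert v == pytest.approx(1.0 + 0.25 * 0.3)

    def test_stage_map_monotone(self, sched):
        times = list(sched.stage_map.values())
        assert times == sorted(times)
        assert sched.stage_map["HH10-"] == sched.t_initial_end
        assert sched.stage_map["HH12"] == sched.t_end


class TestTotalMorphogenesis:
    def masks(self, n, **true_sets):
        keys = ["HT", "LOV", "ROV", "CT", "MY", "CJ", "DM", "AIP",
                "LOV_cranial", "ROV_cranial", "SPL", "FG"]
        m = {k: np.zeros(n, dtype=bool) for k in keys}
        for k, idx in true_sets.items():
            m[k][idx] = True
        return m

    def test_identity_at_time_zero(self):
        sched = mg.baseline_schedule()
        masks = self.masks(3, HT=[0, 1, 2], MY=[0, 1], CJ=[2])
        M = mg.total_morphogenesis(0.0, sched, masks, np.zeros(3),
                                   Q=np.broadcast_to(np.eye(3), (3, 3, 3)))
        assert np.allclose(M, np.eye(3))

    def test_composition_determinant_at_looping_end(self):
        # element exposed to jelly growth, differential growth, cell shape and
        # fusion at theta=pi: det = 1.43^3 * G(pi) * 1 * 1.5 (oracle: multiply
        # the individual factor determinants)
        sched = mg.baseline_schedule()
        masks = self.masks(1, HT=[0], MY=[0], CJ=[0])
        d = mg.total_morphogenesis(sched.t_end, sched, masks, np.array([np.pi]))
        det = diag_det(d)[0]
        assert det == pytest.approx(1.43**3 * 3.0 * 1.0 * 1.5, rel=1e-12)

    def test_order_invariance(self):
        # all factors are diagonal in the shared frame: permuting the process
        # list leaves the product unchanged
        sched = mg.baseline_schedule()
        perm = mg.MorphSchedule(tuple(reversed(sched.processes)), sched.step_durations)
        masks = self.masks(4, HT=[0, 1], MY=[0], CJ=[1], DM=[0], SPL=[2], AIP=[3])
        th = np.array([0.1, 0.5, 0.0, 0.0])
        t = sched.t_initial_end + 0.37
        assert np.allclose(
            mg.total_morphogenesis(t, sched, masks, th),
            mg.total_morphogenesis(t, perm, masks, th),
        )

    def test_rotation_to_global_frame(self):
        # fusion growth along a local e_Z = global x must appear as xx growth
        sched = mg.MorphSchedule((mg.MorphProcess("fusion", 1.5, ("HT",)),))
        masks = self.masks(1, HT=[0])
        Q = np.array([[[0, 0, 1], [0, 1, 0], [-1, 0, 0]]], dtype=float)  # e_Z = +x
        M = mg.total_morphogenesis(sched.t_end, sched, masks, np.zeros(1), Q)
        assert np.allclose(M[0], np.diag([1.5, 1.0, 1.0]))

    def test_continuity_in_time(self):
        sched = mg.baseline_schedule()
        masks = self.masks(2, HT=[0, 1], MY=[0], CJ=[1])
        th = np.array([0.3, 2.0])
        t0 = sched.t_initial_end
        before = mg.total_morphogenesis(t0 - 1e-9, sched, masks, th)
        after = mg.total_morphogenesis(t0 + 1e-9, sched, masks, th)
        assert np.allclose(before, after, atol=1e-6)

    def test_overrides_disable_process(self):
        sched = mg.baseline_schedule().with_overrides(contraction=1.0, fusion=1.0)
        masks = self.masks(2, HT=[0], SPL=[1])
        d = mg.total_morphogenesis(sched.t_end, sched, masks, np.zeros(2))
        assert np.allclose(d[1], 1.0)  # SPL contraction off
        # HT element keeps only the non-fusion HT processes (none: not MY/CJ)
        assert np.allclose(d[0], 1.0)
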