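"""Scenario catalogue: deltas, mesh surgery, metrics, determinism."""

import numpy as np
import pytest

from cloop.morphogenesis import baseline_schedule, ramp_value
from cloop.scenarios import (CATALOGUE, apply_scenario, bending_deflection,
                             buckling_metric, make_scenario, remove_parts,
                             run_scenario)
from cloop.solver import SimulationConfig, run_simulation


class TestMakeScenario:
    def test_catalogue_complete(self):
        for name in CATALOGUE:
            sc = make_scenario(name)
            assert sc.name == name

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            make_scenario("no_such_perturbation")

    def test_baseline_has_no_deltas(self):
        sc = make_scenario("baseline")
        assert not sc.schedule_overrides and not sc.removed_parts
        assert sc.dm_variant == "baseline"

    def test_no_contraction_pins_parameter_everywhere(self, tiny_mesh):
        sc = make_scenario("no_contraction")
        _, sched, _ = apply_scenario(sc, tiny_mesh)
        c = next(p for p in sched.processes if p.kind == "contraction")
        for t in np.linspace(0, sched.t_end, 7):
            assert ramp_value(c, t, sched) == 1.0

    def test_no_fusion_dm_rollers_deltas(self, tiny_mesh):
        sc = make_scenario("no_fusion_dm_rollers")
        _, sched, cfg = apply_scenario(sc, tiny_mesh)
        f = next(p for p in sched.processes if p.kind == "fusion")
        assert f.param_final == 1.0
        assert cfg.dm_variant == "rollers_full_length"

    def test_all_other_parameters_unchanged(self, tiny_mesh):
        sc = make_scenario("no_contraction")
        _, sched, _ = apply_scenario(sc, tiny_mesh)
        base = {p.name: p.param_final for p in baseline_schedule().processes}
        for p in sched.processes:
            if p.kind != "contraction":
                assert p.param_final == base[p.name]


class TestRemoveParts:
    def test_spl_removed(self, tiny_mesh):
        m2 = remove_parts(tiny_mesh, ("SPL",))
        assert "SPL" not in m2.tri_sets
        assert len(m2.tri_sets["FG"]) == len(tiny_mesh.tri_sets["FG"])
        assert len(m2.tets) == len(tiny_mesh.tets)
        assert not any(t for t in m2.ties
                       if m2.nodes[t.slave, 2] > 100)  # AIP ties gone
        m2.validate()

    def test_left_ov_removed(self, tiny_mesh):
        m2 = remove_parts(tiny_mesh, ("SPL", "LOV"))
        assert "LOV" not in m2.elem_sets
        assert len(m2.elem_sets["ROV"]) == len(tiny_mesh.elem_sets["ROV"])
        m2.validate()

    def test_ht_removed_keeps_veins(self, tiny_mesh):
        m2 = remove_parts(tiny_mesh, ("SPL", "HT", "CT"))
        assert "HT" not in m2.elem_sets
        assert len(m2.elem_sets["LOV"]) > 0 and len(m2.elem_sets["ROV"]) > 0
        m2.validate()

    def test_unknown_part_rejected(self, tiny_mesh):
        with pytest.raises(KeyError):
            remove_parts(tiny_mesh, ("ENDOCARDIUM",))

    def test_ct_transverse_cut_splits_ct(self, tiny_mesh):
        m2 = remove_parts(tiny_mesh, ("SPL",), cuts=("CT_transverse",))
        assert len(m2.elem_sets["CT"]) < len(tiny_mesh.elem_sets["CT"])


class TestMetrics:
    def test_buckling_metric_zero_on_straight_strip(self, tiny_mesh, coarse_frames):
        from cloop.frames import compute_local_frames, partition_subregions
        from cloop.solver import Trajectory, TrajectoryFrame

        ff = compute_local_frames(tiny_mesh)
        rm = partition_subregions(tiny_mesh, ff)
        traj = Trajectory(tiny_mesh, ff, rm, baseline_schedule(), SimulationConfig())
        nt = len(tiny_mesh.tets)
        eye = np.broadcast_to(np.eye(3), (nt, 3, 3))
        traj.frames.append(TrajectoryFrame(
            t=1.0, stage="HH10-", positions=tiny_mesh.nodes.copy(),
            M=eye, F=eye, F_star=eye, sigma=np.zeros((nt, 3, 3))))
        assert buckling_metric(traj) < 1.0

    def test_buckling_metric_recovers_sinusoid(self, tiny_mesh):
        from cloop.frames import compute_local_frames, partition_subregions
        from cloop.scenarios import _ov_strip_nodes
        from cloop.solver import Trajectory, TrajectoryFrame

        ff = compute_local_frames(tiny_mesh)
        rm = partition_subregions(tiny_mesh, ff)
        traj = Trajectory(tiny_mesh, ff, rm, baseline_schedule(), SimulationConfig())
        nt = len(tiny_mesh.tets)
        eye = np.broadcast_to(np.eye(3), (nt, 3, 3))
        traj.frames.append(TrajectoryFrame(
            t=1.0, stage="HH10-", positions=tiny_mesh.nodes.copy(), M=eye,
            F=eye, F_star=eye, sigma=np.zeros((nt, 3, 3))))
        pos = tiny_mesh.nodes.copy()
        ids, s, _psi = _ov_strip_nodes(tiny_mesh, "LOV", "cranial")
        amp = 12.0
        pos[ids, 2] += amp * np.sin(2 * np.pi * s / (np.ptp(s) / 2 + 1e-9))
        traj.frames.append(TrajectoryFrame(
            t=2.0, stage="HH12", positions=pos, M=eye, F=eye, F_star=eye,
            sigma=np.zeros((nt, 3, 3))))
        m = buckling_metric(traj)
        assert 0.4 * amp < m < 1.6 * amp


class TestDeterminism:
    def test_identical_runs_bit_for_bit(self, tiny_mesh, fast_sim_config):
        # scenario isolation: equal seeds and increments reproduce the
        # trajectory exactly (implicit solver, no hidden randomness).
        # Checked on the bare heart tube so two full runs stay cheap.
        bare = remove_parts(tiny_mesh, ("SPL", "FG", "LOV", "ROV", "CT"))
        r1 = run_simulation(bare, baseline_schedule(), fast_sim_config)
        r2 = run_simulation(bare, baseline_schedule(), fast_sim_config)
        for f1, f2 in zip(r1.frames, r2.frames):
            assert np.array_equal(f1.positions, f2.positions)
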