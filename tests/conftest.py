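"""Shared fixtures: meshes are generated at test time (no stored data).

Solver-backed fixtures use a deliberately coarse mesh and few increments so
the whole suite stays desk-scale; resolution behaviour is characterised by
the bilayer verification problem, and the acceptance script runs the finer
production setting.
"""

import pytest

from cloop.frames import compute_local_frames, partition_subregions
from cloop.geometry import GeometryParams, build_idealized_heart
from cloop.measures import rotation_history
from cloop.morphogenesis import baseline_schedule
from cloop.scenarios import ScenarioResult
from cloop.solver import SimulationConfig, run_simulation

COARSE_EDGE = 130.0  # um; geometry/frames tests (no solver)
TINY_EDGE = 200.0  # um; fastest usable discretisation for solver runs


def pytest_collection_modifyitems(items):
    """Run cheap unit tests before the solver-backed end-to-end tests so a
    tight wall-clock budget truncates only the heaviest tail."""
    order = {"left_vein": 0, "right_vein": 1, "both_veins": 2, "spl_removal": 3,
             "no_fusion": 4, "no_contraction": 5}

    def key(item):
        if item.module.__name__.endswith("test_acceptance"):
            if "PerturbationCatalogue" in item.nodeid:
                sub = next((v for k, v in order.items() if k in item.name), 9)
                return (3, sub)
            if "BaselineLooping" in item.nodeid:
                return (2, 0)
            return (1, 0)
        return (0, 0)

    items.sort(key=key)


@pytest.fixture(scope="session")
def coarse_params():
    return GeometryParams(target_edge_length=COARSE_EDGE)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return build_idealized_heart(coarse_params)


@pytest.fixture(scope="session")
def coarse_frames(coarse_mesh):
    return compute_local_frames(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_regions(coarse_mesh, coarse_frames):
    return partition_subregions(coarse_mesh, coarse_frames)


@pytest.fixture(scope="session")
def tiny_mesh():
    return build_idealized_heart(GeometryParams(target_edge_length=TINY_EDGE))


@pytest.fixture(scope="session")
def fast_sim_config():
    return SimulationConfig(n_increments_initial=10, n_increments_looping=12,
                            output_every=4)


@pytest.fixture(scope="session")
def baseline_traj(tiny_mesh, fast_sim_config):
    """One shared baseline looping run, reused by all end-to-end tests."""
    return run_simulation(tiny_mesh, baseline_schedule(), fast_sim_config)


@pytest.fixture(scope="session")
def baseline_result(baseline_traj):
    """The shared baseline wrapped as a scenario result (for comparative
    perturbation checks)."""
    return ScenarioResult("baseline", baseline_traj, rotation_history(baseline_traj))
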