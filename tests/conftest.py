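import numpy as np
import pytest

import hemoflow as hf
from hemoflow.mesh import DOFMap
from hemoflow.rheology import CaseConfig
from hemoflow.solver import SolverConfig, newton_solve


@pytest.fixture(scope="session")
def straight_geom():
    """Lesion-free channel of height 2 and length 16."""
    return hf.build_channel(hf.StenosisSpec(eps=0.0))


@pytest.fixture(scope="session")
def straight_mesh(straight_geom):
    return hf.mesh_channel(straight_geom, h_far=0.5, h_lesion=0.25)


@pytest.fixture(scope="session")
def poiseuille_solution(straight_geom, straight_mesh):
    """Converged Newtonian channel flow at Re=100 with unit mean inflow."""
    mesh = straight_mesh
    dofmap = DOFMap(mesh.n_nodes, mesh.n_corners)
    cfg = SolverConfig(
        re=100.0, wi=0.0, case=CaseConfig("newtonian"), u_in=1.0, stabilize=False
    )
    state, hist = newton_solve(mesh, dofmap, cfg)
    assert hist.converged, hist.message
    return state, cfg, straight_geom


@pytest.fixture(scope="session")
def oldroyd_channel_solution(straight_geom, straight_mesh):
    """Oldroyd-B channel flow at Wi=0.1: fully developed everywhere."""
    mesh = straight_mesh
    dofmap = DOFMap(mesh.n_nodes, mesh.n_corners)
    cfg = SolverConfig(
        re=100.0, wi=0.1, case=CaseConfig("oldroyd_b"), u_in=1.0, stabilize=False
    )
    state, hist = newton_solve(mesh, dofmap, cfg)
    assert hist.converged, hist.message
    return state, cfg, straight_geom
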