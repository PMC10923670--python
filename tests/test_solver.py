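"""Assembly, boundary conditions, Newton iteration, conservation."""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.mesh import DOFMap
from hemoflow.rheology import CaseConfig, CrossParams, OldroydParams
from hemoflow.solver import (
    FlowState,
    SolverConfig,
    assemble,
    continuation_solve,
    dirichlet_data,
    flux,
    inlet_profile,
    newton_solve,
)


@pytest.fixture(scope="module")
def tiny_mesh():
    geom = hf.build_channel(hf.StenosisSpec(eps=0.0, centers=(), domain_length=2.0))
    mesh = hf.mesh_channel(geom, h_far=1.0, h_lesion=1.0)
    return mesh, DOFMap(mesh.n_nodes, mesh.n_corners)


class TestAssemble:
    def test_zero_state_zero_forcing_gives_zero_momentum_residual(self, tiny_mesh):
        mesh, dm = tiny_mesh
        cfg = SolverConfig(re=100.0, wi=0.3, case=CaseConfig("oldroyd_b"), stabilize=False)
        r, _ = assemble(mesh, dm, FlowState(mesh, dm), cfg, residual_only=True)
        assert np.allclose(r, 0.0)

    @pytest.mark.parametrize("case", ["newtonian", "gen_newtonian", "gen_oldroyd_b"])
    def test_jacobian_matches_finite_differences(self, tiny_mesh, case):
        mesh, dm = tiny_mesh
        cfg = SolverConfig(
            re=50.0, wi=0.3, case=CaseConfig(case), u_in=0.5, stabilize=False
        )
        rng = np.random.default_rng(11)
        state = FlowState(mesh, dm, 0.3 * rng.standard_normal(dm.n_dofs))
        _, jac = assemble(mesh, dm, state, cfg)
        eps = 1e-7
        for k in rng.integers(0, dm.n_dofs, 25):
            dv = np.zeros(dm.n_dofs)
            dv[k] = eps
            rp, _ = assemble(mesh, dm, FlowState(mesh, dm, state.vec + dv), cfg, residual_only=True)
            rm, _ = assemble(mesh, dm, FlowState(mesh, dm, state.vec - dv), cfg, residual_only=True)
            fd = (rp - rm) / (2 * eps)
            an = jac[:, int(k)].toarray().ravel()
            err = np.max(np.abs(fd - an)) / max(1.0, np.max(np.abs(an)))
            assert err < 1e-6

    def test_poiseuille_state_has_small_residual(self, tiny_mesh):
        # manufactured check: the exact channel solution annihilates the
        # discrete residual on the free dofs
        mesh, dm = tiny_mesh
        cfg = SolverConfig(re=100.0, wi=0.2, case=CaseConfig("oldroyd_b"), u_in=1.0, stabilize=False)
        state = FlowState(mesh, dm)
        y = mesh.coords[:, 1]
        nu_v = cfg.rheology.nu_v
        dudy = -3.0 * (y - 1.0)
        state.vec[dm.field_dofs("u")] = 1.5 * (1 - (y - 1) ** 2)
        state.vec[dm.field_dofs("s12")] = nu_v * dudy
        state.vec[dm.field_dofs("s11")] = 2 * nu_v * cfg.wi * dudy**2
        slope = (1.0 + nu_v) * 3.0
        state.vec[dm.field_dofs("p")] = slope * (2.0 - mesh.coords[: dm.n1, 0])
        r, _ = assemble(mesh, dm, state, cfg, residual_only=True)
        d_idx, _ = dirichlet_data(mesh, dm, cfg)
        free = np.ones(dm.n_dofs, bool)
        free[d_idx] = False
        assert np.max(np.abs(r[free])) < 1e-10


class TestBoundaryConditions:
    def test_inlet_profile_peak_walls_mean(self):
        y = np.linspace(0.0, 2.0, 101)
        prof = inlet_profile(y, 1.0, 1.0)
        assert prof[50] == pytest.approx(1.5)  # axis peak 1.5 U_i
        assert prof[0] == prof[-1] == 0.0  # vanishes at walls
        assert np.trapezoid(prof, y) / 2.0 == pytest.approx(1.0, abs=1e-3)

    def test_inlet_stress_data_consistent_with_steady_shear(self, tiny_mesh):
        mesh, dm = tiny_mesh
        cfg = SolverConfig(re=10.0, wi=0.5, case=CaseConfig("oldroyd_b"), u_in=1.0)
        idx, vals = dirichlet_data(mesh, dm, cfg)
        lookup = dict(zip(idx, vals))
        inlet = np.unique(mesh.boundary_edges[mesh.boundary_tags == "inlet"].ravel())
        nu_v = cfg.rheology.nu_v
        for n in inlet:
            y = mesh.coords[n, 1]
            dudy = -3.0 * (y - 1.0)
            assert lookup[dm.field_dofs("s12", [n])[0]] == pytest.approx(nu_v * dudy)
            assert lookup[dm.field_dofs("s11", [n])[0]] == pytest.approx(
                2 * nu_v * 0.5 * dudy**2
            )

    def test_walls_override_inlet_corners(self, tiny_mesh):
        mesh, dm = tiny_mesh
        cfg = SolverConfig(re=10.0, wi=0.0, case=CaseConfig("newtonian"), u_in=1.0)
        idx, vals = dirichlet_data(mesh, dm, cfg)
        lookup = dict(zip(idx, vals))
        wall = np.unique(mesh.boundary_edges[mesh.boundary_tags == "wall"].ravel())
        for n in wall:
            assert lookup[dm.field_dofs("u", [n])[0]] == 0.0
            assert lookup[dm.field_dofs("v", [n])[0]] == 0.0


class TestNewton:
    def test_poiseuille_recovery_machine_precision(self, poiseuille_solution):
        state, cfg, _ = poiseuille_solution
        y = state.mesh.coords[:, 1]
        u_exact = 1.5 * (1.0 - (y - 1.0) ** 2)
        rel = np.linalg.norm(state.u - u_exact) / np.linalg.norm(u_exact)
        assert rel < 1e-6
        assert np.max(np.abs(state.v)) < 1e-8

    def test_continuation_invariance(self, straight_mesh):
        # ramping Re {1, 10, 100} must land on the direct Re=100 solution
        dm = DOFMap(straight_mesh.n_nodes, straight_mesh.n_corners)
        cfg = SolverConfig(re=100.0, wi=0.0, case=CaseConfig("newtonian"), u_in=1.0, stabilize=False)
        direct, h1 = newton_solve(straight_mesh, dm, cfg)
        ramped, hists = continuation_solve(
            straight_mesh, dm, cfg, schedule=[1.0, 10.0, 100.0]
        )
        assert h1.converged and all(h.converged for _, h in hists)
        assert np.max(np.abs(direct.vec - ramped.vec)) < 1e-5

    def test_nonconvergence_is_flagged(self, straight_mesh):
        dm = DOFMap(straight_mesh.n_nodes, straight_mesh.n_corners)
        cfg = SolverConfig(
            re=100.0, wi=0.0, case=CaseConfig("newtonian"), u_in=1.0,
            stabilize=False, max_newton=1,
        )
        _, hist = newton_solve(straight_mesh, dm, cfg)
        assert not hist.converged
        assert "convergence" in hist.message

    def test_solver_config_range_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(re=0.0)
        with pytest.raises(ValueError):
            SolverConfig(wi=1.5)


class TestDegeneracies:
    """Constitutive cases must collapse onto each other in their limits."""

    @pytest.fixture(scope="class")
    def coarse_setup(self):
        geom = hf.build_channel(hf.StenosisSpec())
        mesh = hf.mesh_channel(geom, h_far=0.6, h_lesion=0.3)
        return geom, mesh, DOFMap(mesh.n_nodes, mesh.n_corners)

    def _solve(self, mesh, dm, case_cfg, wi=0.6):
        cfg = SolverConfig(
            re=300.0, wi=wi, case=case_cfg, u_in=0.0608, stabilize=False,
            tol=1e-8, rel_resid_tol=1e-12,
        )
        state, hist = newton_solve(mesh, dm, cfg)
        assert hist.converged, hist.message
        return state

    def test_gn_with_equal_plateaus_equals_newtonian(self, coarse_setup):
        _, mesh, dm = coarse_setup
        flat = CrossParams(mu0=0.0036, mu_inf=0.0036)
        gn = self._solve(mesh, dm, CaseConfig("gen_newtonian", cross=flat))
        nt = self._solve(mesh, dm, CaseConfig("newtonian"))
        assert np.max(np.abs(gn.vec - nt.vec)) < 1e-10

    def test_oldroyd_with_zero_muv_equals_newtonian(self, coarse_setup):
        _, mesh, dm = coarse_setup
        od0 = self._solve(
            mesh, dm, CaseConfig("oldroyd_b", oldroyd=OldroydParams(mu_v=0.0))
        )
        nt = self._solve(mesh, dm, CaseConfig("newtonian"))
        assert np.max(np.abs(od0.u - nt.u)) < 1e-10
        assert np.max(np.abs(od0.v - nt.v)) < 1e-10

    def test_gd_with_equal_plateaus_equals_oldroyd(self, coarse_setup):
        _, mesh, dm = coarse_setup
        flat = CrossParams(mu0=0.0036, mu_inf=0.0036)
        gd = self._solve(mesh, dm, CaseConfig("gen_oldroyd_b", cross=flat))
        od = self._solve(mesh, dm, CaseConfig("oldroyd_b"))
        assert np.max(np.abs(gd.vec - od.vec)) < 1e-10


class TestFluxAndSymmetry:
    def test_poiseuille_flux_equals_mean_times_height(self, poiseuille_solution):
        state, _, _ = poiseuille_solution
        assert flux(state, x=0.0) == pytest.approx(2.0, rel=1e-12)

    def test_flux_constant_along_interior_stations(self, poiseuille_solution):
        state, _, _ = poiseuille_solution
        q0 = flux(state, station_index=0)
        for x in (3.0, 6.0, 8.0, 11.0, 14.0):
            assert abs(flux(state, x=x) - q0) / q0 < 1e-5

    def test_outside_domain_rejected(self, poiseuille_solution):
        state, _, _ = poiseuille_solution
        with pytest.raises(ValueError):
            flux(state, x=20.0)

    def test_midplane_symmetry_of_stenosis_flow(self):
        geom = hf.build_channel(hf.StenosisSpec())
        mesh = hf.mesh_channel(geom, h_far=0.6, h_lesion=0.3)
        dm = DOFMap(mesh.n_nodes, mesh.n_corners)
        cfg = SolverConfig(re=500.0, wi=0.0, case=CaseConfig("newtonian"), u_in=0.0608, stabilize=False)
        state, hists = continuation_solve(mesh, dm, cfg)
        assert all(h.converged for _, h in hists)
        md = mesh.metadata
        ny = md["ny"]
        cg = md["corner_grid"]
        for d in range(1, ny // 2):
            upper = state.u[cg[:, ny // 2 + d]]
            lower = state.u[cg[:, ny // 2 - d]]
            assert np.max(np.abs(upper - lower)) < 1e-8
            vu = state.v[cg[:, ny // 2 + d]]
            vl = state.v[cg[:, ny // 2 - d]]
            assert np.max(np.abs(vu + vl)) < 1e-8


class TestSolveCase:
    def test_one_operating_point_with_conservation(self):
        from hemoflow.solver import solve_case

        state, geom, histories, cfg = solve_case(
            "stenosis", "gd", re=200.0, wi=0.6, h_far=0.8, h_lesion=0.4,
            stabilize=False,
        )
        assert all(h.converged for _, h in histories)
        assert np.all(np.isfinite(state.vec))
        q_in = flux(state, station_index=0)
        q_out = flux(state, x=geom.length)
        assert abs(q_in - q_out) / abs(q_in) < 1e-6

    def test_warm_start_skips_continuation(self):
        from hemoflow.solver import solve_case

        state, geom, hists, cfg = solve_case(
            "aneurysm", "newtonian", re=150.0, wi=0.0, h_far=0.8, h_lesion=0.4,
            stabilize=False,
        )
        mesh = state.mesh
        state2, _, hists2, _ = solve_case(
            "aneurysm", "newtonian", re=200.0, wi=0.0, mesh=mesh,
            initial_state=state, stabilize=False,
        )
        assert len(hists2) == 1  # direct solve from the warm start
        assert all(h.converged for _, h in hists2)
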