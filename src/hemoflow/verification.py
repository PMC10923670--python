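"""Analytic fixtures and solver-verification oracles.

Everything here is synthetic and closed-form: plane Poiseuille flow (the
inlet profile is its own exact solution), the steady homogeneous-shear
Oldroyd-B stress state, and trigonometric manufactured solutions whose
forcing is derived symbolically so the discretization error can be measured
exactly on a sequence of meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _fem
from .geometry import StenosisSpec, build_channel
from .mesh import DOFMap, mesh_channel
from .rheology import CaseConfig, OldroydParams
from .solver import FlowState, SolverConfig, newton_solve

__all__ = [
    "ManufacturedCase",
    "poiseuille_fixture",
    "shear_fixture",
    "manufactured_vortex",
    "solve_manufactured",
    "l2_errors",
    "convergence_study",
]


@dataclass
class ManufacturedCase:
    """Closed-form fields plus the forcing that makes them an exact solution.

    ``u``/``v`` are divergence-free by construction (stream-function based);
    ``forcing`` returns the momentum source required for the fields to
    satisfy the steady dimensionless system exactly at the stated (Re, nu).
    """

    u: Callable
    v: Callable
    p: Callable
    forcing: Callable
    re: float
    nu: float = 1.0
    domain_length: float = 1.0
    domain_height: float = 1.0
    description: str = ""
    extras: dict = field(default_factory=dict)

    def divergence(self, x, y, h: float = 1e-6):
        """Centered-difference check that the fields are divergence-free."""
        dudx = (self.u(x + h, y) - self.u(x - h, y)) / (2 * h)
        dvdy = (self.v(x, y + h) - self.v(x, y - h)) / (2 * h)
        return dudx + dvdy


def poiseuille_fixture(
    u_mean: float = 1.0,
    height: float = 2.0,
    viscosity: float = 1.0,
    length: float = 16.0,
) -> ManufacturedCase:
    """Plane Poiseuille flow: parabolic U, zero V, linear p, zero forcing.

    With half-height a = height/2 the axis velocity is 1.5*u_mean, the flux
    is u_mean*height, the wall velocity gradient is 3*u_mean/a and the wall
    shear stress is 3*viscosity*u_mean/a.  The pressure datum is zero at the
    outlet.
    """
    a = 0.5 * height
    slope = 3.0 * viscosity * u_mean / a**2

    def u(x, y):
        eta = (np.asarray(y, float) - a) / a
        return 1.5 * u_mean * (1.0 - eta**2)

    def v(x, y):
        return np.zeros_like(np.asarray(x, float))

    def p(x, y):
        return slope * (length - np.asarray(x, float))

    def forcing(x, y):
        z = np.zeros_like(np.asarray(x, float))
        return z, z

    return ManufacturedCase(
        u=u,
        v=v,
        p=p,
        forcing=forcing,
        re=1.0,
        nu=viscosity,
        domain_length=length,
        domain_height=height,
        description="plane Poiseuille flow",
        extras={
            "flux": u_mean * height,
            "axis_velocity": 1.5 * u_mean,
            "wall_gradient": 3.0 * u_mean / a,
            "wss": 3.0 * viscosity * u_mean / a,
            "pressure_slope": -slope,
        },
    )


def shear_fixture(gamma_dot: float, params: OldroydParams, wi: float):
    """Steady homogeneous-shear Oldroyd-B stress triple.

    For a velocity field U = gamma_dot * y the transported extra stress
    settles to ``sigma11 = 2 mu_v Wi gamma_dot^2``, ``sigma12 = mu_v
    gamma_dot``, ``sigma22 = 0`` — the state a solver must reproduce in any
    fully developed channel region.
    """
    mu_v = params.mu_v
    return (2.0 * mu_v * wi * gamma_dot**2, mu_v * gamma_dot, 0.0)


def manufactured_vortex(re: float = 10.0, nu: float = 1.0, amp: float = 1.0) -> ManufacturedCase:
    """Trigonometric vortex on the unit square with symbolically derived forcing.

    Stream function psi = (amp/pi) sin^2(pi x) sin^2(pi y) gives a
    divergence-free velocity that vanishes on the whole boundary; pressure
    is cos(pi x) cos(pi y).  The forcing is computed with sympy from the
    steady momentum equation Re (u.grad)u + grad p - nu Lap(u) = f.
    """
    import sympy as sp

    x, y = sp.symbols("x y", real=True)
    psi = (amp / sp.pi) * sp.sin(sp.pi * x) ** 2 * sp.sin(sp.pi * y) ** 2
    u = sp.diff(psi, y)
    v = -sp.diff(psi, x)
    p = sp.cos(sp.pi * x) * sp.cos(sp.pi * y)
    fx = re * (u * sp.diff(u, x) + v * sp.diff(u, y)) + sp.diff(p, x) - nu * (
        sp.diff(u, x, 2) + sp.diff(u, y, 2)
    )
    fy = re * (u * sp.diff(v, x) + v * sp.diff(v, y)) + sp.diff(p, y) - nu * (
        sp.diff(v, x, 2) + sp.diff(v, y, 2)
    )
    fns = [sp.lambdify((x, y), expr, "numpy") for expr in (u, v, p, fx, fy)]

    def wrap(fn):
        def g(xx, yy):
            return np.broadcast_to(
                np.asarray(fn(xx, yy), float), np.broadcast_shapes(np.shape(xx), np.shape(yy))
            ).copy()

        return g

    uf, vf, pf, fxf, fyf = (wrap(f) for f in fns)

    def forcing(xx, yy):
        return fxf(xx, yy), fyf(xx, yy)

    return ManufacturedCase(
        u=uf,
        v=vf,
        p=pf,
        forcing=forcing,
        re=re,
        nu=nu,
        domain_length=1.0,
        domain_height=1.0,
        description="trigonometric vortex (method of manufactured solutions)",
    )


def _square_mesh(case: ManufacturedCase, h: float):
    spec = StenosisSpec(
        D=case.domain_height, eps=0.0, centers=(), Ls=1.0, domain_length=case.domain_length
    )
    geom = build_channel(spec, n_samples=17)
    return mesh_channel(geom, h_far=h, h_lesion=h)


def solve_manufactured(case: ManufacturedCase, h: float):
    """Solve a manufactured case on a uniform mesh of spacing h."""
    mesh = _square_mesh(case, h)
    dofmap = DOFMap(mesh.n_nodes, mesh.n_corners)
    pin_xy = (0.0, 0.0)
    cfg = SolverConfig(
        re=case.re,
        wi=0.0,
        case=CaseConfig("newtonian"),
        bc_mode="dirichlet",
        exact={"u": case.u, "v": case.v},
        forcing=case.forcing,
        pin_pressure=(pin_xy[0], pin_xy[1], float(case.p(*pin_xy))),
        stabilize=False,
        tol=1e-10,
        rel_resid_tol=1e-12,
        max_newton=25,
    )
    state, hist = newton_solve(mesh, dofmap, cfg)
    if not hist.converged:
        raise RuntimeError(f"manufactured solve failed at h={h}: {hist.message}")
    return state, mesh, dofmap


def l2_errors(state: FlowState, case: ManufacturedCase) -> dict:
    """L2 field errors against the exact solution, by degree-5 quadrature."""
    mesh = state.mesh
    detj, inv_jt = _fem.element_geometry(mesh.coords, mesh.tris)
    wdet = _fem.QUAD_WEIGHTS[None, :] * detj[:, None]
    corners = mesh.coords[mesh.tris[:, :3]]
    qp = np.einsum("mq,emi->eqi", _fem.QP_H, corners)
    N, H = _fem.QP_N2, _fem.QP_H
    uh = state.u[mesh.tris] @ N
    vh = state.v[mesh.tris] @ N
    ph = state.p[mesh.tris[:, :3]] @ H
    ue = case.u(qp[..., 0], qp[..., 1])
    ve = case.v(qp[..., 0], qp[..., 1])
    pe = case.p(qp[..., 0], qp[..., 1])
    err_u = float(np.sqrt(np.sum(wdet * ((uh - ue) ** 2 + (vh - ve) ** 2))))
    err_p = float(np.sqrt(np.sum(wdet * (ph - pe) ** 2)))
    norm_u = float(np.sqrt(np.sum(wdet * (ue**2 + ve**2))))
    return {"velocity": err_u, "pressure": err_p, "velocity_rel": err_u / max(norm_u, 1e-300)}


def convergence_study(case: ManufacturedCase, hs=(0.25, 0.125, 0.0625)) -> dict:
    """Observed L2 convergence orders over a sequence of mesh sizes.

    Returns per-field errors and least-squares log-log slopes; quadratic
    velocity elements should show order >= 1.8 and linear pressure >= 0.9.
    """
    hs = sorted(hs, reverse=True)
    if len(hs) < 3:
        raise ValueError("need at least 3 mesh sizes for a credible slope")
    errs_u, errs_p = [], []
    for h in hs:
        state, mesh, _ = solve_manufactured(case, h)
        e = l2_errors(state, case)
        errs_u.append(e["velocity"])
        errs_p.append(e["pressure"])
    log_h = np.log(np.asarray(hs))
    slope_u = float(np.polyfit(log_h, np.log(errs_u), 1)[0])
    slope_p = float(np.polyfit(log_h, np.log(errs_p), 1)[0])
    return {
        "h": list(hs),
        "velocity_errors": errs_u,
        "pressure_errors": errs_p,
        "velocity_order": slope_u,
        "pressure_order": slope_p,
    }
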