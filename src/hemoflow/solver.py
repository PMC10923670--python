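"""Steady mixed-FEM solver for Newtonian and Oldroyd-B channel flow.

Dimensionless governing system (starred variables, stars dropped), on the
mixed P2/P1 triangle with quadratic extra-stress support:

* continuity        ``div U = 0``
* momentum          ``Re (U.grad)U = -grad p + div(nu_s grad U) + div sigma + f``
* stress transport  ``Wi (U.grad)sigma + sigma
                      = 2 nu_v V(U) + Wi [ (grad U) sigma + sigma (grad U)^T ]``

``nu_s`` is the dimensionless solvent viscosity (1 for Newtonian, the
generalized Cross law for shear-thinning cases) and ``nu_v`` the
dimensionless viscoelastic viscosity; both are produced by
:class:`hemoflow.rheology.DimensionlessRheology`.  The viscous term is kept
in Laplacian (gradient-gradient) weak form and the stress divergence is
tested directly (not integrated by parts), so the outflow natural condition
is ``(-p I + nu_s grad U) . n = 0`` — uniform zero-datum outlet pressure —
and the extra stress needs boundary data only on the inflow.

The nonlinear system is solved by damped Newton iteration with an analytic
Jacobian, optional SUPG enrichment of the stress test functions plus
streamline diffusion on momentum convection (activated at high Re), and
Reynolds continuation for hard operating points.  Convergence is declared
when the per-field sum of absolute nodal increments drops below ``tol``
(default 1e-5) for every field, or when the relative residual falls below a
stricter safety threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from . import _fem
from .geometry import AneurysmSpec, ChannelGeometry, StenosisSpec, build_channel
from .mesh import DOFMap, FIELDS, TriMesh, mesh_channel
from .rheology import CaseConfig, DimensionlessRheology, canonical_case

__all__ = [
    "SolverConfig",
    "FlowState",
    "NewtonHistory",
    "assemble",
    "dirichlet_data",
    "newton_solve",
    "continuation_solve",
    "solve_case",
    "flux",
    "inlet_profile",
]


def inlet_profile(y, u_in: float, axis_y: float):
    """Centered parabolic inflow 1.5*u_in*(1 - eta^2), eta = (y-axis)/axis.

    Vanishes at both walls, peaks at 1.5*u_in on the axis, and has mean
    ``u_in`` across the inlet.
    """
    eta = (np.asarray(y, dtype=float) - axis_y) / axis_y
    return 1.5 * u_in * (1.0 - eta**2)


def inlet_profile_dy(y, u_in: float, axis_y: float):
    eta = (np.asarray(y, dtype=float) - axis_y) / axis_y
    return -3.0 * u_in * eta / axis_y


@dataclass
class SolverConfig:
    """Operating point and numerical controls for one steady solve."""

    re: float = 1000.0
    wi: float = 0.6
    case: CaseConfig = field(default_factory=CaseConfig)
    u_in: float = 0.0608
    tol: float = 1e-5
    max_newton: int = 40
    relaxation: float = 1.0
    rel_resid_tol: float = 1e-8
    shear_smoothing: float = 1e-3  # delta in gd_eff = sqrt(gd^2 + delta^2)
    stabilize: bool | None = None  # None = auto (element-Peclet heuristic)
    stab_peclet_threshold: float = 60.0
    h_est: float = 0.4  # coarse element-size estimate for the auto heuristic
    supg_const: float = 1.0
    forcing: tuple | Callable | None = None
    bc_mode: str = "channel"  # or "dirichlet" (all-boundary velocity data)
    exact: dict | None = None  # manufactured fields for bc_mode="dirichlet"
    pin_pressure: tuple | None = None  # (x, y, value)
    U_ref: float = 1.0
    L_ref: float = 0.0062

    def __post_init__(self):
        if not 0.0 < self.re <= 3000.0:
            raise ValueError("Reynolds number must lie in (0, 3000]")
        if not 0.0 <= self.wi <= 1.0:
            raise ValueError("Weissenberg number must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def stabilized(self) -> bool:
        """SUPG/streamline-diffusion switch.

        Auto mode estimates the inlet-peak element Peclet number
        ``Re * 1.5 u_in * h / 2`` and enables stabilization only when it
        exceeds ``stab_peclet_threshold`` (default 60, an empirical bound
        between regimes observed Newton-stable unstabilized and divergent
        on channel meshes) — plain Galerkin on quadratic elements is clean
        below that, and analytic verification runs then see no
        stabilization terms at all.
        """
        if self.stabilize is None:
            peclet = self.re * 1.5 * abs(self.u_in) * self.h_est / 2.0
            return peclet > self.stab_peclet_threshold
        return bool(self.stabilize)

    @property
    def rheology(self) -> DimensionlessRheology:
        return DimensionlessRheology(self.case, U_ref=self.U_ref, L_ref=self.L_ref)


class FlowState:
    """Nodal solution fields over a mesh: U, V, P and sigma components."""

    def __init__(self, mesh: TriMesh, dofmap: DOFMap, vec: np.ndarray | None = None):
        self.mesh = mesh
        self.dofmap = dofmap
        self.vec = np.zeros(dofmap.n_dofs) if vec is None else np.asarray(vec, float)

    def _field(self, name):
        off = self.dofmap.offsets[name]
        n = self.dofmap.n1 if name == "p" else self.dofmap.n2
        return self.vec[off : off + n]

    u = property(lambda s: s._field("u"))
    v = property(lambda s: s._field("v"))
    p = property(lambda s: s._field("p"))
    s11 = property(lambda s: s._field("s11"))
    s12 = property(lambda s: s._field("s12"))
    s22 = property(lambda s: s._field("s22"))

    def copy(self) -> "FlowState":
        return FlowState(self.mesh, self.dofmap, self.vec.copy())

    def pressure_on_all_nodes(self) -> np.ndarray:
        """Linear pressure evaluated at every node (midsides = edge means)."""
        p = np.zeros(self.mesh.n_nodes)
        p[: self.dofmap.n1] = self.p
        counts = np.zeros(self.mesh.n_nodes)
        counts[: self.dofmap.n1] = 1.0
        for loc, (i1, i2) in zip((3, 4, 5), ((0, 1), (1, 2), (2, 0))):
            mids = self.mesh.tris[:, loc]
            vals = 0.5 * (self.p[self.mesh.tris[:, i1]] + self.p[self.mesh.tris[:, i2]])
            np.add.at(p, mids, vals)
            np.add.at(counts, mids, 1.0)
        return p / np.maximum(counts, 1.0)

    def nodal_velocity_gradient(self) -> np.ndarray:
        """Recovered nodal velocity gradient, shape (n_nodes, 2, 2)."""
        mesh = self.mesh
        nodes_ref = np.array(
            [[0, 0], [1, 0], [0, 1], [0.5, 0], [0.5, 0.5], [0, 0.5]], dtype=float
        )
        dref = _fem.p2_grad(nodes_ref[:, 0], nodes_ref[:, 1])  # (6, 2, 6)
        detj, inv_jt = _fem.element_geometry(mesh.coords, mesh.tris)
        # dphys[e, a, i, n] : gradient of basis a, component i, at local node n
        dphys = np.einsum("eik,akn->eain", inv_jt, dref)
        ue = self.u[mesh.tris]
        ve = self.v[mesh.tris]
        grad = np.zeros((mesh.n_nodes, 2, 2))
        counts = np.zeros(mesh.n_nodes)
        ge = np.empty((mesh.tris.shape[0], 6, 2, 2))
        ge[:, :, 0, :] = np.einsum("ea,eain->eni", ue, dphys)
        ge[:, :, 1, :] = np.einsum("ea,eain->eni", ve, dphys)
        np.add.at(grad, mesh.tris.ravel(), ge.reshape(-1, 2, 2))
        np.add.at(counts, mesh.tris.ravel(), 1.0)
        return grad / counts[:, None, None]

    def nodal_shear_rate(self) -> np.ndarray:
        from .rheology import shear_rate, strain_rate_tensor

        return shear_rate(strain_rate_tensor(self.nodal_velocity_gradient()))


@dataclass
class NewtonHistory:
    converged: bool
    iterations: int
    residual_norms: list
    increments: list  # per-iteration dict of per-field absolute increment sums
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (r, inc) in enumerate(zip(self.residual_norms, self.increments)):
            row = {"iteration": k, "residual_norm": r}
            row.update({f"dsum_{f}": inc.get(f, 0.0) for f in FIELDS})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discretization cache


class _Disc:
    """Per-mesh discretization factors shared by every assembly call."""

    def __init__(self, mesh: TriMesh, dofmap: DOFMap):
        self.mesh = mesh
        self.dofmap = dofmap
        self.detj, inv_jt = _fem.element_geometry(mesh.coords, mesh.tris)
        if np.any(self.detj <= 0):
            bad = int(np.argmax(self.detj <= 0))
            raise ValueError(f"element {bad} has non-positive Jacobian")
        self.dn2, self.dh = _fem.physical_gradients(inv_jt)
        self.wdet = _fem.QUAD_WEIGHTS[None, :] * self.detj[:, None]  # (Ne, nq)
        self.dnx = np.ascontiguousarray(self.dn2[:, :, 0, :])  # (Ne, 6, nq)
        self.dny = np.ascontiguousarray(self.dn2[:, :, 1, :])
        # quadrature point coordinates
        corners = mesh.coords[mesh.tris[:, :3]]  # (Ne, 3, 2)
        self.qp = np.einsum("mq,emi->eqi", _fem.QP_H, corners)  # (Ne, nq, 2)
        self.h_el = np.sqrt(self.detj)  # element length scale
        # element dof indices per field
        off = dofmap.offsets
        self.edofs = {
            f: off[f] + mesh.tris for f in ("u", "v", "s11", "s12", "s22")
        }
        self.edofs["p"] = off["p"] + mesh.tris[:, :3]


_DISC_CACHE: dict[int, _Disc] = {}


def _get_disc(mesh: TriMesh, dofmap: DOFMap) -> _Disc:
    key = id(mesh)
    disc = _DISC_CACHE.get(key)
    if disc is None or disc.mesh is not mesh:
        disc = _Disc(mesh, dofmap)
        _DISC_CACHE.clear()
        _DISC_CACHE[key] = disc
    return disc


# ---------------------------------------------------------------------------
# assembly


def _forcing_at(cfg: SolverConfig, qp: np.ndarray):
    if cfg.forcing is None:
        return None
    if callable(cfg.forcing):
        fx, fy = cfg.forcing(qp[..., 0], qp[..., 1])
        return np.asarray(fx, float), np.asarray(fy, float)
    fx, fy = cfg.forcing
    if callable(fx):
        return np.asarray(fx(qp[..., 0], qp[..., 1]), float), np.asarray(
            fy(qp[..., 0], qp[..., 1]), float
        )
    shape = qp.shape[:-1]
    return np.full(shape, float(fx)), np.full(shape, float(fy))


def assemble(
    mesh: TriMesh,
    dofmap: DOFMap,
    state: FlowState,
    cfg: SolverConfig,
    residual_only: bool = False,
):
    """Assemble the weak residual (and exact Jacobian) at the given state.

    Returns ``(residual, jacobian)``; the Jacobian is ``None`` when
    ``residual_only``.  The Jacobian is the analytic linearization of every
    Galerkin term; when stabilization is active its advection direction and
    the SUPG weight are frozen at the current iterate (Picard-type), which
    leaves the converged solution unchanged.
    """
    disc = _get_disc(mesh, dofmap)
    rheo = cfg.rheology
    N = _fem.QP_N2  # (6, nq)
    H = _fem.QP_H  # (3, nq)
    dnx, dny, wdet = disc.dnx, disc.dny, disc.wdet
    tris = mesh.tris
    re, wi = cfg.re, cfg.wi
    nu_v = rheo.nu_v

    # field values and gradients at quadrature points, all (Ne, nq)
    def val(arr_nodes):
        return arr_nodes @ N

    def grads(arr_nodes):
        gx = np.einsum("ea,eaq->eq", arr_nodes, dnx)
        gy = np.einsum("ea,eaq->eq", arr_nodes, dny)
        return gx, gy

    ue, ve = state.u[tris], state.v[tris]
    U, V = val(ue), val(ve)
    Ux, Uy = grads(ue)
    Vx, Vy = grads(ve)
    pe = state.p[tris[:, :3]]
    P = pe @ H
    se11, se12, se22 = state.s11[tris], state.s12[tris], state.s22[tris]
    S11, S12, S22 = val(se11), val(se12), val(se22)
    S11x, S11y = grads(se11)
    S12x, S12y = grads(se12)
    S22x, S22y = grads(se22)

    # smoothed shear rate: the b < 1 Cross slope is unbounded as gd -> 0, so
    # gd_eff = sqrt(gd^2 + delta^2) keeps the Jacobian bounded along
    # stagnation lines (e.g. the jet axis); affects the viscosity only where
    # gd ~ delta, i.e. at the zero-shear plateau
    gd = np.sqrt(2.0 * (Ux**2 + Vy**2) + (Uy + Vx) ** 2 + cfg.shear_smoothing**2)
    nus = rheo.nu_s(gd)
    dnus = rheo.nu_s_derivative(gd) if cfg.case.is_shear_thinning else None

    force = _forcing_at(cfg, disc.qp)

    adv_u = U * Ux + V * Uy
    adv_v = U * Vx + V * Vy

    # stabilization weights
    stab = cfg.stabilized
    if stab:
        speed = np.sqrt(U**2 + V**2)
        h = disc.h_el[:, None]
        # stress transport is advection-reaction (reaction coefficient 1):
        # tau = 1/(1 + 2 Wi|U|/h), enrichment tau * Wi (U.grad N) -- bounded,
        # vanishing at no-slip walls, h/2-scaled in the advective limit
        tau_s = cfg.supg_const * wi * h / (h + 2.0 * wi * speed + 1e-14)
        pe_num = re * speed * h / np.maximum(2.0 * nus, 1e-12)
        tau_m = h / (2.0 * speed + 1e-12) * np.minimum(1.0, pe_num / 3.0)
        # streamline test direction (Ne, 6, nq)
        sdir = U[:, None, :] * dnx + V[:, None, :] * dny
        T = N[None, :, :] + tau_s[:, None, :] * sdir
    else:
        T = N

    # residual accumulation -------------------------------------------------
    def rsum(coeff, A):
        """Sum_q wdet*coeff * A[a]; A either (6|3, nq) or (Ne, na, nq)."""
        if A.ndim == 2:
            return np.einsum("eq,aq->ea", wdet * coeff, A)
        return np.einsum("eq,eaq->ea", wdet * coeff, A)

    div_sx = S11x + S12y
    div_sy = S12x + S22y

    r_u = (
        rsum(re * adv_u, N)
        + rsum(nus * Ux, dnx)
        + rsum(nus * Uy, dny)
        - rsum(P, dnx)
        - rsum(div_sx, N)
    )
    r_v = (
        rsum(re * adv_v, N)
        + rsum(nus * Vx, dnx)
        + rsum(nus * Vy, dny)
        - rsum(P, dny)
        - rsum(div_sy, N)
    )
    if force is not None:
        r_u -= rsum(force[0], N)
        r_v -= rsum(force[1], N)
    if stab:
        r_u += rsum(re * tau_m * adv_u, sdir)
        r_v += rsum(re * tau_m * adv_v, sdir)
    r_p = rsum(Ux + Vy, H)

    res_s11 = wi * (U * S11x + V * S11y) + S11 - 2.0 * wi * (Ux * S11 + Uy * S12) - 2.0 * nu_v * Ux
    res_s22 = wi * (U * S22x + V * S22y) + S22 - 2.0 * wi * (Vx * S12 + Vy * S22) - 2.0 * nu_v * Vy
    res_s12 = (
        wi * (U * S12x + V * S12y)
        + S12
        - wi * (Vx * S11 + (Ux + Vy) * S12 + Uy * S22)
        - nu_v * (Uy + Vx)
    )
    r_s11 = rsum(res_s11, T)
    r_s12 = rsum(res_s12, T)
    r_s22 = rsum(res_s22, T)

    residual = np.zeros(dofmap.n_dofs)
    for name, r in (
        ("u", r_u),
        ("v", r_v),
        ("p", r_p),
        ("s11", r_s11),
        ("s12", r_s12),
        ("s22", r_s22),
    ):
        np.add.at(residual, disc.edofs[name].ravel(), r.ravel())

    if residual_only:
        return residual, None

    # Jacobian blocks -------------------------------------------------------
    blocks: list[tuple[str, str, np.ndarray]] = []

    def blk(row, col, coeff, A, B):
        """J[row,col] += Sum_q wdet*coeff*A[a]*B[b]."""
        asub = "aq" if A.ndim == 2 else "eaq"
        bsub = "bq" if B.ndim == 2 else "ebq"
        arr = np.einsum(f"eq,{asub},{bsub}->eab", wdet * coeff, A, B)
        blocks.append((row, col, arr))

    one = np.ones_like(U)

    # momentum u-row
    blk("u", "u", re * Ux, N, N)
    blk("u", "u", re * U, N, dnx)
    blk("u", "u", re * V, N, dny)
    blk("u", "u", nus, dnx, dnx)
    blk("u", "u", nus, dny, dny)
    blk("u", "v", re * Uy, N, N)
    blk("u", "p", -one, dnx, H)
    blk("u", "s11", -one, N, dnx)
    blk("u", "s12", -one, N, dny)
    # momentum v-row
    blk("v", "v", re * Vy, N, N)
    blk("v", "v", re * U, N, dnx)
    blk("v", "v", re * V, N, dny)
    blk("v", "v", nus, dnx, dnx)
    blk("v", "v", nus, dny, dny)
    blk("v", "u", re * Vx, N, N)
    blk("v", "p", -one, dny, H)
    blk("v", "s12", -one, N, dnx)
    blk("v", "s22", -one, N, dny)
    if dnus is not None:
        # shear-thinning coupling: d(nu_s)/d(velocity dofs)
        gd_safe = gd
        SAu = dnx * Ux[:, None, :] + dny * Uy[:, None, :]  # (Ne,6,nq)
        SAv = dnx * Vx[:, None, :] + dny * Vy[:, None, :]
        Gu = (2.0 * Ux[:, None, :] * dnx + (Uy + Vx)[:, None, :] * dny) / gd_safe[:, None, :]
        Gv = ((Uy + Vx)[:, None, :] * dnx + 2.0 * Vy[:, None, :] * dny) / gd_safe[:, None, :]
        blk("u", "u", dnus, SAu, Gu)
        blk("u", "v", dnus, SAu, Gv)
        blk("v", "u", dnus, SAv, Gu)
        blk("v", "v", dnus, SAv, Gv)
    if stab:
        # frozen-direction linearization of the streamline-diffusion term
        blk("u", "u", re * tau_m * U, sdir, dnx)
        blk("u", "u", re * tau_m * V, sdir, dny)
        blk("v", "v", re * tau_m * U, sdir, dnx)
        blk("v", "v", re * tau_m * V, sdir, dny)
    # continuity row
    blk("p", "u", one, H, dnx)
    blk("p", "v", one, H, dny)
    # stress rows (test T, trial N or gradients)
    blk("s11", "s11", one - 2.0 * wi * Ux, T, N)
    blk("s11", "s11", wi * U, T, dnx)
    blk("s11", "s11", wi * V, T, dny)
    blk("s11", "s12", -2.0 * wi * Uy, T, N)
    blk("s11", "u", wi * S11x, T, N)
    blk("s11", "u", -2.0 * wi * S11 - 2.0 * nu_v, T, dnx)
    blk("s11", "u", -2.0 * wi * S12, T, dny)
    blk("s11", "v", wi * S11y, T, N)
    blk("s22", "s22", one - 2.0 * wi * Vy, T, N)
    blk("s22", "s22", wi * U, T, dnx)
    blk("s22", "s22", wi * V, T, dny)
    blk("s22", "s12", -2.0 * wi * Vx, T, N)
    blk("s22", "v", wi * S22y, T, N)
    blk("s22", "v", -2.0 * wi * S22 - 2.0 * nu_v, T, dny)
    blk("s22", "v", -2.0 * wi * S12, T, dnx)
    blk("s22", "u", wi * S22x, T, N)
    blk("s12", "s12", one - wi * (Ux + Vy), T, N)
    blk("s12", "s12", wi * U, T, dnx)
    blk("s12", "s12", wi * V, T, dny)
    blk("s12", "s11", -wi * Vx, T, N)
    blk("s12", "s22", -wi * Uy, T, N)
    blk("s12", "u", wi * S12x, T, N)
    blk("s12", "u", -wi * S12, T, dnx)
    blk("s12", "u", -wi * S22 - nu_v, T, dny)
    blk("s12", "v", wi * S12y, T, N)
    blk("s12", "v", -wi * S11 - nu_v, T, dnx)
    blk("s12", "v", -wi * S12, T, dny)

    rows_all, cols_all, vals_all = [], [], []
    for rname, cname, arr in blocks:
        er = disc.edofs[rname]
        ec = disc.edofs[cname]
        na, nb = arr.shape[1], arr.shape[2]
        rows_all.append(np.repeat(er[:, :, None], nb, axis=2).ravel())
        cols_all.append(np.repeat(ec[:, None, :], na, axis=1).ravel())
        vals_all.append(arr.ravel())
    n = dofmap.n_dofs
    jac = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    ).tocsr()
    return residual, jac


# ---------------------------------------------------------------------------
# boundary conditions


def dirichlet_data(mesh: TriMesh, dofmap: DOFMap, cfg: SolverConfig):
    """Dirichlet dof indices and values for the configured boundary scheme.

    Channel mode: parabolic inflow with the consistent steady-shear stress
    triple on the inlet, no-slip walls, natural (zero-traction) outflow.
    Dirichlet mode: velocity (and inlet stress) prescribed from ``cfg.exact``
    callables on every boundary, with an optional pressure pin.
    """
    tags = mesh.boundary_tags
    edges = mesh.boundary_edges
    if len(edges) == 0:
        raise ValueError("mesh has no boundary edges")
    nodesof = lambda mask: np.unique(edges[mask].ravel())
    wall_nodes = nodesof(tags == "wall")
    inlet_nodes = nodesof(tags == "inlet")
    untagged = set(tags.tolist()) - {"inlet", "outlet", "wall"}
    if untagged:
        raise ValueError(f"untagged/unknown boundary tags: {sorted(untagged)}")

    idx: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rheo = cfg.rheology

    if cfg.bc_mode == "channel":
        axis_y = mesh.metadata.get("axis_y")
        if axis_y is None:
            axis_y = 0.5 * (mesh.coords[:, 1].min() + mesh.coords[:, 1].max())
        y_in = mesh.coords[inlet_nodes, 1]
        uprof = inlet_profile(y_in, cfg.u_in, axis_y)
        dudy = inlet_profile_dy(y_in, cfg.u_in, axis_y)
        # inlet velocity + consistent extra-stress data
        idx.append(dofmap.field_dofs("u", inlet_nodes))
        vals.append(uprof)
        idx.append(dofmap.field_dofs("v", inlet_nodes))
        vals.append(np.zeros_like(uprof))
        idx.append(dofmap.field_dofs("s11", inlet_nodes))
        vals.append(2.0 * rheo.nu_v * cfg.wi * dudy**2)
        idx.append(dofmap.field_dofs("s12", inlet_nodes))
        vals.append(rheo.nu_v * dudy)
        idx.append(dofmap.field_dofs("s22", inlet_nodes))
        vals.append(np.zeros_like(uprof))
        # walls: no slip (overrides inlet corners, where both give zero)
        idx.append(dofmap.field_dofs("u", wall_nodes))
        vals.append(np.zeros(len(wall_nodes)))
        idx.append(dofmap.field_dofs("v", wall_nodes))
        vals.append(np.zeros(len(wall_nodes)))
    elif cfg.bc_mode == "dirichlet":
        if not cfg.exact:
            raise ValueError("bc_mode='dirichlet' requires cfg.exact callables")
        bnodes = np.unique(edges.ravel())
        x, y = mesh.coords[bnodes, 0], mesh.coords[bnodes, 1]
        idx.append(dofmap.field_dofs("u", bnodes))
        vals.append(np.asarray(cfg.exact["u"](x, y), float))
        idx.append(dofmap.field_dofs("v", bnodes))
        vals.append(np.asarray(cfg.exact["v"](x, y), float))
        for comp in ("s11", "s12", "s22"):
            fn = cfg.exact.get(comp)
            xi, yi = mesh.coords[inlet_nodes, 0], mesh.coords[inlet_nodes, 1]
            idx.append(dofmap.field_dofs(comp, inlet_nodes))
            vals.append(
                np.asarray(fn(xi, yi), float) if fn else np.zeros(len(inlet_nodes))
            )
    else:
        raise ValueError(f"unknown bc_mode {cfg.bc_mode!r}")

    if cfg.pin_pressure is not None:
        px, py, pval = cfg.pin_pressure
        corner = np.argmin(
            (mesh.coords[: dofmap.n1, 0] - px) ** 2 + (mesh.coords[: dofmap.n1, 1] - py) ** 2
        )
        idx.append(dofmap.field_dofs("p", np.array([corner])))
        vals.append(np.array([float(pval)]))

    idx_arr = np.concatenate(idx)
    val_arr = np.concatenate(vals)
    # later entries win (walls override inlet corners)
    order = np.arange(len(idx_arr))
    seen: dict[int, int] = {}
    for i in order:
        seen[int(idx_arr[i])] = i
    keep = sorted(seen.values())
    return idx_arr[keep], val_arr[keep]


def apply_bcs(jac, residual, dirichlet_idx, n_dofs):
    """Reduce an assembled system to the free unknowns."""
    free = np.ones(n_dofs, dtype=bool)
    free[dirichlet_idx] = False
    return jac[free][:, free], residual[free], free


# ---------------------------------------------------------------------------
# Newton iteration


def newton_solve(
    mesh: TriMesh,
    dofmap: DOFMap,
    cfg: SolverConfig,
    initial_state: FlowState | None = None,
) -> tuple[FlowState, NewtonHistory]:
    """Damped Newton iteration at a fixed operating point.

    Stops when the summed absolute nodal increment of every field falls
    below ``cfg.tol``, or when the relative residual drops below
    ``cfg.rel_resid_tol``; flags (never silently returns) non-convergence.
    Deterministic for fixed inputs.
    """
    state = initial_state.copy() if initial_state is not None else FlowState(mesh, dofmap)
    d_idx, d_vals = dirichlet_data(mesh, dofmap, cfg)
    state.vec[d_idx] = d_vals
    free = np.ones(dofmap.n_dofs, dtype=bool)
    free[d_idx] = False

    res_norms: list[float] = []
    inc_hist: list[dict] = []
    res0 = None
    best = np.inf
    message = ""
    converged = False

    for it in range(cfg.max_newton):
        residual, jac = assemble(mesh, dofmap, state, cfg)
        r_f = residual[free]
        rnorm = float(np.linalg.norm(r_f))
        res_norms.append(rnorm)
        if res0 is None:
            res0 = max(rnorm, 1e-30)
        best = min(best, rnorm)
        if rnorm / res0 <= cfg.rel_resid_tol:
            converged = True
            inc_hist.append({f: 0.0 for f in FIELDS})
            break
        if rnorm > 1e4 * max(best, 1.0) or not np.isfinite(rnorm):
            message = f"residual diverged at iteration {it} (|R| = {rnorm:.3g})"
            inc_hist.append({f: np.nan for f in FIELDS})
            break

        j_ff = jac[free][:, free].tocsc()
        try:
            lu = splu(j_ff)
        except RuntimeError as err:
            message = f"singular Jacobian at iteration {it}: {err}"
            inc_hist.append({f: np.nan for f in FIELDS})
            break
        delta_f = lu.solve(-r_f)

        # backtracking under-relaxation on the residual norm
        omega = cfg.relaxation
        trial = state.copy()
        for _ in range(5):
            trial.vec[free] = state.vec[free] + omega * delta_f
            r_try, _ = assemble(mesh, dofmap, trial, cfg, residual_only=True)
            if np.linalg.norm(r_try[free]) <= (1.0 + 1e-8) * rnorm or omega <= 0.1:
                break
            omega *= 0.5
        delta = np.zeros(dofmap.n_dofs)
        delta[free] = omega * delta_f
        state.vec[free] += omega * delta_f

        sums = {f: float(np.sum(np.abs(arr))) for f, arr in dofmap.split(delta).items()}
        inc_hist.append(sums)
        # Eq-style stopping rule: summed absolute nodal change per field
        fields_ok = (
            max(sums["u"], sums["v"]) <= cfg.tol
            and sums["p"] <= cfg.tol
            and max(sums["s11"], sums["s12"], sums["s22"]) <= cfg.tol
        )
        if fields_ok:
            converged = True
            r_fin, _ = assemble(mesh, dofmap, state, cfg, residual_only=True)
            res_norms.append(float(np.linalg.norm(r_fin[free])))
            break

    if not converged and not message:
        message = f"no convergence in {cfg.max_newton} iterations"
    return state, NewtonHistory(
        converged=converged,
        iterations=len(inc_hist),
        residual_norms=res_norms,
        increments=inc_hist,
        message=message,
    )


def _re_schedule(re_target: float, start: float = 200.0) -> list[float]:
    """Monotone Reynolds continuation ladder ending at the target."""
    if re_target <= start:
        return [re_target]
    steps = [start]
    while steps[-1] * 2.5 < re_target:
        steps.append(steps[-1] * 2.5)
    steps.append(re_target)
    return steps


def continuation_solve(
    mesh: TriMesh,
    dofmap: DOFMap,
    cfg: SolverConfig,
    initial_state: FlowState | None = None,
    schedule: list[float] | None = None,
):
    """Solve at cfg.re via Reynolds continuation, warm-starting each stage.

    Returns the final state and the list of per-stage histories; raises
    ``RuntimeError`` at the last stable continuation point on divergence.
    """
    stages = schedule if schedule is not None else _re_schedule(cfg.re)
    state = initial_state
    histories = []
    for re_k in stages:
        cfg_k = replace(cfg, re=float(re_k))
        state, hist = newton_solve(mesh, dofmap, cfg_k, state)
        histories.append((re_k, hist))
        if not hist.converged:
            raise RuntimeError(
                f"continuation failed at Re={re_k:g}: {hist.message}; "
                f"last stable point Re={stages[max(stages.index(re_k) - 1, 0)]:g}"
            )
    return state, histories


def _as_geometry(model) -> ChannelGeometry:
    if isinstance(model, ChannelGeometry):
        return model
    if isinstance(model, (StenosisSpec, AneurysmSpec)):
        return build_channel(model)
    if model == "stenosis":
        return build_channel(StenosisSpec())
    if model == "aneurysm":
        return build_channel(AneurysmSpec())
    raise ValueError(f"unknown model {model!r}")


def solve_case(
    model,
    case: str | CaseConfig = "gen_oldroyd_b",
    re: float = 1000.0,
    wi: float = 0.6,
    h_far: float = 0.4,
    h_lesion: float = 0.15,
    mesh: TriMesh | None = None,
    initial_state: FlowState | None = None,
    **cfg_kwargs,
):
    """One converged operating point for a vessel model and constitutive case.

    Returns ``(state, geometry, histories, config)``; reuses Reynolds
    continuation from low Re (and warm starts when ``initial_state`` is
    given, e.g. along a Reynolds sweep).
    """
    geom = _as_geometry(model)
    if mesh is None:
        mesh = mesh_channel(geom, h_far=h_far, h_lesion=h_lesion)
    dofmap = DOFMap(mesh.n_nodes, mesh.n_corners)
    case_cfg = case if isinstance(case, CaseConfig) else CaseConfig(canonical_case(case))
    cfg_kwargs.setdefault("h_est", h_far)
    cfg = SolverConfig(re=re, wi=wi, case=case_cfg, **cfg_kwargs)
    if initial_state is not None:
        schedule = [re]
    else:
        schedule = None
    state, histories = continuation_solve(
        mesh, dofmap, cfg, initial_state=initial_state, schedule=schedule
    )
    if not np.all(np.isfinite(state.vec)):
        raise RuntimeError("non-finite values in converged state")
    return state, geom, histories, cfg


# ---------------------------------------------------------------------------
# flux


def flux(state: FlowState, x: float | None = None, station_index: int | None = None) -> float:
    """Volumetric flux (line integral of axial velocity) at a cross-section.

    The station snaps to the nearest mesh line, where the integral of the
    quadratic velocity trace is evaluated exactly by Simpson's rule on each
    crossed edge.
    """
    mesh = state.mesh
    md = mesh.metadata
    if "corner_grid" not in md:
        raise ValueError("flux requires a structured channel mesh")
    xs = md["x_stations"]
    if station_index is None:
        if x is None:
            raise ValueError("give either x or station_index")
        if x < xs[0] - 1e-12 or x > xs[-1] + 1e-12:
            raise ValueError(f"station x={x:g} outside the domain")
        station_index = int(np.argmin(np.abs(xs - x)))
    cg = md["corner_grid"][station_index]  # (ny+1,) corner node ids
    vm = md["vmid_grid"][station_index]  # (ny,) vertical midside ids
    y = mesh.coords[cg, 1]
    u_c = state.u[cg]
    u_m = state.u[vm]
    h = np.diff(y)
    return float(np.sum(h / 6.0 * (u_c[:-1] + 4.0 * u_m + u_c[1:])))
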