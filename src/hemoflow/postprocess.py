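"""Reported quantities derived from a converged flow state.

Velocity-magnitude and pressure profiles along the vessel axis, wall shear
stress along the bottom wall, recirculation-zone detection, and the
percent-deviation severity metrics ``100 (max - min)/max`` used to compare
stenotic against aneurysmal vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .geometry import ChannelGeometry, lesion_windows
from .solver import FlowState, SolverConfig, flux

__all__ = [
    "velocity_magnitude",
    "AxialProfile",
    "axial_profiles",
    "WSSCurve",
    "wall_shear_stress",
    "percent_deviation",
    "recirculation_zones",
    "build_metrics",
]


def velocity_magnitude(state: FlowState) -> np.ndarray:
    """Pointwise speed |U| = sqrt(u^2 + v^2) at every node."""
    return np.hypot(state.u, state.v)


@dataclass
class AxialProfile:
    """A quantity sampled along the vessel axis with metric windows attached.

    ``windows`` maps window names (``interior``, ``between``, ``lesion_span``)
    to closed x-intervals; ``mask(window)`` selects the stations inside one.
    """

    x: np.ndarray
    value: np.ndarray
    windows: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("stations must be strictly increasing")

    def mask(self, window: str) -> np.ndarray:
        lo, hi = self.windows[window]
        return (self.x >= lo - 1e-12) & (self.x <= hi + 1e-12)

    def extrema(self, window: str = "interior") -> tuple[float, float]:
        m = self.mask(window)
        return float(np.max(self.value[m])), float(np.min(self.value[m]))

    def extrema_with_locations(self, window: str = "interior"):
        """(max, x_of_max, min, x_of_min) over a window."""
        m = self.mask(window)
        xv, vv = self.x[m], self.value[m]
        imax, imin = int(np.argmax(vv)), int(np.argmin(vv))
        return float(vv[imax]), float(xv[imax]), float(vv[imin]), float(xv[imin])


def axial_profiles(
    state: FlowState, geom: ChannelGeometry, n_stations: int | None = None
) -> tuple[AxialProfile, AxialProfile]:
    """Speed and pressure sampled along the channel axis.

    The axis ``y = axis_y`` is a mesh line of the structured channel mesh, so
    the quadratic velocity trace is read off nodes (stations and
    half-stations) exactly; the linear pressure is read at corner stations
    and interpolated to half-stations.  ``n_stations`` optionally resamples
    both profiles onto a uniform grid by linear interpolation.
    """
    md = state.mesh.metadata
    if "corner_grid" not in md:
        raise ValueError("axial profiles require a structured channel mesh")
    ny = md["ny"]
    xs = md["x_stations"]
    mid_row = ny // 2
    corner_ids = md["corner_grid"][:, mid_row]
    hmid_ids = md["hmid_grid"][:, mid_row]
    # interleave stations and half-stations
    x_axis = np.empty(2 * len(xs) - 1)
    x_axis[0::2] = xs
    x_axis[1::2] = 0.5 * (xs[:-1] + xs[1:])
    node_ids = np.empty(2 * len(xs) - 1, dtype=int)
    node_ids[0::2] = corner_ids
    node_ids[1::2] = hmid_ids
    speed = velocity_magnitude(state)[node_ids]
    p_c = state.p[corner_ids]
    pressure = np.empty_like(x_axis)
    pressure[0::2] = p_c
    pressure[1::2] = 0.5 * (p_c[:-1] + p_c[1:])

    windows = lesion_windows(geom)
    if n_stations is not None:
        lo, hi = x_axis[0], x_axis[-1]
        xq = np.linspace(lo, hi, int(n_stations))
        if xq[0] < x_axis[0] or xq[-1] > x_axis[-1]:
            raise ValueError("requested station outside the domain")
        speed = np.interp(xq, x_axis, speed)
        pressure = np.interp(xq, x_axis, pressure)
        x_axis = xq
    return (
        AxialProfile(x=x_axis.copy(), value=speed, windows=windows),
        AxialProfile(x=x_axis.copy(), value=pressure, windows=windows),
    )


@dataclass
class WSSCurve:
    """Wall shear stress along the bottom wall.

    Sign convention: positive where the fluid drags the wall in the +x
    (mean-flow) direction; negative values mark reversed near-wall flow.
    ``s`` is the arc-length coordinate, ``x`` the axial position.
    """

    s: np.ndarray
    x: np.ndarray
    wss: np.ndarray

    def negative_intervals(self) -> list[tuple[float, float]]:
        return _sign_intervals(self.x, self.wss < 0.0)


def _sign_intervals(x: np.ndarray, flag: np.ndarray) -> list[tuple[float, float]]:
    """Maximal x-intervals where a boolean mask holds."""
    out = []
    i = 0
    n = len(x)
    while i < n:
        if flag[i]:
            j = i
            while j + 1 < n and flag[j + 1]:
                j += 1
            out.append((float(x[i]), float(x[j])))
            i = j + 1
        else:
            i += 1
    return out


def wall_shear_stress(state: FlowState, cfg: SolverConfig | None = None) -> WSSCurve:
    """Tangential deviatoric traction (sigma . n) . t along the bottom wall.

    The traction combines the Newtonian part ``2 nu_s V(U)`` with the
    elastic extra stress when present.  Velocity gradients are evaluated in
    the parent element of each wall edge with the quadratic basis; for
    Poiseuille flow the result matches the analytic wall gradient.
    """
    mesh = state.mesh
    rheo = cfg.rheology if cfg is not None else None

    # bottom-wall edges: wall edges whose nodes sit below the axis
    axis_y = mesh.metadata.get("axis_y", np.mean(mesh.coords[:, 1]))
    wall = mesh.boundary_tags == "wall"
    edges = mesh.boundary_edges[wall]
    mid_y = mesh.coords[edges[:, 2], 1]
    edges = edges[mid_y < axis_y]
    order = np.argsort(mesh.coords[edges[:, 2], 0])
    edges = edges[order]

    # map each edge to its parent element
    edge_key = {}
    for e, tri in enumerate(mesh.tris):
        for i1, i2 in ((0, 1), (1, 2), (2, 0)):
            a, b = int(tri[i1]), int(tri[i2])
            edge_key[(min(a, b), max(a, b))] = e

    detj, inv_jt = _fem.element_geometry(mesh.coords, mesh.tris)
    xs_list, s_list, wss_list = [], [], []
    s_acc = 0.0
    for a, b, m in edges:
        el = edge_key[(min(int(a), int(b)), max(int(a), int(b)))]
        tri = mesh.tris[el]
        pa, pb = mesh.coords[a], mesh.coords[b]
        t_vec = pb - pa
        elen = np.linalg.norm(t_vec)
        t_hat = t_vec / elen
        n_hat = np.array([t_hat[1], -t_hat[0]])  # outward (downward) normal
        # local (xi, eta) of the three sample points on this edge
        corners = mesh.coords[tri[:3]]
        A = np.column_stack([corners[1] - corners[0], corners[2] - corners[0]])
        Ainv = np.linalg.inv(A)
        pts = np.array([pa, 0.5 * (pa + pb), pb])
        loc = (Ainv @ (pts - corners[0]).T).T  # (3, 2) reference coords
        dref = _fem.p2_grad(loc[:, 0], loc[:, 1])  # (6, 2, 3)
        dphys = np.einsum("ik,akp->aip", inv_jt[el], dref)
        ue, ve = state.u[tri], state.v[tri]
        gxx = ue @ dphys[:, 0, :]
        gxy = ue @ dphys[:, 1, :]
        gyx = ve @ dphys[:, 0, :]
        gyy = ve @ dphys[:, 1, :]
        v11, v12, v22 = gxx, 0.5 * (gxy + gyx), gyy
        gd = np.sqrt(np.maximum(2.0 * (v11**2 + v22**2) + 4.0 * v12**2, 0.0))
        nus = rheo.nu_s(gd) if rheo is not None else np.ones(3)
        s11 = 2.0 * nus * v11
        s12 = 2.0 * nus * v12
        s22 = 2.0 * nus * v22
        # the elastic extra stress is nodal data; include it (zero if inelastic)
        phi = _fem.p2_basis(loc[:, 0], loc[:, 1])  # (6, 3)
        s11 = s11 + state.s11[tri] @ phi
        s12 = s12 + state.s12[tri] @ phi
        s22 = s22 + state.s22[tri] @ phi
        tx = s11 * n_hat[0] + s12 * n_hat[1]
        ty = s12 * n_hat[0] + s22 * n_hat[1]
        tau = -(tx * t_hat[0] + ty * t_hat[1])  # positive = forward drag
        pts_s = s_acc + np.array([0.0, 0.5 * elen, elen])
        s_acc += elen
        xs_list.append(pts[:, 0])
        s_list.append(pts_s)
        wss_list.append(tau)

    s = np.concatenate(s_list)
    x = np.concatenate(xs_list)
    w = np.concatenate(wss_list)
    # deduplicate shared edge endpoints
    keep = np.concatenate([[True], np.diff(s) > 1e-14])
    return WSSCurve(s=s[keep], x=x[keep], wss=w[keep])


def percent_deviation(a: float, b: float) -> float:
    """Severity metric 100*(a - b)/a between two extrema (a the reference)."""
    if a == 0:
        raise ZeroDivisionError("reference extremum must be non-zero")
    return 100.0 * (a - b) / a


def recirculation_zones(
    state: FlowState, cfg: SolverConfig | None = None
) -> dict[str, list[tuple[float, float]]]:
    """Reversed-flow intervals along the bottom wall.

    Two detectors: maximal x-intervals of negative wall shear stress, and of
    negative near-wall axial velocity (first node layer off the wall); both
    are empty when the minimum wall WSS is non-negative.
    """
    wss = wall_shear_stress(state, cfg)
    by_wss = wss.negative_intervals()
    md = state.mesh.metadata
    if "corner_grid" in md:
        layer = md["corner_grid"][:, 1]
        xs = md["x_stations"]
        neg = state.u[layer] < 0.0
        by_vel = _sign_intervals(xs, neg)
    else:
        by_vel = []
    return {"wss": by_wss, "near_wall_velocity": by_vel}


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def build_metrics(
    state: FlowState,
    geom: ChannelGeometry,
    cfg: SolverConfig,
) -> dict:
    """One MetricsTable row for a converged run.

    Extrema conventions: velocity max is the masked global maximum along the
    axis (one channel height excluded at each end), velocity min is taken
    over the closed between-lesion window; pressure extrema are reported for
    both the between-lesion and full lesion-span windows with the outlet
    pressure datum at zero.
    """
    speed, pressure = axial_profiles(state, geom)
    vmax, vmax_x, _, _ = speed.extrema_with_locations("interior")
    _, _, vmin_between, vmin_between_x = speed.extrema_with_locations("between")
    pmax_b, _, pmin_b, _ = pressure.extrema_with_locations("between")
    pmax_span, pmax_span_x, pmin_span, pmin_span_x = pressure.extrema_with_locations(
        "lesion_span"
    )
    wss = wall_shear_stress(state, cfg)
    zones = recirculation_zones(state, cfg)
    m_between = speed.mask("between")
    mean_between = float(np.trapezoid(speed.value[m_between], speed.x[m_between])) / (
        speed.x[m_between][-1] - speed.x[m_between][0]
    )
    q_in = flux(state, station_index=0)
    q_out = flux(state, station_index=len(state.mesh.metadata["x_stations"]) - 1)
    recirc_extent = sum(hi - lo for lo, hi in zones["wss"])
    row = {
        "model": geom.model,
        "case": cfg.case.case,
        "re": cfg.re,
        "wi": cfg.wi,
        "u_in": cfg.u_in,
        "umax_axis": vmax,
        "umax_axis_x": vmax_x,
        "umin_between": vmin_between,
        "umin_between_x": vmin_between_x,
        "velocity_deviation_pct": percent_deviation(vmax, vmin_between),
        "mean_u_between": mean_between,
        "pmax_between": pmax_b,
        "pmin_between": pmin_b,
        "pmax_lesion_span": pmax_span,
        "pmax_lesion_span_x": pmax_span_x,
        "pmin_lesion_span": pmin_span,
        "pmin_lesion_span_x": pmin_span_x,
        "pressure_deviation_pct": (
            percent_deviation(pmax_b, pmin_b) if pmax_b != 0 else np.nan
        ),
        "wss_max": float(np.max(wss.wss)),
        "wss_max_x": float(wss.x[np.argmax(wss.wss)]),
        "wss_min": float(np.min(wss.wss)),
        "wss_min_x": float(wss.x[np.argmin(wss.wss)]),
        "flux_in": q_in,
        "flux_out": q_out,
        "flux_mismatch_rel": abs(q_in - q_out) / max(abs(q_in), 1e-30),
        "n_recirc_zones": len(zones["wss"]),
        "recirc_extent": recirc_extent,
        "n_elements": state.mesh.n_elements,
        "n_dofs": state.dofmap.n_dofs,
    }
    return row
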