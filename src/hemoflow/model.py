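"""Model/Results front end for one steady blood-flow simulation.

:class:`ArterialFlowModel` bundles a vessel geometry, a constitutive case
and an operating point (Re, Wi, inflow); ``fit()`` meshes the channel,
solves the steady system by Newton iteration with Reynolds continuation and
returns an :class:`ArterialFlowResults` carrying the flow state, the
convergence history, the severity metrics and plotting/export helpers.

Example
-------
>>> from hemoflow import ArterialFlowModel
>>> res = ArterialFlowModel("stenosis", case="gen_oldroyd_b", re=1000, wi=0.6).fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .geometry import AneurysmSpec, ChannelGeometry, StenosisSpec, build_channel
from .mesh import DOFMap, mesh_channel, validate_mesh
from .postprocess import (
    axial_profiles,
    build_metrics,
    recirculation_zones,
    wall_shear_stress,
)
from .rheology import CaseConfig, canonical_case
from .solver import FlowState, SolverConfig, continuation_solve, flux

__all__ = ["ArterialFlowModel", "ArterialFlowResults"]


class ArterialFlowModel:
    """A steady channel-hemodynamics problem ready to be solved.

    Parameters
    ----------
    geometry : "stenosis" | "aneurysm" | StenosisSpec | AneurysmSpec | ChannelGeometry
        Vessel model; string tags use the default two-lesion specs.
    case : constitutive case tag or CaseConfig
    re, wi : operating point (0 < Re <= 3000, 0 <= Wi <= 1)
    u_in : dimensionless inlet mean velocity
    h_far, h_lesion : target mesh spacings away from / inside lesion bands
    solver_options : forwarded to SolverConfig (tol, max_newton, stabilize, ...)
    """

    def __init__(
        self,
        geometry="stenosis",
        case: str | CaseConfig = "gen_oldroyd_b",
        re: float = 1000.0,
        wi: float = 0.6,
        u_in: float = 0.0608,
        h_far: float = 0.4,
        h_lesion: float = 0.15,
        **solver_options: Any,
    ):
        if isinstance(geometry, ChannelGeometry):
            self.geometry = geometry
        elif isinstance(geometry, (StenosisSpec, AneurysmSpec)):
            self.geometry = build_channel(geometry)
        elif geometry == "stenosis":
            self.geometry = build_channel(StenosisSpec())
        elif geometry == "aneurysm":
            self.geometry = build_channel(AneurysmSpec())
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        self.case = case if isinstance(case, CaseConfig) else CaseConfig(canonical_case(case))
        self.re = float(re)
        self.wi = float(wi)
        self.u_in = float(u_in)
        self.h_far = float(h_far)
        self.h_lesion = float(h_lesion)
        self.solver_options = solver_options
        self._mesh = None

    @classmethod
    def from_config(cls, config: dict) -> "ArterialFlowModel":
        """Build a model from a flat configuration mapping (e.g. YAML)."""
        cfg = dict(config)
        geometry = cfg.pop("model", cfg.pop("geometry", "stenosis"))
        return cls(geometry=geometry, **cfg)

    @property
    def mesh(self):
        if self._mesh is None:
            self._mesh = mesh_channel(self.geometry, h_far=self.h_far, h_lesion=self.h_lesion)
        return self._mesh

    def solver_config(self) -> SolverConfig:
        opts = dict(self.solver_options)
        opts.setdefault("h_est", self.h_far)
        return SolverConfig(
            re=self.re, wi=self.wi, case=self.case, u_in=self.u_in, **opts
        )

    def fit(self, initial_state: FlowState | None = None, schedule=None) -> "ArterialFlowResults":
        """Solve the steady system; raises on failed continuation."""
        mesh = self.mesh
        dofmap = DOFMap(mesh.n_nodes, mesh.n_corners)
        cfg = self.solver_config()
        state, histories = continuation_solve(
            mesh, dofmap, cfg, initial_state=initial_state, schedule=schedule
        )
        metrics = build_metrics(state, self.geometry, cfg)
        return ArterialFlowResults(
            model=self, state=state, config=cfg, histories=histories, metrics=metrics
        )


@dataclass
class ArterialFlowResults:
    """Converged flow solution with severity metrics and diagnostics."""

    model: ArterialFlowModel
    state: FlowState
    config: SolverConfig
    histories: list
    metrics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(h.converged for _, h in self.histories)

    @property
    def newton_iterations(self) -> int:
        return sum(h.iterations for _, h in self.histories)

    def axial_profiles(self, n_stations: int | None = None):
        return axial_profiles(self.state, self.model.geometry, n_stations)

    def wall_shear_stress(self):
        return wall_shear_stress(self.state, self.config)

    def recirculation_zones(self):
        return recirculation_zones(self.state, self.config)

    def flux(self, x: float):
        return flux(self.state, x=x)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.metrics])

    def convergence_frame(self) -> pd.DataFrame:
        frames = []
        for re_k, hist in self.histories:
            df = hist.to_frame()
            df.insert(0, "re_stage", re_k)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_vtu(self, path) -> None:
        from .vtkio import write_state_vtu

        write_state_vtu(path, self.state, self.config.rheology)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        m = self.metrics
        rep = validate_mesh(self.state.mesh)
        lines = [
            "Steady arterial flow results",
            "=" * 60,
            f"model:            {m['model']} ({len(self.model.geometry.lesions)} lesions)",
            f"constitutive case:{m['case']:>18s}",
            f"Re = {m['re']:g}   Wi = {m['wi']:g}   inlet mean U = {m['u_in']:g}",
            f"mesh: {self.state.mesh.n_elements} elements, "
            f"{self.state.mesh.n_nodes} nodes (min angle {rep.min_angle_deg:.1f} deg)",
            f"Newton iterations (all continuation stages): {self.newton_iterations}",
            f"converged: {self.converged}",
            "-" * 60,
            f"max |U| on axis (interior):      {m['umax_axis']:.4f}",
            f"min |U| between lesions:         {m['umin_between']:.4f}",
            f"velocity deviation:              {m['velocity_deviation_pct']:.2f} %",
            f"pressure extrema between lesions: {m['pmin_between']:.4f} .. {m['pmax_between']:.4f}",
            f"WSS extrema: {m['wss_min']:.4f} (x={m['wss_min_x']:.2f}) .. "
            f"{m['wss_max']:.4f} (x={m['wss_max_x']:.2f})",
            f"recirculation zones (neg. WSS): {m['n_recirc_zones']} "
            f"(total extent {m['recirc_extent']:.2f})",
            f"flux in/out: {m['flux_in']:.6g} / {m['flux_out']:.6g} "
            f"(rel. mismatch {m['flux_mismatch_rel']:.2e})",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_profiles(self, path=None):
        """Axis speed and pressure profiles; saves to path if given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        speed, pressure = self.axial_profiles()
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        ax1.plot(speed.x, speed.value)
        ax1.set_ylabel("|U| on axis")
        ax2.plot(pressure.x, pressure.value)
        ax2.set_ylabel("p on axis")
        ax2.set_xlabel("x")
        for ax in (ax1, ax2):
            for lo, hi in (l["interval"] for l in self.model.geometry.lesions):
                ax.axvspan(lo, hi, alpha=0.15, color="red")
        fig.suptitle(
            f"{self.metrics['model']} / {self.metrics['case']} "
            f"(Re={self.metrics['re']:g}, Wi={self.metrics['wi']:g})"
        )
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig

    def plot_wss(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        wss = self.wall_shear_stress()
        fig, ax = plt.subplots(figsize=(8, 3.5))
        ax.plot(wss.x, wss.wss)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("x")
        ax.set_ylabel("WSS (bottom wall)")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig
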