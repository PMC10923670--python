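"""Parametric 2D channel geometries with serial stenoses or serial aneurysms.

A vessel is modelled as a straight channel of full height ``D`` (equivalently
healthy half-height ``R0 = D/2``) whose walls are perturbed by one or more
axisymmetric lesions:

* a *stenosis* is a cosine-shaped wall intrusion of depth ``eps``:
  inside a lesion interval of length ``Ls`` centred at ``x_c`` the local
  half-height is ``0.5*D*(1 - (eps/D)*(1 + cos(pi*M(x))))`` with
  ``M(x) = 2*(x - x_c)/Ls`` mapping the interval to [-1, 1];
* an *aneurysm* is a quartic-polynomial outward bulge: with
  ``t = (x - l0)/la`` in [0, 1] the radius ratio is
  ``h_a(t) = 1 + (eps/(2*R0)) * (11 t - 47 t^2 + 72 t^3 - 36 t^4)``,
  which vanishes at both lesion ends so the wall is continuous.

All coordinates are dimensionless (channel heights); the channel axis sits at
``y = D/2`` and walls are mirror images about it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
from scipy import optimize

__all__ = [
    "StenosisSpec",
    "AneurysmSpec",
    "ChannelGeometry",
    "stenosis_half_height",
    "aneurysm_radius_ratio",
    "aneurysm_half_height",
    "build_channel",
    "lesion_landmarks",
]

# Coefficients of the bulge polynomial 11 t - 47 t^2 + 72 t^3 - 36 t^4.
_BULGE_POLY = np.array([-36.0, 72.0, -47.0, 11.0, 0.0])
_BULGE_DPOLY = np.polyder(_BULGE_POLY)


def _check_intervals(intervals: list[tuple[float, float]], length: float) -> None:
    intervals = sorted(intervals)
    for lo, hi in intervals:
        if lo < 0.0 or hi > length:
            raise ValueError(
                f"lesion interval [{lo:g}, {hi:g}] falls outside the domain "
                f"[0, {length:g}]"
            )
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError(
                f"lesion intervals [{lo1:g}, {hi1:g}] and [{lo2:g}, {hi2:g}] overlap"
            )


@dataclass(frozen=True)
class StenosisSpec:
    """Serial cosine stenoses in a channel of full height ``D``.

    Defaults give a two-stenosis vessel: unit-length lesions centred at
    x = 7 and 9 in a channel of height 2 and length 16, leaving entrance and
    exit runs of more than three channel heights.
    """

    D: float = 2.0
    eps: float = 0.5
    centers: tuple[float, ...] = (7.0, 9.0)
    Ls: float = 1.0
    domain_length: float = 16.0

    def __post_init__(self):
        object.__setattr__(self, "centers", tuple(float(c) for c in self.centers))
        if self.D <= 0:
            raise ValueError("channel height D must be positive")
        if not 0.0 <= self.eps < 0.5 * self.D:
            raise ValueError(
                f"stenosis depth eps={self.eps:g} must satisfy 0 <= eps < D/2 "
                f"= {0.5 * self.D:g} (channel must not close)"
            )
        if self.Ls <= 0:
            raise ValueError("lesion length Ls must be positive")
        _check_intervals(self.intervals, self.domain_length)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        h = 0.5 * self.Ls
        return [(c - h, c + h) for c in self.centers]

    @property
    def axis_y(self) -> float:
        return 0.5 * self.D


@dataclass(frozen=True)
class AneurysmSpec:
    """Serial quartic-polynomial aneurysms on a vessel of half-height ``R0``."""

    R0: float = 1.0
    eps: float = 0.5
    l0_list: tuple[float, ...] = (6.5, 8.5)
    la: float = 1.0
    domain_length: float = 16.0

    def __post_init__(self):
        object.__setattr__(self, "l0_list", tuple(float(v) for v in self.l0_list))
        if self.R0 <= 0:
            raise ValueError("healthy half-height R0 must be positive")
        if self.la <= 0:
            raise ValueError("lesion length la must be positive")
        if self.eps < 0:
            raise ValueError("bulge amplitude eps must be non-negative")
        _check_intervals(self.intervals, self.domain_length)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return [(l0, l0 + self.la) for l0 in self.l0_list]

    @property
    def axis_y(self) -> float:
        return self.R0

    @property
    def D(self) -> float:
        return 2.0 * self.R0


def stenosis_half_height(x, spec: StenosisSpec):
    """Local half-height of the stenosed channel at axial position(s) ``x``.

    Inside a lesion interval the cosine intrusion reaches its maximum depth
    ``eps`` at the lesion centre (throat half-height ``D/2 - eps``); outside
    every lesion the healthy half-height ``D/2`` is returned.  The profile is
    C0-continuous at the interval ends.
    """
    x = np.asarray(x, dtype=float)
    y = np.full(x.shape, 0.5 * spec.D)
    for c in spec.centers:
        m = 2.0 * (x - c) / spec.Ls
        inside = np.abs(m) <= 1.0
        y = np.where(
            inside,
            0.5 * spec.D * (1.0 - (spec.eps / spec.D) * (1.0 + np.cos(np.pi * m))),
            y,
        )
    return y if y.shape else float(y)


def aneurysm_radius_ratio(x, spec: AneurysmSpec):
    """Radius ratio h_a(x) = R(x)/R0 of the aneurysmal vessel.

    Equals 1 outside every lesion interval and
    ``1 + (eps/(2 R0)) * (11 t - 47 t^2 + 72 t^3 - 36 t^4)`` with
    ``t = (x - l0)/la`` inside; >= 1 everywhere for eps > 0 since the quartic
    is non-negative on [0, 1].
    """
    x = np.asarray(x, dtype=float)
    h = np.ones(x.shape)
    amp = spec.eps / (2.0 * spec.R0)
    for l0 in spec.l0_list:
        t = (x - l0) / spec.la
        inside = (t >= 0.0) & (t <= 1.0)
        h = np.where(inside, 1.0 + amp * np.polyval(_BULGE_POLY, np.clip(t, 0, 1)), h)
    return h if h.shape else float(h)


def aneurysm_half_height(x, spec: AneurysmSpec):
    """Local half-height R0*h_a(x) of the aneurysmal channel."""
    return spec.R0 * aneurysm_radius_ratio(x, spec)


def half_height(x, spec):
    """Half-height profile for either spec kind."""
    if isinstance(spec, StenosisSpec):
        return stenosis_half_height(x, spec)
    if isinstance(spec, AneurysmSpec):
        return aneurysm_half_height(x, spec)
    raise TypeError(f"unsupported spec type {type(spec).__name__}")


def lesion_landmarks(spec) -> list[dict]:
    """Per-lesion wall-profile extrema and standard landmark values.

    For each lesion the throat (stenosis) or apex (aneurysm) is located by a
    dense scan refined with bounded scalar minimisation.  For aneurysms the
    radius ratio is also reported at the midpoint ``l0 + la/2`` and at the
    abscissae ``l0 + la/6`` and ``l0 + 5 la/6``.

    Note: the bulge polynomial evaluated at the midpoint gives a wall
    excursion of ``eps/4`` (ratio excess ``eps/(4 R0)``), not ``3 eps/4``;
    the true values are reported, see docs/methods.md.
    """
    out = []
    for k, (lo, hi) in enumerate(spec.intervals):
        if isinstance(spec, StenosisSpec):
            f = lambda x: stenosis_half_height(x, spec)
            res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded")
            grid = np.linspace(lo, hi, 401)
            vals = f(grid)
            xb = grid[np.argmin(vals)]
            x_star = res.x if res.fun <= np.min(vals) else xb
            out.append(
                {
                    "kind": "stenosis",
                    "index": k,
                    "interval": (lo, hi),
                    "apex_x": float(x_star),
                    "apex_half_height": float(f(x_star)),
                }
            )
        else:
            f = lambda x: -aneurysm_radius_ratio(x, spec)
            res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded")
            grid = np.linspace(lo, hi, 401)
            vals = f(grid)
            xb = grid[np.argmin(vals)]
            x_star = res.x if res.fun <= np.min(vals) else xb
            mid = lo + 0.5 * spec.la
            out.append(
                {
                    "kind": "aneurysm",
                    "index": k,
                    "interval": (lo, hi),
                    "apex_x": float(x_star),
                    "apex_half_height": float(spec.R0 * aneurysm_radius_ratio(x_star, spec)),
                    "ratio_at_midpoint": float(aneurysm_radius_ratio(mid, spec)),
                    "ratio_at_sixth": float(
                        aneurysm_radius_ratio(lo + spec.la / 6.0, spec)
                    ),
                    "ratio_at_five_sixths": float(
                        aneurysm_radius_ratio(lo + 5.0 * spec.la / 6.0, spec)
                    ),
                }
            )
    return out


@dataclass
class ChannelGeometry:
    """Tagged closed boundary polyline of a lesioned channel.

    The boundary is walked counter-clockwise: bottom wall left-to-right,
    outlet upwards, top wall right-to-left, inlet downwards.  Upper and lower
    walls are mirror images about the axis ``y = axis_y``.
    """

    spec: StenosisSpec | AneurysmSpec
    x_samples: np.ndarray
    half: np.ndarray  # half-height at each sample
    lesions: list[dict] = field(default_factory=list)

    @property
    def length(self) -> float:
        return float(self.spec.domain_length)

    @property
    def axis_y(self) -> float:
        return self.spec.axis_y

    @property
    def model(self) -> str:
        return "stenosis" if isinstance(self.spec, StenosisSpec) else "aneurysm"

    def half_height(self, x):
        return half_height(x, self.spec)

    def lower_wall(self, x):
        return self.axis_y - self.half_height(x)

    def upper_wall(self, x):
        return self.axis_y + self.half_height(x)

    def boundary_polyline(self) -> tuple[np.ndarray, list[str]]:
        """Closed CCW polyline (points, per-segment tags).

        Returns the polyline vertices (first point not repeated) and one tag
        per edge, in walking order.
        """
        xs = self.x_samples
        bottom = np.column_stack([xs, self.axis_y - self.half])
        top = np.column_stack([xs[::-1], (self.axis_y + self.half)[::-1]])
        pts = np.vstack([bottom, top])
        tags = (
            ["wall"] * (len(xs) - 1)
            + ["outlet"]
            + ["wall"] * (len(xs) - 1)
            + ["inlet"]
        )
        return pts, tags

    def to_csv(self, path) -> None:
        """Write the boundary polyline as a plain two-column CSV."""
        pts, _ = self.boundary_polyline()
        closed = np.vstack([pts, pts[:1]])
        np.savetxt(path, closed, delimiter=",", header="x,y", comments="")

    def to_geo(self, path, h: float = 0.2) -> None:
        """Write a Gmsh .geo-style tagged curve loop."""
        pts, tags = self.boundary_polyline()
        lines = ["// hemoflow channel geometry"]
        for i, (x, y) in enumerate(pts, start=1):
            lines.append(f"Point({i}) = {{{x:.17g}, {y:.17g}, 0, {h:g}}};")
        n = len(pts)
        for i in range(n):
            lines.append(f"Line({i + 1}) = {{{i + 1}, {(i + 1) % n + 1}}};")
        lines.append(
            "Curve Loop(1) = {" + ", ".join(str(i + 1) for i in range(n)) + "};"
        )
        lines.append("Plane Surface(1) = {1};")
        for tag in ("inlet", "outlet", "wall"):
            ids = [str(i + 1) for i, t in enumerate(tags) if t == tag]
            lines.append(f'Physical Curve("{tag}") = {{{", ".join(ids)}}};')
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_channel(spec, n_samples: int = 257) -> ChannelGeometry:
    """Sample a spec into a tagged, mirror-symmetric channel geometry.

    ``n_samples`` points are placed uniformly along the axis; each lesion
    must be resolved by at least four sample intervals or an error naming
    the lesion is raised.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    xs = np.linspace(0.0, spec.domain_length, int(n_samples))
    dx = xs[1] - xs[0]
    for k, (lo, hi) in enumerate(spec.intervals):
        if (hi - lo) / dx < 4.0:
            raise ValueError(
                f"sampling too coarse to resolve lesion {k} on [{lo:g}, {hi:g}]: "
                f"need at least {int(np.ceil(4 * (len(xs) - 1) * spec.domain_length / (hi - lo) / (len(xs) - 1)))} "
                f"samples per lesion (got spacing {dx:g})"
            )
    half = half_height(xs, spec)
    return ChannelGeometry(
        spec=spec, x_samples=xs, half=np.asarray(half), lesions=lesion_landmarks(spec)
    )


def lesion_windows(geom: ChannelGeometry) -> dict:
    """Axial windows used by the severity metrics.

    ``between``: closed interval between the first and last lesion apexes
    (lesion centres); ``lesion_span``: from the start of the first lesion to
    the end of the last; ``interior``: domain minus one channel height at
    each end (inlet/outlet exclusion).
    """
    d = 2.0 * geom.axis_y
    interior = (d, geom.length - d)
    if not geom.lesions:
        return {"between": interior, "lesion_span": interior, "interior": interior}
    apexes = [l["apex_x"] for l in geom.lesions]
    intervals = [l["interval"] for l in geom.lesions]
    return {
        "between": (min(apexes), max(apexes)),
        "lesion_span": (min(i[0] for i in intervals), max(i[1] for i in intervals)),
        "interior": interior,
    }
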