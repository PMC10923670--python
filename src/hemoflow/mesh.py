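"""Six-node triangular meshes on channel geometries, with graded refinement.

The channel is a mapped rectangle, so meshing is done structurally: axial
stations are laid out with a target spacing (``h_far`` away from lesions,
``h_lesion`` inside a padded band around each lesion), the transverse
direction is divided into an even number of layers, and each mapped quad is
split into two triangles with a diagonal pattern that is mirror-symmetric
about the channel axis.  Corner nodes carry the pressure; edge-midpoint
nodes complete the quadratic velocity/stress support.  Elements are
straight-sided, so curved walls are approximated by the boundary polyline
density.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .geometry import ChannelGeometry

__all__ = ["TriMesh", "DOFMap", "mesh_channel", "validate_mesh", "write_mesh", "read_msh"]

FIELDS = ("u", "v", "p", "s11", "s12", "s22")

# Gmsh element type codes
_GMSH_TRI6 = 9
_GMSH_LINE3 = 8
_TAG_CODES = {"inlet": 1, "outlet": 2, "wall": 3}
_CODE_TAGS = {v: k for k, v in _TAG_CODES.items()}


@dataclass
class TriMesh:
    """Quadratic triangle mesh with tagged boundary edges.

    Attributes
    ----------
    coords : (n_nodes, 2) node coordinates (corners first, then midsides)
    tris : (n_el, 6) connectivity; local order corners 0-2 then midsides
        3=(0,1), 4=(1,2), 5=(2,0)
    n_corners : number of corner (pressure-bearing) nodes
    boundary_edges : (n_b, 3) node triples (end, end, midside)
    boundary_tags : (n_b,) array of tag strings in {inlet, outlet, wall}
    metadata : structured-grid bookkeeping and geometry landmarks
    """

    coords: np.ndarray
    tris: np.ndarray
    n_corners: int
    boundary_edges: np.ndarray
    boundary_tags: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tris.shape[0]

    @property
    def is_corner(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[: self.n_corners] = True
        return mask

    def edges_with_tag(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    def signed_areas(self) -> np.ndarray:
        p0 = self.coords[self.tris[:, 0]]
        p1 = self.coords[self.tris[:, 1]]
        p2 = self.coords[self.tris[:, 2]]
        d1, d2 = p1 - p0, p2 - p0
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.coords).tobytes())
        h.update(np.ascontiguousarray(self.tris).tobytes())
        h.update(np.ascontiguousarray(self.boundary_edges).tobytes())
        h.update("".join(self.boundary_tags.tolist()).encode())
        return h.hexdigest()[:16]


@dataclass
class DOFMap:
    """Dense, disjoint global indices for (node, field) unknowns.

    Velocity and stress components are supported on all nodes; pressure only
    on corner nodes.
    """

    n_nodes: int
    n_corners: int

    @property
    def n2(self) -> int:
        return self.n_nodes

    @property
    def n1(self) -> int:
        return self.n_corners

    @property
    def offsets(self) -> dict:
        n2, n1 = self.n_nodes, self.n_corners
        return {
            "u": 0,
            "v": n2,
            "p": 2 * n2,
            "s11": 2 * n2 + n1,
            "s12": 3 * n2 + n1,
            "s22": 4 * n2 + n1,
        }

    @property
    def n_dofs(self) -> int:
        return 5 * self.n_nodes + self.n_corners

    def field_dofs(self, name: str, nodes=None) -> np.ndarray:
        off = self.offsets[name]
        if nodes is None:
            n = self.n_corners if name == "p" else self.n_nodes
            return off + np.arange(n)
        nodes = np.asarray(nodes)
        if name == "p" and np.any(nodes >= self.n_corners):
            raise ValueError("pressure unknowns exist only on corner nodes")
        return off + nodes

    def split(self, vec: np.ndarray) -> dict:
        out = {}
        for name, off in self.offsets.items():
            n = self.n_corners if name == "p" else self.n_nodes
            out[name] = vec[off : off + n]
        return out


def _grade_stations(geom: ChannelGeometry, h_far: float, h_lesion: float) -> np.ndarray:
    """Axial stations with spacing h_lesion in padded lesion bands, h_far outside."""
    length = geom.length
    pad = 0.5 * 2.0 * geom.axis_y  # half a channel height of padding
    bands = []
    for les in geom.lesions:
        lo, hi = les["interval"]
        bands.append((max(0.0, lo - pad), min(length, hi + pad)))
    # merge overlapping bands
    bands.sort()
    merged: list[list[float]] = []
    for lo, hi in bands:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    # breakpoints partition the axis into uniform-spacing segments; lesion
    # apexes are forced into the station set so the exact throat/bulge crest
    # is sampled
    bps = [0.0]
    for lo, hi in merged:
        bps.extend([lo, hi])
    bps.extend(les["apex_x"] for les in geom.lesions)
    bps.append(length)
    bps = sorted(set(bps))
    xs = [0.0]
    for lo, hi in zip(bps, bps[1:]):
        mid = 0.5 * (lo + hi)
        fine = any(blo - 1e-12 <= mid <= bhi + 1e-12 for blo, bhi in merged)
        h = h_lesion if fine else h_far
        n = max(1, int(np.ceil((hi - lo) / h)))
        xs.extend(np.linspace(lo, hi, n + 1)[1:].tolist())
    return np.array(xs)


def mesh_channel(
    geom: ChannelGeometry, h_far: float = 0.4, h_lesion: float = 0.15
) -> TriMesh:
    """Mesh a channel geometry with graded axial refinement at lesions.

    The transverse layer count is chosen so layers are about ``h_lesion``
    thick in the healthy channel; at least six element layers must span the
    narrowest throat, otherwise an error states the required ``h_lesion``.
    Deterministic: identical inputs produce identical meshes.
    """
    if h_lesion > h_far:
        raise ValueError("h_lesion must not exceed h_far")
    d = 2.0 * geom.axis_y
    min_half = float(np.min(geom.half))
    ny = int(np.ceil(d / h_lesion))
    ny += ny % 2
    ny = max(ny, 6)
    if ny < 6:  # pragma: no cover - ny is clamped above
        raise ValueError("fewer than 6 layers across the throat")
    if 2.0 * min_half / ny < h_lesion / 8.0:
        req = 2.0 * min_half / 6.0
        raise ValueError(
            f"throat (gap {2 * min_half:g}) unresolvable at h_lesion={h_lesion:g}; "
            f"need h_lesion <= {req:g}"
        )
    xs = _grade_stations(geom, h_far, h_lesion)
    nx = len(xs) - 1
    y_lo = geom.lower_wall(xs)
    y_up = geom.upper_wall(xs)

    # corner nodes
    fracs = np.arange(ny + 1) / ny
    corner_grid = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
    cx = np.repeat(xs, ny + 1)
    cy = (y_lo[:, None] + fracs[None, :] * (y_up - y_lo)[:, None]).ravel()
    corners = np.column_stack([cx, cy])
    n_corners = corners.shape[0]

    # triangles: mirror-symmetric diagonal pattern about the mid-layer
    tris_c = []
    half_ny = ny // 2
    for i in range(nx):
        for j in range(ny):
            a = corner_grid[i, j]
            b = corner_grid[i + 1, j]
            c = corner_grid[i, j + 1]
            dd = corner_grid[i + 1, j + 1]
            if j < half_ny:
                tris_c.append((a, b, dd))
                tris_c.append((a, dd, c))
            else:
                tris_c.append((a, b, c))
                tris_c.append((b, dd, c))
    tris_c = np.array(tris_c, dtype=np.int64)

    # midside nodes, shared through an edge dictionary
    mid_nodes: dict[tuple[int, int], int] = {}
    mid_coords: list[np.ndarray] = []

    def midside(n1: int, n2: int) -> int:
        key = (n1, n2) if n1 < n2 else (n2, n1)
        idx = mid_nodes.get(key)
        if idx is None:
            idx = n_corners + len(mid_coords)
            mid_nodes[key] = idx
            mid_coords.append(0.5 * (corners[n1] + corners[n2]))
        return idx

    tris = np.empty((tris_c.shape[0], 6), dtype=np.int64)
    tris[:, :3] = tris_c
    for e, (a, b, c) in enumerate(tris_c):
        tris[e, 3] = midside(a, b)
        tris[e, 4] = midside(b, c)
        tris[e, 5] = midside(c, a)
    coords = np.vstack([corners, np.array(mid_coords)])

    # boundary edges with tags
    b_edges = []
    b_tags = []
    for i in range(nx):  # bottom and top walls
        a, b = corner_grid[i, 0], corner_grid[i + 1, 0]
        b_edges.append((a, b, midside(a, b)))
        b_tags.append("wall")
        a, b = corner_grid[i, ny], corner_grid[i + 1, ny]
        b_edges.append((a, b, midside(a, b)))
        b_tags.append("wall")
    for j in range(ny):
        a, b = corner_grid[0, j], corner_grid[0, j + 1]
        b_edges.append((a, b, midside(a, b)))
        b_tags.append("inlet")
        a, b = corner_grid[nx, j], corner_grid[nx, j + 1]
        b_edges.append((a, b, midside(a, b)))
        b_tags.append("outlet")

    vmid = np.empty((nx + 1, ny), dtype=np.int64)
    for i in range(nx + 1):
        for j in range(ny):
            vmid[i, j] = midside(corner_grid[i, j], corner_grid[i, j + 1])
    hmid = np.empty((nx, ny + 1), dtype=np.int64)
    for i in range(nx):
        for j in range(ny + 1):
            hmid[i, j] = midside(corner_grid[i, j], corner_grid[i + 1, j])

    metadata = {
        "x_stations": xs,
        "ny": ny,
        "corner_grid": corner_grid,
        "vmid_grid": vmid,
        "hmid_grid": hmid,
        "axis_y": geom.axis_y,
        "model": geom.model,
        "lesions": geom.lesions,
        "domain_length": geom.length,
        "h_far": h_far,
        "h_lesion": h_lesion,
    }
    return TriMesh(
        coords=coords,
        tris=tris,
        n_corners=n_corners,
        boundary_edges=np.array(b_edges, dtype=np.int64),
        boundary_tags=np.array(b_tags),
        metadata=metadata,
    )


@dataclass
class MeshReport:
    min_angle_deg: float
    min_area: float
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_mesh(mesh: TriMesh) -> MeshReport:
    """Check mesh invariants; an empty violation list means acceptable."""
    violations: list[str] = []
    areas = mesh.signed_areas()
    if np.any(areas <= 0):
        violations.append(f"{int(np.sum(areas <= 0))} triangles with non-positive area")

    # midside nodes must sit at the corner-edge midpoints
    c = mesh.coords
    for loc, (i1, i2) in zip((3, 4, 5), ((0, 1), (1, 2), (2, 0))):
        expect = 0.5 * (c[mesh.tris[:, i1]] + c[mesh.tris[:, i2]])
        err = np.max(np.abs(c[mesh.tris[:, loc]] - expect)) if len(mesh.tris) else 0.0
        if err > 1e-12:
            violations.append(f"midside off edge midpoint (max error {err:g})")
            break

    # Euler relation on the corner graph of a simply connected mesh
    edges = set()
    for tri in mesh.tris[:, :3]:
        for i1, i2 in ((0, 1), (1, 2), (2, 0)):
            a, b = int(tri[i1]), int(tri[i2])
            edges.add((a, b) if a < b else (b, a))
    vset = {int(n) for tri in mesh.tris[:, :3] for n in tri}
    euler = len(vset) - len(edges) + mesh.n_elements
    if euler != 1:
        violations.append(f"Euler relation V-E+F = {euler}, expected 1")

    if len(mesh.boundary_tags) != len(set(map(tuple, mesh.boundary_edges))):
        violations.append("duplicate boundary edge tagging")
    for tag in set(mesh.boundary_tags.tolist()):
        if tag not in _TAG_CODES:
            violations.append(f"unknown boundary tag {tag!r}")

    # minimum angle
    p0 = c[mesh.tris[:, 0]]
    p1 = c[mesh.tris[:, 1]]
    p2 = c[mesh.tris[:, 2]]
    angles = []
    for a, b, cc in ((p0, p1, p2), (p1, p2, p0), (p2, p0, p1)):
        v1 = b - a
        v2 = cc - a
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    min_angle = float(np.min(angles)) if mesh.n_elements else 0.0
    return MeshReport(
        min_angle_deg=min_angle,
        min_area=float(np.min(areas)) if len(areas) else 0.0,
        violations=violations,
    )


def write_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as Gmsh MSH v2.2 (.msh) or VTK XML (.vtu), by extension."""
    path = str(path)
    if path.endswith(".msh"):
        _write_msh(mesh, path)
    elif path.endswith(".vtu"):
        from .vtkio import write_vtu

        write_vtu(path, mesh)
    else:
        raise ValueError(f"unsupported mesh format for {path!r} (use .msh or .vtu)")


def _write_msh(mesh: TriMesh, path: str) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.coords, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} 0")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(len(mesh.boundary_edges) + mesh.n_elements))
    eid = 1
    for (a, b, m), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
        code = _TAG_CODES[tag]
        lines.append(f"{eid} {_GMSH_LINE3} 2 {code} {code} {a + 1} {b + 1} {m + 1}")
        eid += 1
    for tri in mesh.tris:
        nodes = " ".join(str(n + 1) for n in tri)
        lines.append(f"{eid} {_GMSH_TRI6} 2 0 0 {nodes}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> TriMesh:
    """Read a Gmsh MSH v2.2 mesh written by :func:`write_mesh` (round-trip)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    coords = None
    tris = []
    b_edges = []
    b_tags = []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            coords = np.empty((n, 2))
            for _ in range(n):
                parts = next(it).split()
                coords[int(parts[0]) - 1] = [float(p) for p in parts[1:3]]
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                nodes = [int(p) - 1 for p in parts[3 + ntags :]]
                if etype == _GMSH_LINE3:
                    b_edges.append(nodes)
                    b_tags.append(_CODE_TAGS[int(parts[3])])
                elif etype == _GMSH_TRI6:
                    tris.append(nodes)
    tris = np.array(tris, dtype=np.int64)
    n_corners = int(np.max(tris[:, :3])) + 1 if len(tris) else 0
    return TriMesh(
        coords=coords,
        tris=tris,
        n_corners=n_corners,
        boundary_edges=np.array(b_edges, dtype=np.int64),
        boundary_tags=np.array(b_tags),
    )
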