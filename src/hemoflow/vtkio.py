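"""Minimal ASCII VTK XML (.vtu) writer for quadratic-triangle meshes.

Writes an unstructured grid with cell type 22 (quadratic triangle) and
optional point-data arrays, suitable for ParaView.  Boundary tags are not
stored in the .vtu (use the .msh format for lossless round-trips); a
`boundary` point array marks inlet/outlet/wall membership instead.
"""

from __future__ import annotations

import numpy as np

_VTK_QUADRATIC_TRIANGLE = 22


def write_vtu(path, mesh, point_data: dict | None = None) -> None:
    """Write mesh (and optional nodal fields) to an ASCII .vtu file.

    ``point_data`` maps array names to (n_nodes,) scalars or (n_nodes, 2)
    vectors; vectors are padded to three components.
    """
    point_data = dict(point_data or {})
    tag_code = {"inlet": 1.0, "outlet": 2.0, "wall": 3.0}
    marker = np.zeros(mesh.n_nodes)
    for (a, b, m), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
        for n in (a, b, m):
            marker[n] = tag_code[tag]
    point_data.setdefault("boundary", marker)

    def fmt(arr):
        return "\n".join(" ".join(f"{v:.12g}" for v in row) for row in np.atleast_2d(arr))

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        fmt(np.column_stack([mesh.coords, np.zeros(mesh.n_nodes)])),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(n) for n in tri) for tri in mesh.tris),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(6 * (i + 1)) for i in range(mesh.n_elements)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(_VTK_QUADRATIC_TRIANGLE) for _ in range(mesh.n_elements)),
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            ncomp = 1
            body = "\n".join(f"{v:.12g}" for v in arr)
        else:
            arr3 = np.column_stack([arr, np.zeros(arr.shape[0])]) if arr.shape[1] == 2 else arr
            ncomp = arr3.shape[1]
            body = fmt(arr3)
        lines.append(
            f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">'
        )
        lines.append(body)
        lines.append("</DataArray>")
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_state_vtu(path, state, rheology=None) -> None:
    """Write a flow state with velocity, pressure, stress, viscosity fields."""
    from .postprocess import velocity_magnitude

    mesh = state.mesh
    p_full = state.pressure_on_all_nodes()
    data = {
        "velocity": np.column_stack([state.u, state.v]),
        "speed": velocity_magnitude(state),
        "pressure": p_full,
        "sigma11": state.s11,
        "sigma12": state.s12,
        "sigma22": state.s22,
    }
    if rheology is not None:
        gd = state.nodal_shear_rate()
        data["shear_rate"] = gd
        data["viscosity"] = rheology.nu_s(gd)
    write_vtu(path, mesh, data)
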