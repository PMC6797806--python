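"""Minimal legacy-ASCII VTK writer for quad meshes with cell/point data.

Writes the DATASET UNSTRUCTURED_GRID dialect (VTK file version 2.0) so
fields can be inspected in ParaView/VisIt and diffed as plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Mesh

__all__ = ["write_vtk"]

_VTK_QUAD = 9


def write_vtk(
    path,
    mesh: Mesh,
    cell_data: dict | None = None,
    point_data: dict | None = None,
    title: str = "osteoadapt field snapshot",
) -> Path:
    """Write the mesh with optional per-element and per-node scalar fields.

    Cell data arrays must have one value per element (vector-valued point
    data with shape (n_nodes, 2) is written as 3-component vectors with a
    zero z-component).
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 2.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    for quad in mesh.elements:
        lines.append("4 " + " ".join(str(int(n)) for n in quad))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend([str(_VTK_QUAD)] * mesh.n_elements)

    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, values in cell_data.items():
            values = np.asarray(values)
            if values.shape != (mesh.n_elements,):
                raise ValueError(
                    f"cell data '{name}' has shape {values.shape}, "
                    f"expected ({mesh.n_elements},)")
            dtype = "int" if np.issubdtype(values.dtype, np.integer) else "double"
            lines.append(f"SCALARS {name} {dtype} 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" if dtype == "double" else str(int(v))
                         for v in values)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape == (mesh.n_nodes, 2):
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in values)
            elif values.shape == (mesh.n_nodes,):
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in values)
            else:
                raise ValueError(f"point data '{name}' has shape {values.shape}")
    path.write_text("\n".join(lines) + "\n")
    return path
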