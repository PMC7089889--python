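"""Minimal legacy-ASCII VTK export of the assembly mesh and solved fields.

Writes an unstructured grid of VTK_HEXAHEDRON cells with arbitrary point
and cell data arrays, viewable in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import AssemblyMesh

__all__ = ["write_vtk"]

_VTK_HEXAHEDRON = 12


def write_vtk(path: str | Path, mesh: AssemblyMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the mesh (and optional per-node / per-element arrays) as a
    legacy ASCII .vtk unstructured grid.  Vector arrays may be (n, 3);
    everything else is written as scalars."""
    path = Path(path)
    nn, ne = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "boneplug assembly",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nn} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {ne} {ne * 9}")
    lines += ["8 " + " ".join(map(str, e)) for e in mesh.elems]
    lines.append(f"CELL_TYPES {ne}")
    lines += [str(_VTK_HEXAHEDRON)] * ne

    def emit(block: str, n: int, data: dict[str, np.ndarray]) -> None:
        lines.append(f"{block} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != n:
                raise ValueError(f"array {name!r} has wrong length")
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr.ravel())

    base_cell = {"part": mesh.part.astype(float),
                 "slice_index": mesh.slice_index.astype(float)}
    if cell_data:
        base_cell.update(cell_data)
    emit("CELL_DATA", ne, base_cell)
    if point_data:
        emit("POINT_DATA", nn, point_data)
    path.write_text("\n".join(lines) + "\n")
    return path
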