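"""Minimal legacy-ASCII VTK writers for substrate and cell snapshots.

Only the two record types the simulator emits are supported: an
unstructured hexahedral grid with point data (substrate + displacement)
and a point cloud with scalar data (cell centroids).  The legacy VTK
text format is written directly; node ordering follows the VTK_HEXAHEDRON
convention used by the mesh builder.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem import SubstrateMesh

_VTK_HEXAHEDRON = 12
_VTK_VERTEX = 1


def _header(f, title: str) -> None:
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET UNSTRUCTURED_GRID\n")


def _write_points(f, points: np.ndarray) -> None:
    f.write(f"POINTS {len(points)} double\n")
    np.savetxt(f, np.asarray(points, dtype=float), fmt="%.9g")


def _write_point_data(f, n: int, data: dict[str, np.ndarray]) -> None:
    if not data:
        return
    f.write(f"POINT_DATA {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr[:, None], fmt="%.9g")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, arr, fmt="%.9g")
        else:
            raise ValueError(f"unsupported point-data shape {arr.shape} for {name!r}")


def write_unstructured_grid(
    path: str | Path,
    mesh: SubstrateMesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the substrate mesh (plus optional nodal fields) as legacy VTK."""
    with open(path, "w") as f:
        _header(f, "mechanofate substrate")
        _write_points(f, mesh.node_coords)
        conn = mesh.hex_connectivity
        f.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(mesh.n_elems, 8), conn]),
            fmt="%d",
        )
        f.write(f"CELL_TYPES {mesh.n_elems}\n")
        np.savetxt(f, np.full(mesh.n_elems, _VTK_HEXAHEDRON)[:, None], fmt="%d")
        _write_point_data(f, mesh.n_nodes, point_data or {})


def write_point_cloud(
    path: str | Path,
    points: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write cell centroids (one VTK vertex each) with per-cell scalars."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    with open(path, "w") as f:
        _header(f, "mechanofate cells")
        _write_points(f, points)
        f.write(f"CELLS {n} {2 * n}\n")
        np.savetxt(f, np.column_stack([np.ones(n, int), np.arange(n)]), fmt="%d")
        f.write(f"CELL_TYPES {n}\n")
        np.savetxt(f, np.full(n, _VTK_VERTEX)[:, None], fmt="%d")
        _write_point_data(f, n, point_data or {})
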