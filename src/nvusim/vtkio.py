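"""Minimal legacy-VTK (ASCII) structured-grid writer and reader.

The axisymmetric (r, z) mesh is written as a 2-D structured grid in
the x-y plane (x = r, y = z, z = 0) with cell data, readable by any
standard VTK structured-grid reader.  The bundled reader exists for
round-trip validation and quick inspection without a VTK dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh


def write_structured_grid(path: str | Path, mesh: Mesh,
                          cell_data: dict[str, np.ndarray]) -> Path:
    """Write the mesh and (nr, nz) cell arrays as legacy VTK ASCII."""
    path = Path(path)
    nr, nz = mesh.nr, mesh.nz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("nvusim axisymmetric (r,z) structured grid\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nr + 1} {nz + 1} 1\n")
        fh.write(f"POINTS {(nr + 1) * (nz + 1)} double\n")
        for z in mesh.z_faces:
            for r in mesh.r_faces:
                fh.write(f"{r:.12e} {z:.12e} 0.0\n")
        fh.write(f"CELL_DATA {nr * nz}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (nr, nz):
                raise ValueError(f"cell array '{name}' must have shape "
                                 f"({nr}, {nz})")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK cell order: fastest index along the first dimension (r)
            for j in range(nz):
                for i in range(nr):
                    fh.write(f"{arr[i, j]:.12e}\n")
    return path


def read_structured_grid(path: str | Path):
    """Read a file written by :func:`write_structured_grid`.

    Returns ``(points, dims, cell_data)`` with ``points`` of shape
    (n_points, 3), ``dims`` the (nx, ny, nz) point dimensions and
    ``cell_data`` a dict of (nr, nz) arrays.
    """
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    for line in it:
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(x) for x in line.split()[1:4])
            break
    else:
        raise ValueError("not a legacy VTK structured grid file")
    n_points_line = next(it)
    n_points = int(n_points_line.split()[1])
    points = np.array([[float(v) for v in next(it).split()]
                       for _ in range(n_points)])
    cell_data: dict[str, np.ndarray] = {}
    nr, nz = dims[0] - 1, dims[1] - 1
    name = None
    for line in it:
        if line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            vals = np.array([float(next(it)) for _ in range(nr * nz)])
            cell_data[name] = vals.reshape(nz, nr).T
    return points, dims, cell_data
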