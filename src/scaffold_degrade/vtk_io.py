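"""Minimal legacy-ASCII VTK unstructured-grid I/O for hexahedral meshes.

Supports exactly what the simulator needs: POINTS, CELLS/CELL_TYPES with
VTK_HEXAHEDRON (type 12), and scalar CELL_DATA arrays.  Volumes are computed
from the hex geometry and shared-face adjacency is recovered by hashing cell
faces, so a mesh file is a self-contained scaffold field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_vtk", "write_vtk", "field_from_vtk", "write_state_vtk"]

VTK_HEXAHEDRON = 12

# Face connectivity of VTK_HEXAHEDRON (nodes 0-3 bottom, 4-7 top).
_HEX_FACES = ((0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
              (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7))

# 5-tetrahedron decomposition of a hexahedron, for volume.
_HEX_TETS = ((0, 1, 3, 4), (1, 2, 3, 6), (1, 3, 4, 6), (1, 4, 5, 6), (3, 4, 6, 7))


def write_vtk(path: str | Path, points: np.ndarray, cells: np.ndarray,
              cell_data: dict[str, np.ndarray] | None = None,
              title: str = "scaffold") -> None:
    """Write hexahedral cells with optional scalar cell data (legacy ASCII)."""
    points = np.asarray(points, float)
    cells = np.asarray(cells, int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} float\n")
        for p in points:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {len(cells)} {len(cells) * 9}\n")
        for c in cells:
            f.write("8 " + " ".join(str(v) for v in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        f.writelines(f"{VTK_HEXAHEDRON}\n" for _ in cells)
        if cell_data:
            f.write(f"CELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, float):
                    f.write(f"{v:.9g}\n")


def read_vtk(path: str | Path):
    """Read a legacy ASCII unstructured grid of hexahedra.

    Returns ``(points, cells, cell_data)``.
    """
    tokens: list[str] = []
    with open(path) as f:
        lines = f.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise ValueError(f"{path}: not a legacy VTK file")
    if lines[2].strip().upper() != "ASCII":
        raise ValueError(f"{path}: only ASCII VTK is supported")
    for line in lines[3:]:
        tokens.extend(line.split())

    pos = 0

    def expect(keyword: str) -> None:
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != keyword:
            pos += 1
        if pos == len(tokens):
            raise ValueError(f"{path}: missing {keyword} section")
        pos += 1

    expect("DATASET")
    if tokens[pos].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"{path}: only UNSTRUCTURED_GRID is supported")

    expect("POINTS")
    n_pts = int(tokens[pos]); pos += 2  # skip dtype
    points = np.array(tokens[pos:pos + 3 * n_pts], float).reshape(n_pts, 3)
    pos += 3 * n_pts

    expect("CELLS")
    n_cells = int(tokens[pos]); total = int(tokens[pos + 1]); pos += 2
    flat = np.array(tokens[pos:pos + total], int)
    pos += total
    cells = []
    i = 0
    while i < flat.size:
        k = flat[i]
        if k != 8:
            raise ValueError(f"{path}: only 8-node hexahedra are supported, got {k}-node cell")
        cells.append(flat[i + 1:i + 9])
        i += k + 1
    cells = np.array(cells, int)
    if len(cells) != n_cells:
        raise ValueError(f"{path}: CELLS header count mismatch")

    expect("CELL_TYPES")
    n_types = int(tokens[pos]); pos += 1
    types = np.array(tokens[pos:pos + n_types], int)
    pos += n_types
    if np.any(types != VTK_HEXAHEDRON):
        raise ValueError(f"{path}: only VTK_HEXAHEDRON (12) cells are supported")

    cell_data: dict[str, np.ndarray] = {}
    while pos < len(tokens):
        if tokens[pos].upper() == "CELL_DATA":
            pos += 2
        elif tokens[pos].upper() == "SCALARS":
            name = tokens[pos + 1]
            pos += 3  # SCALARS name dtype [components assumed 1]
            if tokens[pos].isdigit():
                pos += 1
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            cell_data[name] = np.array(tokens[pos:pos + n_cells], float)
            pos += n_cells
        else:
            pos += 1
    return points, cells, cell_data


def hex_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Cell volumes via 5-tet decomposition (exact for trilinear hexes with
    planar faces, standard approximation otherwise)."""
    vols = np.zeros(len(cells))
    for a, b, c, d in _HEX_TETS:
        p = points[cells]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]),
            p[:, d] - p[:, a],
        )
        vols += np.abs(v) / 6.0
    return vols


def shared_face_neighbors(cells: np.ndarray) -> list[set]:
    """Adjacency by shared quadrilateral faces."""
    face_owner: dict[tuple, int] = {}
    nbrs: list[set] = [set() for _ in cells]
    for i, cell in enumerate(cells):
        for face in _HEX_FACES:
            key = tuple(sorted(int(cell[j]) for j in face))
            if key in face_owner:
                other = face_owner[key]
                nbrs[i].add(other)
                nbrs[other].add(i)
            else:
                face_owner[key] = i
    return nbrs


def field_from_vtk(path: str | Path):
    """Build a :class:`~scaffold_degrade.scaffold.ScaffoldField` from a mesh.

    Requires a ``max_principal_strain`` scalar cell-data array; negative
    values are clamped to 0 (compression does not drive degradation).
    """
    from .scaffold import ScaffoldField

    points, cells, cell_data = read_vtk(path)
    if "max_principal_strain" not in cell_data:
        raise ValueError(f"{path}: cell-data array 'max_principal_strain' is required")
    strains = np.maximum(cell_data["max_principal_strain"], 0.0)
    return ScaffoldField(
        element_ids=np.arange(len(cells)),
        volumes=hex_volumes(points, cells),
        strains=strains,
        neighbors=[frozenset(s) for s in shared_face_neighbors(cells)],
        points=points,
        cells=cells,
    )


def write_state_vtk(field, state, path: str | Path) -> None:
    """Snapshot a degradation state onto the field's mesh (requires geometry)."""
    if field.points is None or field.cells is None:
        raise ValueError("field carries no mesh geometry; cannot write VTK snapshot")
    write_vtk(
        path,
        field.points,
        field.cells,
        cell_data={
            "max_principal_strain": field.strains,
            "degree": state.degree,
            "alive": state.alive.astype(float),
        },
        title=f"scaffold state at t={state.time_days:g} days",
    )
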