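"""Readers/writers for meshes and layouts in standard text formats.

Meshes go to VTK XML unstructured grids (.vtu, ASCII) and Gmsh MSH v2.2
(ASCII). Cell data always includes the integer field ``tissue_label`` and,
when conductivities are assigned, the 9-component field
``conductivity_tensor`` (row-major, S/m). Electrode layouts go to CSV.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .meshing import HeadMesh

PathLike = Union[str, Path]

_VTK_TETRA = 10


def _fmt_floats(a: np.ndarray, per_line: int) -> str:
    flat = np.asarray(a, dtype=float).reshape(-1, per_line)
    return "\n".join(" ".join(f"{x:.10g}" for x in row) for row in flat)


def write_vtu(
    mesh: HeadMesh,
    path: PathLike,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> Path:
    """Write the mesh (plus optional extra per-element arrays) as ASCII VTU."""
    path = Path(path)
    n, m = len(mesh.nodes), len(mesh.elements)
    arrays: Dict[str, np.ndarray] = {"tissue_label": mesh.labels}
    if mesh.conductivity is not None:
        arrays["conductivity_tensor"] = mesh.conductivity.reshape(m, 9)
    if cell_data:
        arrays.update(cell_data)

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt_floats(mesh.nodes, 3),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in el) for el in mesh.elements),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(m)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(_VTK_TETRA) for _ in range(m)),
        "        </DataArray>",
        "      </Cells>",
        "      <CellData>",
    ]
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(
                f'        <DataArray type="Int32" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            lines.append(" ".join(str(int(x)) for x in arr.reshape(-1)))
        else:
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            lines.append(_fmt_floats(arr, ncomp))
        lines.append("        </DataArray>")
    lines += [
        "      </CellData>",
        "    </Piece>",
        "  </UnstructuredGrid>",
        "</VTKFile>",
        "",
    ]
    path.write_text("\n".join(lines))
    return path


def read_vtu(path: PathLike) -> HeadMesh:
    """Read a mesh written by :func:`write_vtu` (ASCII tetrahedra only)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTU unstructured grid")

    def _data(parent_tag: str, name: Optional[str] = None) -> np.ndarray:
        parent = piece.find(parent_tag)
        assert parent is not None
        for da in parent.findall("DataArray"):
            if name is None or da.get("Name") == name:
                text = da.text or ""
                dtype = float if da.get("type", "").startswith("Float") else np.int64
                vals = np.array(text.split(), dtype=float)
                arr = vals.astype(dtype)
                ncomp = int(da.get("NumberOfComponents", "1"))
                return arr.reshape(-1, ncomp) if ncomp > 1 else arr
        raise KeyError(f"{path}: DataArray {name!r} not found under {parent_tag}")

    nodes = _data("Points")
    conn = _data("Cells", "connectivity").reshape(-1, 4)
    labels = _data("CellData", "tissue_label").astype(np.int32)
    try:
        cond = _data("CellData", "conductivity_tensor").reshape(-1, 3, 3)
    except KeyError:
        cond = None
    return HeadMesh(nodes=nodes, elements=conn, labels=labels, conductivity=cond)


def write_msh(mesh: HeadMesh, path: PathLike) -> Path:
    """Write Gmsh MSH v2.2 ASCII; tissue labels become physical tags."""
    path = Path(path)
    lines = [
        "$MeshFormat",
        "2.2 0 8",
        "$EndMeshFormat",
        "$Nodes",
        str(len(mesh.nodes)),
    ]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.10g} {y:.10g} {z:.10g}")
    lines += ["$EndNodes", "$Elements", str(len(mesh.elements))]
    for i, (el, lab) in enumerate(zip(mesh.elements, mesh.labels), start=1):
        a, b, c, d = (int(v) + 1 for v in el)
        lines.append(f"{i} 4 2 {int(lab)} {int(lab)} {a} {b} {c} {d}")
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))
    return path


def read_msh(path: PathLike) -> HeadMesh:
    """Read a tetrahedra-only Gmsh MSH v2.2 ASCII file."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes = []
    elements = []
    labels = []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
        elif line.strip() == "$Elements":
            m = int(next(it))
            for _ in range(m):
                parts = next(it).split()
                if parts[1] != "4":
                    continue
                ntags = int(parts[2])
                labels.append(int(parts[3]))
                elements.append([int(v) - 1 for v in parts[3 + ntags :]])
    return HeadMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=np.asarray(elements, dtype=np.int64),
        labels=np.asarray(labels, dtype=np.int32),
    )


def write_electrode_csv(electrodes: Sequence, path: PathLike) -> Path:
    """Write an electrode layout as CSV (id, x, y, z, radius, role)."""
    path = Path(path)
    lines = ["id,x_mm,y_mm,z_mm,radius_mm,role"]
    for e in electrodes:
        x, y, z = e.center
        lines.append(f"{e.id},{x:.6g},{y:.6g},{z:.6g},{e.radius:.6g},{e.role}")
    path.write_text("\n".join(lines) + "\n")
    return path
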