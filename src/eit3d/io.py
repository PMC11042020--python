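"""Mesh and field I/O: Gmsh ``.msh`` (v2.2 ASCII) and VTK ``.vtu`` (XML ASCII).

Only tetrahedral volume cells are supported; electrode patches are stored as
extra triangle cells carrying the electrode id (physical tag in ``.msh``, an
``electrode_id`` cell-data array in ``.vtu``). Conductivity fields export as
a per-tet ``sigma_S_per_m`` scalar. Write-then-read round trips preserve
node coordinates to better than 1e-12 relative, connectivity exactly, and
electrode assignments.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .fem import ConductivityField
from .mesh import Mesh


class UnsupportedMeshFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gmsh 2.2 ASCII
# ---------------------------------------------------------------------------

def _write_msh(mesh: Mesh, path: Path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append("$EndNodes")
    tri_rows = []
    for el, faces in sorted(mesh.electrode_faces.items()):
        for f in sorted(int(i) for i in faces):
            tri_rows.append((el, mesh.boundary_faces[f]))
    lines.append("$Elements")
    lines.append(str(len(tri_rows) + mesh.n_elements))
    eid = 1
    for el, tri in tri_rows:
        a, b, c = (int(v) + 1 for v in tri)
        lines.append(f"{eid} 2 2 {el} {el} {a} {b} {c}")
        eid += 1
    for tet in mesh.tets:
        a, b, c, d = (int(v) + 1 for v in tet)
        lines.append(f"{eid} 4 2 0 0 {a} {b} {c} {d}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> Mesh:
    text = path.read_text().split("\n")
    it = iter(text)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise UnsupportedMeshFormatError(f"missing section {tag} in {path}")

    until("$Nodes")
    n = int(next(it))
    nodes = np.empty((n, 3))
    for k in range(n):
        parts = next(it).split()
        nodes[k] = [float(v) for v in parts[1:4]]
    until("$Elements")
    m = int(next(it))
    tets, tris = [], []
    for _ in range(m):
        parts = next(it).split()
        etype = int(parts[1])
        ntags = int(parts[2])
        tags = [int(v) for v in parts[3 : 3 + ntags]]
        conn = [int(v) - 1 for v in parts[3 + ntags :]]
        if etype == 4:
            tets.append(conn)
        elif etype == 2:
            tris.append((tags[0] if tags else 0, conn))
        else:
            raise UnsupportedMeshFormatError(
                f"unsupported element type {etype} (only tetrahedra + electrode triangles)"
            )
    mesh = Mesh(nodes=nodes, tets=np.asarray(tets, dtype=np.int64))
    _attach_electrodes(mesh, tris, path)
    return mesh


# ---------------------------------------------------------------------------
# VTU (XML ASCII, UnstructuredGrid)
# ---------------------------------------------------------------------------

_VTK_TET = 10
_VTK_TRI = 5


def _write_vtu(mesh: Mesh, path: Path, cell_scalars: dict | None = None) -> None:
    """cell_scalars: per-tet float arrays; electrode triangles are appended."""
    tri_rows = []
    for el, faces in sorted(mesh.electrode_faces.items()):
        for f in sorted(int(i) for i in faces):
            tri_rows.append((el, mesh.boundary_faces[f]))
    n_cells = mesh.n_elements + len(tri_rows)

    conn, offs, types, elec = [], [], [], []
    off = 0
    for tet in mesh.tets:
        conn.extend(int(v) for v in tet)
        off += 4
        offs.append(off)
        types.append(_VTK_TET)
        elec.append(0)
    for el, tri in tri_rows:
        conn.extend(int(v) for v in tri)
        off += 3
        offs.append(off)
        types.append(_VTK_TRI)
        elec.append(el)

    def arr(tag: str, name: str, dtype: str, values, per_line=6) -> str:
        body = "\n".join(
            " ".join(str(v) for v in values[i : i + per_line]) for i in range(0, len(values), per_line)
        )
        return (
            f'<DataArray type="{dtype}" Name="{name}" format="ascii">\n{body}\n</DataArray>'
        )

    pts = [f"{v:.17g}" for row in mesh.nodes for v in row]
    cd = [arr("", "electrode_id", "Int32", elec)]
    for name, vals in (cell_scalars or {}).items():
        full = [f"{v:.17g}" for v in vals] + ["0"] * len(tri_rows)
        cd.append(arr("", name, "Float64", full))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">
<Points>
{arr('', 'Points', 'Float64', pts, 3)}
</Points>
<Cells>
{arr('', 'connectivity', 'Int64', conn)}
{arr('', 'offsets', 'Int64', offs)}
{arr('', 'types', 'UInt8', types)}
</Cells>
<CellData>
{chr(10).join(cd)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)


def _read_vtu(path: Path) -> tuple[Mesh, dict]:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise UnsupportedMeshFormatError(f"{path} is not an unstructured-grid VTU file")

    def get_array(parent, name):
        for da in parent.iter("DataArray"):
            if da.get("Name") == name:
                return np.array(da.text.split(), dtype=float)
        return None

    pts = get_array(piece.find("Points"), "Points").reshape(-1, 3)
    cells = piece.find("Cells")
    conn = get_array(cells, "connectivity").astype(np.int64)
    offs = get_array(cells, "offsets").astype(np.int64)
    types = get_array(cells, "types").astype(int)
    bad = set(types) - {_VTK_TET, _VTK_TRI}
    if bad:
        raise UnsupportedMeshFormatError(f"unsupported VTK cell types {sorted(bad)}")
    cd = piece.find("CellData")
    elec_arr = get_array(cd, "electrode_id") if cd is not None else None

    tets, tris, scalars = [], [], {}
    tet_rows = []
    start = 0
    for ci, (end, t) in enumerate(zip(offs, types)):
        nodes = conn[start:end]
        if t == _VTK_TET:
            tets.append(nodes)
            tet_rows.append(ci)
        else:
            el = int(elec_arr[ci]) if elec_arr is not None else 0
            tris.append((el, list(nodes)))
        start = end
    if cd is not None:
        for da in cd.iter("DataArray"):
            name = da.get("Name")
            if name and name != "electrode_id":
                vals = np.array(da.text.split(), dtype=float)
                scalars[name] = vals[tet_rows]
    mesh = Mesh(nodes=pts, tets=np.asarray(tets, dtype=np.int64))
    _attach_electrodes(mesh, tris, path)
    return mesh, scalars


def _attach_electrodes(mesh: Mesh, tris, path) -> None:
    if not tris:
        warnings.warn(f"no electrode metadata in {path}; electrodes left unset", stacklevel=3)
        return
    lookup = {tuple(sorted(f)): i for i, f in enumerate(mesh.boundary_faces)}
    electrode_faces: dict[int, list[int]] = {}
    for el, conn in tris:
        if el <= 0:
            continue
        fi = lookup.get(tuple(sorted(conn)))
        if fi is None:
            raise UnsupportedMeshFormatError("electrode triangle is not a boundary face")
        electrode_faces.setdefault(el, []).append(fi)
    mesh.electrode_faces = {k: np.asarray(sorted(v)) for k, v in sorted(electrode_faces.items())}


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def save_mesh(mesh: Mesh, path) -> None:
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtu":
        _write_vtu(mesh, path)
    else:
        raise UnsupportedMeshFormatError(f"unsupported mesh format {path.suffix!r}")


def load_mesh(path) -> Mesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".msh":
        return _read_msh(path)
    if path.suffix == ".vtu":
        return _read_vtu(path)[0]
    raise UnsupportedMeshFormatError(f"unsupported mesh format {path.suffix!r}")


def export_vtk(field: ConductivityField, mesh: Mesh, path) -> None:
    """Write the per-element conductivity as a ``sigma_S_per_m`` VTU scalar."""
    field.check_bound(mesh)
    _write_vtu(mesh, Path(path), cell_scalars={"sigma_S_per_m": field.values})


def load_field_vtu(path, mesh: Mesh | None = None) -> ConductivityField:
    m, scalars = _read_vtu(Path(path))
    if "sigma_S_per_m" not in scalars:
        raise UnsupportedMeshFormatError("file carries no sigma_S_per_m cell data")
    ref = mesh if mesh is not None else m
    return ConductivityField(scalars["sigma_S_per_m"], ref.mesh_hash)
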