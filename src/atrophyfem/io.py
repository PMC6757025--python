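"""Mesh and field I/O: Gmsh MSH 2.2 ASCII, native JSON, and VTU export.

Physical-group names are fixed: surface groups ``gray`` and ``white`` for
the tissue regions, line groups ``pial``, ``ventricular`` and ``brainstem``
for the boundary markers. The native format is versioned JSON and is the
only format that round-trips sulcal landmarks and generator metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import MARKERS, REGIONS, TriMesh

__all__ = ["read_mesh", "write_mesh", "write_vtu", "MeshParseError"]

NATIVE_VERSION = 1

# fixed MSH physical ids: 2D tissue groups then 1D boundary groups
_PHYS_2D = {"gray": 1, "white": 2}
_PHYS_1D = {"pial": 3, "ventricular": 4, "brainstem": 5}


class MeshParseError(ValueError):
    """Malformed mesh file; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_mesh(mesh: TriMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as ``msh`` (Gmsh 2.2 ASCII), ``native`` JSON, or ``vtu``."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        _write_msh(mesh, path)
    elif fmt == "native":
        _write_native(mesh, path)
    elif fmt == "vtu":
        write_vtu(path, mesh)
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (expected msh|native|vtu)")


def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read a mesh from MSH 2.2 ASCII or native JSON."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "msh":
        return _read_msh(path)
    if fmt == "native":
        return _read_native(path)
    raise ValueError(f"unknown mesh format {fmt!r} (expected msh|native)")


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    return {".msh": "msh", ".json": "native", ".vtu": "vtu"}.get(suf, suf.lstrip("."))


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII
# ---------------------------------------------------------------------------

def _write_msh(mesh: TriMesh, path: Path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(_PHYS_2D) + len(_PHYS_1D))]
    for name, pid in _PHYS_1D.items():
        lines.append(f'1 {pid} "{name}"')
    for name, pid in _PHYS_2D.items():
        lines.append(f'2 {pid} "{name}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i} {x:.16g} {y:.16g} 0")
    lines += ["$EndNodes", "$Elements"]
    n_lines = sum(len(v) for v in mesh.boundary_edges.values())
    lines.append(str(n_lines + mesh.n_elements))
    eid = 1
    for marker, edges in mesh.boundary_edges.items():
        pid = _PHYS_1D[marker]
        for a, b in edges:
            lines.append(f"{eid} 1 2 {pid} {pid} {a + 1} {b + 1}")
            eid += 1
    for cell, region in zip(mesh.elements, mesh.element_region):
        pid = _PHYS_2D[str(region)]
        lines.append(f"{eid} 2 2 {pid} {pid} {cell[0] + 1} {cell[1] + 1} {cell[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> TriMesh:
    text = path.read_text().splitlines()
    if not text:
        raise MeshParseError(f"{path}: empty file", line=1)
    i = 0
    n = len(text)

    def expect(token):
        nonlocal i
        if i >= n:
            raise MeshParseError(f"unexpected end of file, expected {token}", line=n)
        if text[i].strip() != token:
            raise MeshParseError(f"expected {token!r}, got {text[i].strip()!r}", line=i + 1)
        i += 1

    expect("$MeshFormat")
    ver = text[i].split()
    if not ver or not ver[0].startswith("2.2"):
        raise MeshParseError(f"unsupported MSH version {text[i].strip()!r} "
                             "(need 2.2 ASCII)", line=i + 1)
    i += 1
    expect("$EndMeshFormat")

    phys_names: dict[int, str] = {}
    if i < n and text[i].strip() == "$PhysicalNames":
        i += 1
        try:
            cnt = int(text[i])
        except ValueError:
            raise MeshParseError("bad physical-name count", line=i + 1)
        i += 1
        for _ in range(cnt):
            parts = text[i].split(maxsplit=2)
            phys_names[int(parts[1])] = parts[2].strip().strip('"')
            i += 1
        expect("$EndPhysicalNames")

    expect("$Nodes")
    try:
        n_nodes = int(text[i])
    except (ValueError, IndexError):
        raise MeshParseError("bad node count", line=i + 1)
    i += 1
    coords = np.empty((n_nodes, 2))
    for k in range(n_nodes):
        parts = text[i].split()
        if len(parts) < 4:
            raise MeshParseError("node line needs 'id x y z'", line=i + 1)
        coords[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
        i += 1
    expect("$EndNodes")

    expect("$Elements")
    try:
        n_el = int(text[i])
    except (ValueError, IndexError):
        raise MeshParseError("bad element count", line=i + 1)
    i += 1
    tris, regions = [], []
    edges: dict[str, list] = {m: [] for m in MARKERS}
    for _ in range(n_el):
        parts = text[i].split()
        etype = int(parts[1])
        n_tags = int(parts[2])
        phys = int(parts[3]) if n_tags >= 1 else 0
        conn = [int(p) - 1 for p in parts[3 + n_tags:]]
        name = phys_names.get(phys, "")
        if etype == 2:
            if name not in REGIONS:
                raise MeshParseError(
                    f"triangle with physical group {name!r}; expected one of "
                    f"{list(REGIONS)}", line=i + 1)
            tris.append(conn)
            regions.append(name)
        elif etype == 1:
            if name not in MARKERS:
                raise MeshParseError(
                    f"line element with physical group {name!r}; expected one "
                    f"of {list(MARKERS)}", line=i + 1)
            edges[name].append(conn)
        else:
            raise MeshParseError(f"unsupported element type {etype}", line=i + 1)
        i += 1
    expect("$EndElements")
    if not tris:
        raise MeshParseError(f"{path}: no triangles found", line=i)
    missing = [r for r in REGIONS if r not in regions]
    if missing:
        raise MeshParseError(
            f"{path}: missing required physical group(s) {missing}; a brain "
            f"slice needs surface groups {list(REGIONS)}")
    return TriMesh(coords, np.array(tris), np.array(regions),
                   boundary_edges={m: np.array(v).reshape(-1, 2)
                                   for m, v in edges.items() if v},
                   metadata={"source": str(path), "format": "msh2.2"})


# ---------------------------------------------------------------------------
# Native JSON
# ---------------------------------------------------------------------------

def _write_native(mesh: TriMesh, path: Path) -> None:
    doc = {
        "format": "atrophyfem-mesh",
        "version": NATIVE_VERSION,
        "units": "mm",
        "node_coords": mesh.node_coords.tolist(),
        "elements": mesh.elements.tolist(),
        "element_region": mesh.element_region.tolist(),
        "element_subregion": mesh.element_subregion.tolist(),
        "boundary_edges": {k: v.tolist() for k, v in mesh.boundary_edges.items()},
        "sulci": {k: [[int(a), int(b), float(d)] for a, b, d in v]
                  for k, v in mesh.sulci.items()},
        "metadata": mesh.metadata,
    }
    path.write_text(json.dumps(doc))


def _read_native(path: Path) -> TriMesh:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise MeshParseError(f"{path}: invalid JSON: {e.msg}", line=e.lineno)
    if doc.get("format") != "atrophyfem-mesh":
        raise MeshParseError(f"{path}: not a native mesh file")
    if doc.get("version") != NATIVE_VERSION:
        raise MeshParseError(
            f"{path}: unsupported native mesh version {doc.get('version')}")
    return TriMesh(
        np.asarray(doc["node_coords"], dtype=float),
        np.asarray(doc["elements"], dtype=np.int64),
        np.asarray(doc["element_region"], dtype="U16"),
        element_subregion=np.asarray(doc["element_subregion"], dtype="U32"),
        boundary_edges={k: np.asarray(v, dtype=np.int64).reshape(-1, 2)
                        for k, v in doc["boundary_edges"].items()},
        sulci={k: [(int(a), int(b), float(d)) for a, b, d in v]
               for k, v in doc.get("sulci", {}).items()},
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# VTU (XML, ASCII) field export — write only
# ---------------------------------------------------------------------------

def write_vtu(path, mesh: TriMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh with optional nodal/element fields as ASCII VTU."""
    path = Path(path)
    point_data = point_data or {}
    cell_data = cell_data or {}
    n, m = mesh.n_nodes, mesh.n_elements
    out = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        _darray("Points", np.column_stack([mesh.node_coords,
                                           np.zeros(n)]).ravel(), 3),
        "</Points>",
        "<Cells>",
        _darray("connectivity", mesh.elements.ravel(), dtype="Int64"),
        _darray("offsets", np.arange(3, 3 * m + 1, 3), dtype="Int64"),
        _darray("types", np.full(m, 5), dtype="UInt8"),
        "</Cells>",
    ]
    out.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        comp = 1 if arr.ndim == 1 else arr.shape[1]
        out.append(_darray(name, arr.ravel(), comp))
    out.append("</PointData>")
    out.append("<CellData>")
    region_code = (mesh.element_region == "gray").astype(float)
    out.append(_darray("gray_matter", region_code))
    for name, arr in cell_data.items():
        out.append(_darray(name, np.asarray(arr, dtype=float).ravel()))
    out.append("</CellData>")
    out += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(out) + "\n")


def _darray(name: str, values: np.ndarray, ncomp: int = 1,
            dtype: str = "Float64") -> str:
    if dtype.startswith("Float"):
        body = " ".join(f"{v:.9g}" for v in values)
    else:
        body = " ".join(str(int(v)) for v in values)
    return (f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>')
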