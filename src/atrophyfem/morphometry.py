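"""Clinical-surrogate morphometry on deformed slice configurations.

Metrics mirror what radiologists read off serial MRI in atrophy studies:

* **cortical thickness** — distance from points sampled uniformly by
  arclength on the deformed pial surface to the deformed gray/white
  interface (a 2D analog of surface-based thickness); a margin adjacent to
  the brainstem is excluded;
* **ventricle area** and the **ventricle-to-brain ratio** (VBR =
  ventricular area / (tissue + ventricular area)), the classic global
  atrophy proxy;
* **sulcal width** — distances between generator-defined landmark pairs on
  opposing sulcal walls, advected with the deformation;
* **maximum displacement magnitude** and **maximum element von Mises
  stress** per increment.

All metrics are invariant under rigid motions of the deformed
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString

from .mesh import TriMesh, chain_loops, element_areas, shoelace_area

__all__ = [
    "MorphometryReport",
    "Morphometer",
    "cortical_thickness",
    "ventricle_area",
    "ventricle_to_brain_ratio",
    "sulcal_width",
    "max_displacement",
    "max_von_mises",
    "region_areas",
]


@dataclass
class MorphometryReport:
    time: float                    # months
    mean_cortical_thickness: float  # mm
    thinning_percent: float        # 100·(mean − reference)/reference
    ventricle_area: float          # mm²
    ventricle_to_brain_ratio: float
    sulcal_width_samples: dict     # sulcus id -> {depth: width mm}
    max_displacement: float        # mm
    max_von_mises: float           # kPa
    region_areas: dict             # tissue -> deformed mm²
    warnings: list = field(default_factory=list)

    def as_row(self) -> dict:
        row = {
            "time_months": self.time,
            "mean_cortical_thickness_mm": self.mean_cortical_thickness,
            "thinning_percent": self.thinning_percent,
            "ventricle_area_mm2": self.ventricle_area,
            "ventricle_to_brain_ratio": self.ventricle_to_brain_ratio,
            "max_displacement_mm": self.max_displacement,
            "max_von_mises_kpa": self.max_von_mises,
        }
        for tissue, a in self.region_areas.items():
            row[f"area_{tissue}_mm2"] = a
        for sid, widths in self.sulcal_width_samples.items():
            for depth, w in widths.items():
                row[f"{sid}_width_{int(depth * 100)}pct_mm"] = w
        return row


def _deformed_coords(mesh: TriMesh, state=None) -> np.ndarray:
    if state is None:
        return mesh.node_coords
    return mesh.node_coords + state.u


def pial_paths(mesh: TriMesh) -> list[np.ndarray]:
    """Ordered node paths of the pial boundary (open: ends at the brainstem)."""
    edges = mesh.boundary_edges.get("pial")
    if edges is None or edges.size == 0:
        raise ValueError("mesh has no pial boundary edges")
    closed, open_ = chain_loops(edges)
    return open_ + [np.append(c, c[0]) for c in closed]


def interface_edges(mesh: TriMesh) -> np.ndarray:
    """Edges shared by a gray and a white element (the gray/white interface)."""
    tris = mesh.elements
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    owner = np.tile(np.arange(len(tris)), 3)
    key = np.sort(e, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, owner = key[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    i = np.nonzero(same)[0]
    a, b = owner[i], owner[i + 1]
    mixed = mesh.element_region[a] != mesh.element_region[b]
    out = key[i[mixed]]
    if out.size == 0:
        raise ValueError("mesh has no gray/white interface (single tissue?)")
    return out


def _sample_polyline(coords: np.ndarray, n: int, margin: float) -> np.ndarray:
    """n points uniform in arclength, excluding `margin` fraction per end."""
    seg = np.hypot(*np.diff(coords, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(margin * s[-1], (1.0 - margin) * s[-1], n)
    return np.column_stack([np.interp(si, s, coords[:, 0]),
                            np.interp(si, s, coords[:, 1])])


def cortical_thickness(mesh: TriMesh, state=None, n_samples: int = 256,
                       margin_fraction: float = 0.10):
    """Thickness samples and mean on the (deformed) configuration.

    Samples ≥ ``n_samples`` points uniformly by arclength on the deformed
    pial boundary, excluding a brainstem-adjacent margin at each end of the
    path, and measures the distance to the nearest point of the deformed
    gray/white interface.
    """
    coords = _deformed_coords(mesh, state)
    iface = interface_edges(mesh)
    segs = MultiLineString([coords[e].tolist() for e in iface])
    shapely.prepare(segs)
    samples = []
    for path in pial_paths(mesh):
        pc = coords[path]
        n = max(n_samples, 8)
        pts = _sample_polyline(pc, n, margin_fraction)
        samples.append(shapely.distance(shapely.points(pts), segs))
    d = np.concatenate(samples)
    return d, float(d.mean())


def ventricle_loops(mesh: TriMesh) -> list[np.ndarray]:
    edges = mesh.boundary_edges.get("ventricular")
    if edges is None or edges.size == 0:
        raise ValueError("mesh has no ventricular boundary")
    closed, open_ = chain_loops(edges)
    if open_:
        raise ValueError("ventricular boundary contains non-closed chains")
    return closed


def ventricle_area(mesh: TriMesh, state=None, warnings: list | None = None) -> float:
    """Total shoelace area of the (deformed) ventricular loops, mm²."""
    coords = _deformed_coords(mesh, state)
    total = 0.0
    for loop in ventricle_loops(mesh):
        pts = coords[loop]
        ring = LineString(np.vstack([pts, pts[:1]]))
        if not ring.is_simple and warnings is not None:
            warnings.append("deformed ventricular loop self-intersects")
        total += shoelace_area(pts)
    return total


def ventricle_to_brain_ratio(mesh: TriMesh, state=None) -> float:
    """Ventricular area / (tissue area + ventricular area)."""
    coords = _deformed_coords(mesh, state)
    tissue = float(element_areas(mesh.elements, coords).sum())
    vent = ventricle_area(mesh, state)
    return vent / (tissue + vent)


def region_areas(mesh: TriMesh, state=None) -> dict:
    coords = _deformed_coords(mesh, state)
    areas = element_areas(mesh.elements, coords)
    return {tissue: float(areas[mesh.element_region == tissue].sum())
            for tissue in np.unique(mesh.element_region)}


def max_displacement(state) -> float:
    """Maximum nodal displacement magnitude, mm."""
    return float(np.linalg.norm(state.u, axis=1).max())


def max_von_mises(state) -> float:
    """Maximum element von Mises stress, kPa."""
    return float(state.von_mises.max())


def sulcal_width(mesh: TriMesh, state=None, sulcus_id: str | None = None) -> dict:
    """Distances between landmark pairs on opposing sulcal walls, by depth.

    Returns ``{depth_fraction: width_mm}`` for one sulcus, or a dict over
    all sulci when ``sulcus_id`` is None.
    """
    if not mesh.sulci:
        raise ValueError("mesh defines no sulcal landmarks")
    if sulcus_id is None:
        return {sid: sulcal_width(mesh, state, sid) for sid in mesh.sulci}
    if sulcus_id not in mesh.sulci:
        raise KeyError(f"unknown sulcus {sulcus_id!r}; known ids: "
                       f"{sorted(mesh.sulci)}")
    coords = _deformed_coords(mesh, state)
    return {float(d): float(np.linalg.norm(coords[a] - coords[b]))
            for a, b, d in mesh.sulci[sulcus_id]}


class Morphometer:
    """Per-increment reporting against the undeformed reference of one mesh."""

    def __init__(self, mesh: TriMesh, n_samples: int = 256,
                 margin_fraction: float = 0.10):
        self.mesh = mesh
        self.n_samples = n_samples
        self.margin = margin_fraction
        _, self.reference_thickness = cortical_thickness(
            mesh, None, n_samples, margin_fraction)

    def report(self, mesh: TriMesh, state) -> MorphometryReport:
        warnings: list = []
        _, mean_t = cortical_thickness(mesh, state, self.n_samples, self.margin)
        vent = ventricle_area(mesh, state, warnings)
        return MorphometryReport(
            time=state.time,
            mean_cortical_thickness=mean_t,
            thinning_percent=100.0 * (mean_t - self.reference_thickness)
            / self.reference_thickness,
            ventricle_area=vent,
            ventricle_to_brain_ratio=ventricle_to_brain_ratio(mesh, state),
            sulcal_width_samples=sulcal_width(mesh, state) if mesh.sulci else {},
            max_displacement=max_displacement(state),
            max_von_mises=max_von_mises(state),
            region_areas=region_areas(mesh, state),
            warnings=warnings,
        )
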