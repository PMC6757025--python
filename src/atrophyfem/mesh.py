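"""Labeled 2D brain-slice triangulations.

The geometric substrate of every simulation is a :class:`TriMesh`: a
triangulation of a brain slice with per-element tissue labels (gray /
white), optional named subregions for focal-atrophy targets, and boundary
edges tagged as pial surface, ventricular surface, or brainstem.

Because clinical meshes are segmented from MRI and not redistributable,
the module ships a parametric generator (:func:`generate_slice`) that
emulates adult-scale sagittal and coronal slice geometry: an oval outline
with sinusoidal gyral/sulcal folds, a cortical gray ribbon of constant
thickness offset inward from the pial surface, lateral-ventricle voids,
and a flat brainstem segment at the inferior boundary where the model is
later fixed in space. All lengths are in mm; elements are counter-clockwise
linear triangles; y increases superiorly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "TriMesh",
    "SliceSpec",
    "VentricleSpec",
    "GeometryError",
    "generate_slice",
    "validate_mesh",
    "dof_count",
    "element_areas",
    "chain_loops",
    "structured_rectangle_mesh",
    "crossed_disc_mesh",
]

MARKERS = ("pial", "ventricular", "brainstem")
REGIONS = ("gray", "white")


class GeometryError(ValueError):
    """Infeasible slice geometry (names the conflicting parameters)."""


@dataclass
class TriMesh:
    """Labeled triangulation of a 2D brain slice.

    Attributes
    ----------
    node_coords : (n, 2) float array, mm
    elements : (m, 3) int array, counter-clockwise node triples
    element_region : (m,) str array, each 'gray' or 'white'
    element_subregion : (m,) str array, named focal label or '' (none)
    boundary_edges : dict marker -> (k, 2) int array of node pairs
    sulci : dict sulcus id -> list of (node_left, node_right, depth_fraction)
        landmark pairs on opposing sulcal walls, advected with deformation
    metadata : free-form provenance (generator spec, designed areas, ...)
    """

    node_coords: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    element_subregion: np.ndarray | None = None
    boundary_edges: dict = field(default_factory=dict)
    sulci: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 2)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 3)
        self.element_region = np.asarray(self.element_region, dtype="U16")
        if self.element_subregion is None:
            self.element_subregion = np.full(len(self.elements), "", dtype="U32")
        else:
            self.element_subregion = np.asarray(self.element_subregion, dtype="U32")
        self.boundary_edges = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for k, v in self.boundary_edges.items()
        }

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class VentricleSpec:
    """One ventricular void: an ellipse (center, semi-axes, tilt)."""

    center: tuple  # (x, y) mm
    semi_axes: tuple  # (a, b) mm
    angle_deg: float = 0.0

    def polygon(self, n: int = 96) -> Polygon:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        x = self.semi_axes[0] * np.cos(t)
        y = self.semi_axes[1] * np.sin(t)
        c, s = np.cos(np.radians(self.angle_deg)), np.sin(np.radians(self.angle_deg))
        pts = np.column_stack([self.center[0] + c * x - s * y,
                               self.center[1] + s * x + c * y])
        return Polygon(pts)

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass(frozen=True)
class SliceSpec:
    """Parameters of the synthetic slice generator.

    Defaults (via :meth:`coronal` / :meth:`sagittal`) are adult-scale:
    sagittal 165 × 120 mm, coronal 140 × 120 mm, 4 mm cortical ribbon,
    gyral folds of 8 mm amplitude and 25 mm wavelength.
    """

    profile: str = "coronal"
    bounding_extent: tuple = (140.0, 120.0)  # (width, height) mm
    ribbon_thickness: float = 4.0  # mm
    gyral_amplitude: float = 15.0  # mm, crest-to-fundus sulcal depth
    gyral_wavelength: float = 18.0  # mm fold pitch along the pial envelope
    gyral_sharpness: float = 6.0  # notch concentration: higher = narrower, more slit-like sulci
    deep_gray_margin: float = 8.0  # mm of deep gray (caudate/thalamus analog) around ventricles
    ventricles: tuple = ()  # VentricleSpec tuple
    brainstem_width: float = 25.0  # mm
    brainstem_length: float = 15.0  # mm, inferior stub below the slice body
    brainstem_recess: float = 0.0  # mm; > 0 recesses the fixed boundary upward
    # between the inferior lobes (coronal sections cut the midbrain well
    # above the temporal poles); 0 gives an inferior stub (sagittal)
    target_edge_length: float = 1.6  # mm
    seed: int = 0

    @staticmethod
    def coronal(**overrides) -> "SliceSpec":
        base = dict(
            profile="coronal",
            bounding_extent=(140.0, 120.0),
            # lateral ventricles: slender slanted slits flanked by deep gray
            ventricles=(
                VentricleSpec(center=(-17.0, 8.0), semi_axes=(13.0, 4.0), angle_deg=-25.0),
                VentricleSpec(center=(17.0, 8.0), semi_axes=(13.0, 4.0), angle_deg=25.0),
            ),
            brainstem_width=25.0,
            brainstem_length=0.0,
            brainstem_recess=18.0,
        )
        base.update(overrides)
        return SliceSpec(**base)

    @staticmethod
    def sagittal(**overrides) -> "SliceSpec":
        base = dict(
            profile="sagittal",
            bounding_extent=(165.0, 120.0),
            ventricles=(
                VentricleSpec(center=(0.0, 8.0), semi_axes=(22.0, 5.0), angle_deg=0.0),
            ),
            brainstem_width=30.0,
            brainstem_length=15.0,
        )
        base.update(overrides)
        return SliceSpec(**base)

    def check(self) -> None:
        if self.profile not in ("sagittal", "coronal"):
            raise GeometryError(f"unknown profile {self.profile!r}")
        if self.ribbon_thickness <= 0:
            raise GeometryError("ribbon_thickness must be > 0")
        if self.target_edge_length <= 0:
            raise GeometryError("target_edge_length must be > 0")
        if self.gyral_amplitude < 0 or self.gyral_wavelength <= 0:
            raise GeometryError("gyral fold parameters must be non-negative / positive")
        if self.gyral_sharpness < 1 or self.deep_gray_margin < 0:
            raise GeometryError("gyral_sharpness must be ≥ 1 and deep_gray_margin ≥ 0")
        w, h = self.bounding_extent
        if self.ribbon_thickness > 0.5 * min(w, h) - self.gyral_amplitude:
            raise GeometryError(
                f"ribbon_thickness={self.ribbon_thickness} too large for "
                f"bounding_extent={self.bounding_extent} with "
                f"gyral_amplitude={self.gyral_amplitude}")
        if self.gyral_amplitude > 0 and self.gyral_wavelength < 4 * self.target_edge_length:
            raise GeometryError(
                f"gyral_wavelength={self.gyral_wavelength} unresolvable at "
                f"target_edge_length={self.target_edge_length}")
        if not (0 < self.brainstem_width < 0.8 * w):
            raise GeometryError(
                f"brainstem_width={self.brainstem_width} incompatible with width={w}")
        if self.brainstem_length < 0 or self.brainstem_recess < 0:
            raise GeometryError("brainstem_length and brainstem_recess must be ≥ 0")
        if self.brainstem_recess > 0.35 * h:
            raise GeometryError(
                f"brainstem_recess={self.brainstem_recess} too deep for "
                f"height={h}")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def element_areas(elements: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Signed areas of triangles (positive for counter-clockwise)."""
    p = coords[elements]
    return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                  - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))


def shoelace_area(loop: np.ndarray) -> float:
    """Absolute polygon area of a closed node-coordinate loop."""
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def chain_loops(edges: np.ndarray):
    """Chain an edge set into ordered node paths.

    Returns (closed_loops, open_paths): lists of node-index arrays. A closed
    loop repeats no node and implicitly connects last back to first.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(e)) for e in edges.tolist()}
    closed, open_ = [], []
    # open paths first: start from odd-degree nodes
    starts = [n for n, nb in adj.items() if len(nb) % 2 == 1]
    for start in sorted(starts):
        path = _walk(start, adj, unused)
        if path is not None:
            open_.append(np.array(path))
    while unused:
        a, b = sorted(unused)[0]
        path = _walk(a, adj, unused)
        if path is None:
            break
        if path[0] == path[-1]:
            closed.append(np.array(path[:-1]))
        else:
            open_.append(np.array(path))
    return closed, open_


def _walk(start, adj, unused):
    path = [start]
    node = start
    while True:
        nxt = None
        for nb in adj[node]:
            if tuple(sorted((node, nb))) in unused:
                nxt = nb
                break
        if nxt is None:
            return path if len(path) > 1 else None
        unused.discard(tuple(sorted((node, nxt))))
        path.append(nxt)
        node = nxt
        if node == start:
            return path


def _boundary_edges_of(elements: np.ndarray) -> np.ndarray:
    """Edges that belong to exactly one triangle."""
    e = np.vstack([elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]])
    key = np.sort(e, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return e[idx[counts == 1]]


# ---------------------------------------------------------------------------
# Synthetic slice generator
# ---------------------------------------------------------------------------

def _pial_and_brainstem_curves(spec: SliceSpec):
    """Dense polylines for the folded pial curve and the brainstem stub.

    The pial envelope is the bounding ellipse; sulci are carved inward as
    periodic notches of depth profile ((1 − cos φ)/2)^p — depth 0 on the
    gyral crowns, ``gyral_amplitude`` at the fundus, with sharpness p
    making sulci narrow and gyri broad as in adult cortex — tapered to
    zero near the brainstem junctions. The brainstem is a rectangular stub
    extending ``brainstem_length`` below the inferior pole; its bottom
    edge is the fixed (Dirichlet) boundary. Also returns fold phase data
    used to place sulcal landmarks.
    """
    a = spec.bounding_extent[0] / 2.0
    b = spec.bounding_extent[1] / 2.0
    xr = spec.brainstem_width / 2.0
    # ellipse parameter (not polar angle): x = a cos u, y = b sin u
    u_right = np.arctan2(-np.sqrt(1 - (xr / a) ** 2), xr / a)
    u_left = -np.pi - u_right  # symmetric point on the left, via CCW sweep
    u = np.linspace(u_right, u_left + 2 * np.pi, 4000)
    ex, ey = a * np.cos(u), b * np.sin(u)
    seg = np.hypot(np.diff(ex), np.diff(ey))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_total = s[-1]

    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2 * np.pi)
    # taper folds to zero over one wavelength at each brainstem junction
    taper_len = spec.gyral_wavelength
    taper = np.clip(s / taper_len, 0, 1) * np.clip((s_total - s) / taper_len, 0, 1)
    taper = 0.5 * (1 - np.cos(np.pi * np.clip(taper, 0, 1)))
    fold_phase = 2 * np.pi * s / spec.gyral_wavelength + phase
    # periodic slit profile: ~1 at the fundus (fold_phase = pi mod 2pi),
    # ~0 on the broad gyral crowns; sharpness k sets the notch width
    depth = (spec.gyral_amplitude
             * np.exp(-spec.gyral_sharpness * (1.0 + np.cos(fold_phase))) * taper)

    # inward normal of the ellipse
    nx, ny = ex / a**2, ey / b**2
    norm = np.hypot(nx, ny)
    nx, ny = -nx / norm, -ny / norm
    px, py = ex + depth * nx, ey + depth * ny
    pial = np.column_stack([px, py])

    # brainstem cut: either a stub hanging below the slice (sagittal) or a
    # chord recessed upward between the inferior lobes (coronal)
    dy = spec.brainstem_recess if spec.brainstem_recess > 0 \
        else -spec.brainstem_length
    left_top, right_top = pial[-1], pial[0]
    left_bot = np.array([left_top[0], left_top[1] + dy])
    right_bot = np.array([right_top[0], right_top[1] + dy])
    walls = [np.array([left_top, left_bot]), np.array([right_bot, right_top])]
    bottom = np.array([left_bot, right_bot])
    fold = dict(s=s, total=s_total, phase=phase, taper=taper,
                wavelength=spec.gyral_wavelength, curve=pial)
    return pial, walls, bottom, fold


def _resample_polyline(pts: np.ndarray, h: float, closed: bool = False) -> np.ndarray:
    """Resample a polyline at (approximately) uniform spacing h."""
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(round(s[-1] / h)), 4)
    si = np.linspace(0.0, s[-1], n, endpoint=False) if closed else np.linspace(0.0, s[-1], n + 1)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y])


def _hex_lattice(bounds, h: float) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    dy = h * np.sqrt(3) / 2
    rows = []
    y = y0
    row = 0
    while y <= y1:
        xs = np.arange(x0 + (h / 2 if row % 2 else 0.0), x1 + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    return np.vstack(rows)


def _sulcal_landmarks(spec: SliceSpec, fold: dict, pial_nodes: np.ndarray,
                      coords: np.ndarray):
    """Landmark node pairs on opposing sulcal walls at fractional depths.

    Each sulcus is one full inward fold of the pial curve; for depth
    fraction d in {0.25, 0.5, 0.75} the pair sits where the fold depth
    passes d·amplitude on either side of the fundus.
    """
    if spec.gyral_amplitude <= 0:
        return {}
    s, total, phase = fold["s"], fold["total"], fold["phase"]
    lam = fold["wavelength"]
    curve = fold["curve"]
    # fundus arclengths: fold phase = pi (mod 2pi)
    k0 = int(np.ceil((2 * np.pi * s[0] / lam + phase - np.pi) / (2 * np.pi)))
    sulci = {}
    depths = (0.25, 0.5, 0.75)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords[pial_nodes])
    idx = 0
    k = k0
    while True:
        s_fundus = ((2 * k + 1) * np.pi - phase) * lam / (2 * np.pi)
        if s_fundus > total - lam:
            break
        if s_fundus < lam:
            k += 1
            continue
        taper_here = np.interp(s_fundus, s, fold["taper"])
        if taper_here < 0.9:  # shallow fold near brainstem: skip
            k += 1
            continue
        pairs = []
        ok = True
        for d in depths:
            # fold phase where the notch depth passes d·amplitude
            dphi = np.arccos(-1.0 - np.log(d) / spec.gyral_sharpness)
            s_l = s_fundus - (np.pi - dphi) * lam / (2 * np.pi)
            s_r = s_fundus + (np.pi - dphi) * lam / (2 * np.pi)
            pl = np.array([np.interp(s_l, s, curve[:, 0]), np.interp(s_l, s, curve[:, 1])])
            pr = np.array([np.interp(s_r, s, curve[:, 0]), np.interp(s_r, s, curve[:, 1])])
            _, il = tree.query(pl)
            _, ir = tree.query(pr)
            nl, nr = int(pial_nodes[il]), int(pial_nodes[ir])
            if nl == nr:
                ok = False
                break
            pairs.append((nl, nr, d))
        if ok:
            sulci[f"sulcus_{idx}"] = pairs
            idx += 1
        k += 1
    return sulci


def generate_slice(spec: SliceSpec) -> TriMesh:
    """Generate a labeled synthetic brain-slice triangulation.

    Deterministic for a fixed spec (including its seed). Raises
    :class:`GeometryError` for infeasible parameter combinations.
    """
    spec.check()
    h = spec.target_edge_length
    pial_curve, wall_curves, bottom_curve, fold = _pial_and_brainstem_curves(spec)

    # outer ring: folded pial arc, then down-left wall, bottom, up-right wall
    ring = np.vstack([pial_curve, wall_curves[0][1:], bottom_curve[1:]])
    domain = Polygon(ring)
    if not domain.is_valid:
        raise GeometryError(
            "pial boundary self-intersects; reduce gyral_amplitude "
            f"({spec.gyral_amplitude}) or increase gyral_wavelength "
            f"({spec.gyral_wavelength})")

    holes = []
    pial_ls = LineString(pial_curve)
    for i, v in enumerate(spec.ventricles):
        vp = v.polygon()
        if not domain.contains(vp):
            raise GeometryError(f"ventricle {i} not strictly interior to the slice")
        if vp.exterior.distance(pial_ls) < spec.ribbon_thickness + 2 * h:
            raise GeometryError(
                f"ventricle {i} intrudes into the cortical ribbon "
                f"(ribbon_thickness={spec.ribbon_thickness})")
        for j, w in enumerate(spec.ventricles[:i]):
            if vp.distance(w.polygon()) < 2 * h:
                raise GeometryError(f"ventricles {j} and {i} overlap or nearly touch")
        holes.append(vp)
    domain = Polygon(ring, [hp.exterior.coords for hp in holes])

    # --- node cloud: boundary samples + interior hex lattice -------------
    pial_pts = _resample_polyline(pial_curve, h, closed=False)
    lw_pts = _resample_polyline(wall_curves[0], h, closed=False)[1:]
    bs_pts = _resample_polyline(bottom_curve, h, closed=False)[1:]
    rw_pts = _resample_polyline(wall_curves[1], h, closed=False)[1:-1]
    vent_pts = [_resample_polyline(np.asarray(hp.exterior.coords)[:-1], h, closed=True)
                for hp in holes]

    boundary_pts = np.vstack([pial_pts, lw_pts, bs_pts, rw_pts] + vent_pts)
    bnd = domain.boundary
    shapely.prepare(domain)
    shapely.prepare(bnd)

    # interface-conforming points on the gray-ribbon offset curve, so the
    # element-wise gray/white interface is crisp rather than jagged
    iface_curve = pial_ls.buffer(spec.ribbon_thickness, quad_segs=16).boundary
    iface_curve = iface_curve.intersection(domain.buffer(-0.3 * h))
    iface_pts = []
    for geom in getattr(iface_curve, "geoms", [iface_curve]):
        if geom.length > 2 * h:
            arr = np.asarray(geom.coords)
            iface_pts.append(_resample_polyline(
                arr, h, closed=bool(geom.is_closed)))
    iface_pts = np.vstack(iface_pts) if iface_pts else np.empty((0, 2))
    if iface_pts.size:
        keep = (shapely.contains_xy(domain, iface_pts[:, 0], iface_pts[:, 1])
                & ~shapely.dwithin(bnd, shapely.points(iface_pts), 0.55 * h))
        iface_pts = iface_pts[keep]

    interior = _hex_lattice(domain.bounds, h)
    inside = shapely.contains_xy(domain, interior[:, 0], interior[:, 1])
    far = ~shapely.dwithin(bnd, shapely.points(interior), 0.55 * h)
    interior = interior[inside & far]
    if iface_pts.size:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(iface_pts).query(interior)
        interior = interior[d > 0.55 * h]

    nodes = np.vstack([boundary_pts, iface_pts, interior])
    n_bnd = len(boundary_pts) + len(iface_pts)  # keep interface nodes pinned

    def triangulate(pts):
        tri = Delaunay(pts)
        cells = tri.simplices
        cent = pts[cells].mean(axis=1)
        keep = shapely.contains_xy(domain, cent[:, 0], cent[:, 1])
        return cells[keep]

    cells = triangulate(nodes)
    # Laplacian smoothing of interior nodes, then re-triangulate once;
    # nodes that would drift outside or onto the boundary revert
    for _ in range(4):
        smoothed = _smooth(nodes, cells, fixed=n_bnd)
        moved = smoothed[n_bnd:]
        ok = (shapely.contains_xy(domain, moved[:, 0], moved[:, 1])
              & ~shapely.dwithin(bnd, shapely.points(moved), 0.4 * h))
        moved[~ok] = nodes[n_bnd:][~ok]
        nodes = np.vstack([nodes[:n_bnd], moved])
    cells = triangulate(nodes)

    # drop unused nodes, remap
    used = np.unique(cells)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    coords = nodes[used]
    cells = remap[cells]

    # orient CCW
    ar = element_areas(cells, coords)
    flip = ar < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]

    # --- boundary markers -------------------------------------------------
    bedges = _boundary_edges_of(cells)
    mids = coords[bedges].mean(axis=1)
    bs_ls = LineString(bottom_curve)
    wall_ls = [LineString(w) for w in wall_curves]
    vent_ls = [LineString(np.vstack([hp.exterior.coords])) for hp in holes]
    markers = {m: [] for m in MARKERS}
    for e, (mx, my) in zip(bedges, mids):
        p = Point(mx, my)
        dists = [("pial", pial_ls.distance(p)),
                 ("pial", min(w.distance(p) for w in wall_ls)),  # stub walls
                 ("brainstem", bs_ls.distance(p))]
        dists += [("ventricular", min(v.distance(p) for v in vent_ls))] if vent_ls else []
        markers[min(dists, key=lambda t: t[1])[0]].append(e)
    boundary_edges = {m: np.array(v, dtype=np.int64).reshape(-1, 2)
                      for m, v in markers.items() if v}

    # --- tissue labels ----------------------------------------------------
    cent = coords[cells].mean(axis=1)
    cent_pts = shapely.points(cent)
    dist_pial = shapely.distance(cent_pts, pial_ls)
    region = np.where(dist_pial < spec.ribbon_thickness, "gray", "white").astype("U16")
    sub = np.full(len(cells), "", dtype="U32")
    sub[region == "gray"] = "cortical-ribbon"
    if spec.ventricles and spec.deep_gray_margin > 0:
        # periventricular deep gray (caudate/thalamus analog)
        dist_vent = np.min(np.column_stack(
            [shapely.distance(cent_pts, hp.exterior) for hp in holes]), axis=1)
        deep = (region == "white") & (dist_vent < spec.deep_gray_margin)
        region[deep] = "gray"
        sub[deep] = "deep-gray"
    if spec.ventricles:
        top = max(v.center[1] + max(v.semi_axes) for v in spec.ventricles)
        xs = [v.center[0] for v in spec.ventricles]
        band = ((region == "white") & (cent[:, 1] > top + spec.deep_gray_margin)
                & (cent[:, 1] < top + spec.deep_gray_margin + 8.0)
                & (cent[:, 0] > min(xs) - 5) & (cent[:, 0] < max(xs) + 5))
        sub[band] = "callosal-band"

    # --- sulcal landmarks ---------------------------------------------------
    pial_nodes = np.unique(boundary_edges.get("pial", np.empty((0, 2), np.int64)))
    sulci = _sulcal_landmarks(spec, fold, pial_nodes, coords)

    mesh = TriMesh(
        node_coords=coords,
        elements=cells,
        element_region=region,
        element_subregion=sub,
        boundary_edges=boundary_edges,
        sulci=sulci,
        metadata={
            "generator": "synthetic-slice",
            "spec": _spec_dict(spec),
            "ventricle_area_designed": float(sum(v.area for v in spec.ventricles)),
        },
    )
    report = validate_mesh(mesh)
    if report:
        raise GeometryError(
            "generated mesh failed validation: " + "; ".join(report[:5]))
    return mesh


def _spec_dict(spec: SliceSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["ventricles"] = [dataclasses.asdict(v) for v in spec.ventricles]
    return d


def _smooth(nodes: np.ndarray, cells: np.ndarray, fixed: int) -> np.ndarray:
    """One Laplacian smoothing pass; the first `fixed` nodes stay put."""
    n = len(nodes)
    acc = np.zeros((n, 2))
    cnt = np.zeros(n)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        np.add.at(acc, cells[:, a], nodes[cells[:, b]])
        np.add.at(acc, cells[:, b], nodes[cells[:, a]])
        np.add.at(cnt, cells[:, a], 1)
        np.add.at(cnt, cells[:, b], 1)
    out = nodes.copy()
    free = (cnt > 0)
    free[:fixed] = False
    out[free] = acc[free] / cnt[free, None]
    return out


# ---------------------------------------------------------------------------
# Validation and bookkeeping
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TriMesh) -> list[str]:
    """Check TriMesh invariants; returns a list of violations (empty = valid)."""
    out: list[str] = []
    n = mesh.n_nodes
    if mesh.elements.size and (mesh.elements.min() < 0 or mesh.elements.max() >= n):
        out.append("element node index out of range")
        return out
    areas = element_areas(mesh.elements, mesh.node_coords)
    for i in np.nonzero(areas <= 0)[0]:
        out.append(f"element {i}: non-positive area")
    bad = ~np.isin(mesh.element_region, REGIONS)
    for i in np.nonzero(bad)[0][:10]:
        out.append(f"element {i}: unknown tissue label "
                   f"{mesh.element_region[i]!r} (expected gray/white)")
    for marker, edges in mesh.boundary_edges.items():
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            out.append(f"boundary marker {marker!r}: node index out of range")
    if mesh.boundary_edges.get("brainstem", np.empty(0)).size == 0:
        out.append("missing brainstem boundary marker (empty set)")
    # outer loop: pial + brainstem must close; ventricular loops close alone
    outer = [mesh.boundary_edges.get(m, np.empty((0, 2), np.int64))
             for m in ("pial", "brainstem")]
    outer = np.vstack(outer)
    if outer.size:
        closed, open_ = chain_loops(outer)
        if open_ or not closed:
            out.append("pial+brainstem edges do not form a closed outer loop")
        for loop in closed:
            if len(loop) >= 3 and not LineString(
                    np.vstack([mesh.node_coords[loop],
                               mesh.node_coords[loop[:1]]])).is_simple:
                out.append("outer boundary loop self-intersects")
    vent = mesh.boundary_edges.get("ventricular", np.empty((0, 2), np.int64))
    if vent.size:
        closed, open_ = chain_loops(vent)
        if open_:
            out.append("ventricular edges contain a non-closed chain "
                       f"(starts at node {open_[0][0]})")
        for loop in closed:
            if len(loop) >= 3 and not LineString(
                    np.vstack([mesh.node_coords[loop],
                               mesh.node_coords[loop[:1]]])).is_simple:
                out.append("ventricular loop self-intersects")
    return out


def dof_count(mesh: TriMesh) -> int:
    """Displacement unknowns before constraints: 2 per node."""
    return 2 * mesh.n_nodes


# ---------------------------------------------------------------------------
# Structured meshes for verification problems
# ---------------------------------------------------------------------------

def structured_rectangle_mesh(width: float, height: float, nx: int, ny: int,
                              crossed: bool = False, region: str = "gray") -> TriMesh:
    """Structured triangulation of [0,w]×[0,h]; bottom edge marked brainstem."""
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel()])
    def nid(i, j):
        return i * (ny + 1) + j
    cells = []
    extra = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if crossed:
                m = len(coords) + len(extra)
                extra.append(coords[[a, b, c, d]].mean(axis=0))
                cells += [[a, b, m], [b, c, m], [c, d, m], [d, a, m]]
            else:
                cells += [[a, b, c], [a, c, d]]
    if extra:
        coords = np.vstack([coords, np.array(extra)])
    cells = np.array(cells, dtype=np.int64)
    bedges = _boundary_edges_of(cells)
    mids = coords[bedges].mean(axis=1)
    bottom = np.isclose(mids[:, 1], 0.0)
    boundary_edges = {"brainstem": bedges[bottom], "pial": bedges[~bottom]}
    return TriMesh(coords, cells, np.full(len(cells), region, dtype="U16"),
                   boundary_edges=boundary_edges,
                   metadata={"generator": "structured-rectangle"})


def crossed_disc_mesh(outer_radius: float, core_radius: float,
                      n_r: int = 24, n_theta: int = 64) -> TriMesh:
    """Crossed (union-jack) polar mesh of a disc with a concentric core.

    Core elements (r < core_radius) are labeled gray, the surrounding ring
    white; the interface circle is mesh-conforming. The crossed arrangement
    avoids volumetric locking of linear triangles near incompressibility,
    which matters for the annulus verification problem.
    """
    radii = np.linspace(0.0, outer_radius, n_r + 1)[1:]
    # snap one ring exactly onto the core radius
    k = int(np.argmin(np.abs(radii - core_radius)))
    radii[k] = core_radius
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    coords = [np.zeros((1, 2))]
    for r in radii:
        coords.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    ring_start = lambda i: 1 + i * n_theta
    pts = np.vstack(coords)
    cells = []
    extra = []
    # innermost fan
    for j in range(n_theta):
        cells.append([0, ring_start(0) + j, ring_start(0) + (j + 1) % n_theta])
    for i in range(len(radii) - 1):
        for j in range(n_theta):
            a = ring_start(i) + j
            b = ring_start(i) + (j + 1) % n_theta
            c = ring_start(i + 1) + (j + 1) % n_theta
            d = ring_start(i + 1) + j
            m = len(pts) + len(extra)
            extra.append(pts[[a, b, c, d]].mean(axis=0))
            cells += [[a, b, m], [b, c, m], [c, d, m], [d, a, m]]
    pts = np.vstack([pts, np.array(extra)])
    cells = np.array(cells, dtype=np.int64)
    ar = element_areas(cells, pts)
    cells[ar < 0] = cells[ar < 0][:, [0, 2, 1]]
    cent = pts[cells].mean(axis=1)
    rad = np.hypot(cent[:, 0], cent[:, 1])
    region = np.where(rad < core_radius, "gray", "white").astype("U16")
    bedges = _boundary_edges_of(cells)
    return TriMesh(pts, cells, region,
                   boundary_edges={"pial": bedges,
                                   "brainstem": np.empty((0, 2), np.int64)},
                   metadata={"generator": "crossed-disc",
                             "core_radius": core_radius,
                             "outer_radius": outer_radius})
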