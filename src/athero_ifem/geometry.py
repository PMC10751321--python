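"""Synthetic plaque cross-sections and conforming labeled triangle meshes.

Real coronary plaque contours segmented from intravascular ultrasound are
not publicly deposited, so this module generates parametric surrogates: an
eccentric-lumen fibrotic annulus with elliptical lipid pools and
calcifications, optionally perturbed by smooth low-order Fourier contour
noise. The surrogates reproduce the geometric regimes that matter for the
inverse problem — a thin fibrous cap between lumen and lipid, multiple
inclusions, eccentric stenosis — without any patient data.

Meshing is done with a boundary-sampled Delaunay triangulation: every
region contour is sampled at the target edge length, interior points come
from a hexagonal lattice kept clear of the contours, and the Delaunay
triangulation of the union then contains every contour segment as an
element edge (verified, not assumed: :func:`mesh_plaque` audits conformity
and raises if any contour segment is missing). Tissue labels are assigned
per element, so no element straddles a material interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

__all__ = [
    "PlaqueSpec",
    "InclusionSpec",
    "PlaqueGeometry",
    "LabeledMesh",
    "PlacementError",
    "MeshingError",
    "generate_plaque",
    "mesh_plaque",
    "geometry_metrics",
    "annulus_mesh",
    "default_plaque_spec",
]

TissueKind = Literal["lipid", "calcification"]


class PlacementError(ValueError):
    """An inclusion cannot be placed while respecting the spec constraints."""


class MeshingError(RuntimeError):
    """The triangulation failed an invariant (conformity, orientation, cap)."""


# --------------------------------------------------------------------------
# specification & geometry containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InclusionSpec:
    """An elliptical tissue inclusion inside the plaque wall."""

    kind: TissueKind
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("lipid", "calcification"):
            raise ValueError(f"unknown tissue kind {self.kind!r}")
        if min(self.semi_axes) <= 0:
            raise ValueError("inclusion semi-axes must be positive")


@dataclass(frozen=True)
class PlaqueSpec:
    """Parametric description of a synthetic plaque cross-section [mm]."""

    outer_radius: float = 2.0
    lumen_radius: float = 0.9
    lumen_offset: tuple[float, float] = (0.5, 0.0)
    inclusions: tuple[InclusionSpec, ...] = ()
    min_cap_thickness: float = 0.2
    min_clearance: float = 0.15
    contour_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        off = math.hypot(*self.lumen_offset)
        if self.outer_radius <= self.lumen_radius + off:
            raise ValueError("lumen (with offset) must fit inside the outer wall")
        if self.min_cap_thickness <= 0:
            raise ValueError("min_cap_thickness must be positive")


@dataclass(frozen=True)
class PlaqueGeometry:
    """Closed polygonal contours [mm] of a plaque cross-section.

    Polygons are (K, 2) vertex arrays, implicitly closed, counter-clockwise.
    """

    outer_contour: np.ndarray
    lumen_contour: np.ndarray
    inclusion_contours: tuple[tuple[TissueKind, np.ndarray], ...] = ()

    def shapely_wall(self) -> Polygon:
        """The wall ring (outer minus lumen) as a shapely polygon."""
        return Polygon(self.outer_contour, holes=[self.lumen_contour[::-1]])

    def transformed(self, angle: float = 0.0, shift=(0.0, 0.0)) -> "PlaqueGeometry":
        """Rigidly rotated/translated copy (for invariance checks)."""
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s], [s, c]])
        t = np.asarray(shift, dtype=float)
        f = lambda p: p @ R.T + t
        return PlaqueGeometry(
            f(self.outer_contour), f(self.lumen_contour),
            tuple((k, f(p)) for k, p in self.inclusion_contours),
        )


# --------------------------------------------------------------------------
# geometry generation
# --------------------------------------------------------------------------

def _noisy_circle(radius: float, center, amplitude: float, rng: np.random.Generator,
                  n: int = 256) -> np.ndarray:
    """CCW circle with a smooth low-order Fourier radial perturbation."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r = np.full(n, radius)
    if amplitude > 0:
        modes = np.arange(2, 6)
        amps = rng.uniform(-1.0, 1.0, size=modes.size)
        phases = rng.uniform(0.0, 2.0 * math.pi, size=modes.size)
        bump = sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, modes, phases))
        peak = np.max(np.abs(bump))
        if peak > 0:
            r = r + amplitude * bump / peak
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def _ellipse(inc: InclusionSpec, n: int = 128) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    a, b = inc.semi_axes
    x, y = a * np.cos(theta), b * np.sin(theta)
    c, s = math.cos(inc.rotation), math.sin(inc.rotation)
    return np.column_stack([inc.center[0] + c * x - s * y,
                            inc.center[1] + s * x + c * y])


def generate_plaque(spec: PlaqueSpec) -> PlaqueGeometry:
    """Generate a plaque geometry from a parametric spec.

    Deterministic for a fixed seed. Raises :class:`PlacementError` if any
    inclusion cannot be placed respecting the cap-thickness and clearance
    constraints (inclusions are never silently clipped or moved).
    """
    rng = np.random.default_rng(spec.seed)
    outer = _noisy_circle(spec.outer_radius, (0.0, 0.0), spec.contour_noise_amplitude, rng)
    lumen = _noisy_circle(spec.lumen_radius, spec.lumen_offset,
                          0.5 * spec.contour_noise_amplitude, rng, n=192)
    outer_poly, lumen_poly = Polygon(outer), Polygon(lumen)
    if not (outer_poly.is_valid and lumen_poly.is_valid):
        raise PlacementError("noisy contour self-intersects; reduce noise amplitude")
    if not outer_poly.contains(lumen_poly):
        raise PlacementError("lumen is not strictly inside the outer contour")
    if outer_poly.exterior.distance(lumen_poly.exterior) < spec.min_clearance:
        raise PlacementError("wall thinner than min_clearance somewhere")

    contours: list[tuple[TissueKind, np.ndarray]] = []
    polys: list[Polygon] = []
    for idx, inc in enumerate(spec.inclusions):
        pts = _ellipse(inc)
        poly = Polygon(pts)
        name = f"{inc.kind} inclusion #{idx}"
        if not outer_poly.contains(poly) or \
                outer_poly.exterior.distance(poly) < spec.min_clearance:
            raise PlacementError(f"{name} too close to (or outside) the outer wall")
        if poly.intersects(lumen_poly):
            raise PlacementError(f"{name} overlaps the lumen")
        gap = poly.distance(lumen_poly)
        if inc.kind == "lipid" and gap < spec.min_cap_thickness - 1e-12:
            raise PlacementError(
                f"{name}: fibrous cap {gap:.3f} mm < min_cap_thickness "
                f"{spec.min_cap_thickness} mm")
        if inc.kind != "lipid" and gap < spec.min_clearance:
            raise PlacementError(f"{name} too close to the lumen")
        for j, other in enumerate(polys):
            if poly.distance(other) < spec.min_clearance:
                raise PlacementError(f"{name} too close to inclusion #{j}")
        contours.append((inc.kind, pts))
        polys.append(poly)
    return PlaqueGeometry(outer, lumen, tuple(contours))


def default_plaque_spec(include_calcification: bool = True,
                        contour_noise_amplitude: float = 0.03,
                        min_cap_thickness: float = 0.2,
                        seed: int = 0) -> PlaqueSpec:
    """The package's reference plaque: eccentric lumen, one lipid pool and
    (optionally) one calcification in a ~4 mm diameter wall.

    The lipid pool sits opposite the eccentric lumen with a nominal
    fibrous-cap gap of ``min_cap_thickness`` + 0.08 mm (margin absorbs the
    contour noise while keeping the realized cap above the minimum).
    """
    semi = (0.45, 0.26)
    lumen_left = 0.5 - 0.9  # lumen offset minus lumen radius
    cx = lumen_left - (min_cap_thickness + 0.08) - semi[0]
    inclusions = [InclusionSpec("lipid", (cx, 0.0), semi, 0.15)]
    if include_calcification:
        inclusions.append(InclusionSpec("calcification", (0.3, -1.45), (0.28, 0.17), -0.3))
    return PlaqueSpec(
        outer_radius=2.0, lumen_radius=0.9, lumen_offset=(0.5, 0.0),
        inclusions=tuple(inclusions), min_cap_thickness=min_cap_thickness,
        contour_noise_amplitude=contour_noise_amplitude, seed=seed,
    )


# --------------------------------------------------------------------------
# geometry metrics
# --------------------------------------------------------------------------

def geometry_metrics(geom: PlaqueGeometry) -> dict:
    """Vulnerability-related geometric measures.

    Returns ``cap_thickness`` (minimum lumen-to-lipid distance, ``None``
    when no lipid is present), ``lipid_area`` [mm^2] and the area stenosis
    fraction ``1 - lumen_area / outer_area``.
    """
    outer_poly = Polygon(geom.outer_contour)
    lumen_poly = Polygon(geom.lumen_contour)
    lipids = [Polygon(p) for k, p in geom.inclusion_contours if k == "lipid"]
    cap = min((lumen_poly.distance(p) for p in lipids), default=None)
    return {
        "cap_thickness": cap,
        "lipid_area": float(sum(p.area for p in lipids)),
        "stenosis_fraction": 1.0 - lumen_poly.area / outer_poly.area,
    }


# --------------------------------------------------------------------------
# labeled mesh container
# --------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Conforming 2D triangle mesh with per-element tissue labels.

    nodes : (N, 2) coordinates [mm]; triangles : (M, 3) CCW node indices;
    labels : length-M tissue labels; lumen_edges : directed boundary edges
    on the lumen, oriented with the wall on their left; outer_nodes /
    fixed_nodes : node indices on the outer contour (exactly 3 fixed).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    lumen_edges: np.ndarray
    outer_nodes: np.ndarray
    fixed_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.lumen_edges = np.asarray(self.lumen_edges, dtype=np.int64).reshape(-1, 2)
        self.outer_nodes = np.asarray(self.outer_nodes, dtype=np.int64)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)

    # -- basic derived quantities ----------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        p = self.nodes if coords is None else coords
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def centroids(self, coords: np.ndarray | None = None) -> np.ndarray:
        p = self.nodes if coords is None else coords
        return p[self.triangles].mean(axis=1)

    def lumen_centroid(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Centroid of the lumen polygon traced by the lumen boundary edges."""
        p = self.nodes if coords is None else coords
        ring = p[self.lumen_edges[:, 0]]
        poly = Polygon(ring[np.argsort(np.arctan2(*(ring - ring.mean(0)).T[::-1]))])
        return np.array(poly.centroid.coords[0])

    def element_labels_int(self) -> tuple[np.ndarray, list[str]]:
        names = sorted(set(self.labels.tolist()))
        lut = {n: i for i, n in enumerate(names)}
        return np.array([lut[l] for l in self.labels]), names

    def with_coordinates(self, coords: np.ndarray) -> "LabeledMesh":
        """Same topology and labels on a different nodal configuration."""
        return LabeledMesh(np.asarray(coords, float).copy(), self.triangles,
                           self.labels, self.lumen_edges, self.outer_nodes,
                           self.fixed_nodes)

    # -- audits -----------------------------------------------------------
    def boundary_edges(self) -> np.ndarray:
        """Directed edges used by exactly one triangle (domain on the left)."""
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        undirected = np.sort(edges, axis=1)
        _, inv, counts = np.unique(undirected, axis=0, return_inverse=True,
                                   return_counts=True)
        return edges[counts[inv] == 1]

    def audit(self) -> None:
        """Raise :class:`MeshingError` on any violated mesh invariant."""
        if np.any(self.signed_areas() <= 0):
            raise MeshingError("mesh contains non-CCW or degenerate triangles")
        if len(self.labels) != self.n_elements:
            raise MeshingError("labels do not cover every element")
        used = np.unique(self.triangles)
        if used.size != self.n_nodes:
            raise MeshingError("mesh has unused (hanging) nodes")
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        und, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshingError("non-manifold edge (shared by >2 triangles)")
        bset = {tuple(sorted(e)) for e in self.boundary_edges()}
        for e in self.lumen_edges:
            if tuple(sorted(e)) not in bset:
                raise MeshingError("lumen edge is not a mesh boundary edge")
        if self.fixed_nodes.size != 3:
            raise MeshingError("exactly 3 fixed nodes are required")
        if not np.all(np.isin(self.fixed_nodes, self.outer_nodes)):
            raise MeshingError("fixed nodes must lie on the outer contour")
        ctr = self.nodes[self.outer_nodes].mean(axis=0)
        ang = np.sort([math.atan2(*(self.nodes[i] - ctr)[::-1]) for i in self.fixed_nodes])
        gaps = np.diff(np.append(ang, ang[0] + 2 * math.pi))
        if np.min(2 * math.pi - gaps) < math.pi / 2 - 1e-9:
            raise MeshingError("fixed nodes are separated by less than 90 degrees")


# --------------------------------------------------------------------------
# meshing
# --------------------------------------------------------------------------

def _resample_closed(poly: np.ndarray, h: float) -> np.ndarray:
    """Resample a closed polygon at approximately uniform spacing h."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(12, int(math.ceil(s[-1] / h)))
    si = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def _fixed_node_choice(nodes: np.ndarray, outer_nodes: np.ndarray) -> np.ndarray:
    """3 outer nodes nearest to 0, 120 and 240 degrees about the centroid."""
    pts = nodes[outer_nodes]
    ctr = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0])
    picks = []
    for target in (0.0, 2 * math.pi / 3, -2 * math.pi / 3):
        d = np.abs((ang - target + math.pi) % (2 * math.pi) - math.pi)
        picks.append(outer_nodes[int(np.argmin(d))])
    return np.array(picks, dtype=np.int64)


def _cap_layers(mesh: LabeledMesh) -> int | None:
    """Fewest fibrotic elements crossed from a lumen edge to a lipid element."""
    is_lipid = np.array([str(l).startswith("lipid") for l in mesh.labels])
    if not is_lipid.any():
        return None
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    owner = np.tile(np.arange(mesh.n_elements), 3)
    und = np.sort(edges, axis=1)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und, owner = und[order], owner[order]
    same = np.all(und[1:] == und[:-1], axis=1)
    a, b = owner[:-1][same], owner[1:][same]
    n = mesh.n_elements
    g = coo_matrix((np.ones(a.size), (a, b)), shape=(n, n))
    g = g + g.T
    lumen_nodes = set(mesh.lumen_edges.ravel().tolist())
    touches_lumen = np.array([len(lumen_nodes.intersection(tri)) >= 2 for tri in t])
    seeds = np.flatnonzero(touches_lumen)
    dist = shortest_path(g.tocsr(), unweighted=True, indices=seeds, method="D")
    best = dist[:, is_lipid].min()
    return int(best)  # = number of fibrotic elements strictly between


def mesh_plaque(geom: PlaqueGeometry, target_edge_length: float) -> LabeledMesh:
    """Triangulate a plaque geometry into a conforming labeled mesh.

    Every region contour is sampled at the target edge length and appears
    verbatim as element edges; element labels follow the polygon containing
    the element centroid. Raises :class:`MeshingError` when conformity or
    orientation cannot be certified, and when a fibrous cap is resolved by
    fewer than 3 element layers.
    """
    h = float(target_edge_length)
    if h <= 0:
        raise ValueError("target_edge_length must be positive")

    rings: list[np.ndarray] = [_resample_closed(geom.outer_contour, h),
                               _resample_closed(geom.lumen_contour, h)]
    for _, pts in geom.inclusion_contours:
        rings.append(_resample_closed(pts, h))
    ring_start = np.cumsum([0] + [r.shape[0] for r in rings])
    boundary_pts = np.vstack(rings)

    outer_poly = Polygon(rings[0])
    lumen_poly = Polygon(rings[1])
    wall = Polygon(rings[0], holes=[rings[1][::-1]])
    wall_prep = prep(wall)
    ring_lines = [Polygon(r).exterior for r in rings]

    # hexagonal interior lattice, kept clear of all contours
    xmin, ymin, xmax, ymax = outer_poly.bounds
    dy = h * math.sqrt(3.0) / 2.0
    ys = np.arange(ymin - h, ymax + h, dy)
    lattice = []
    for row, y in enumerate(ys):
        xs = np.arange(xmin - h, xmax + h, h) + (0.5 * h if row % 2 else 0.0)
        lattice.append(np.column_stack([xs, np.full(xs.size, y)]))
    lattice = np.vstack(lattice)
    keep = np.fromiter((wall_prep.contains(Point(p)) for p in lattice),
                       bool, count=lattice.shape[0])
    lattice = lattice[keep]
    clearance = 0.62 * h
    for line in ring_lines:
        if lattice.size == 0:
            break
        d = np.fromiter((line.distance(Point(p)) for p in lattice),
                        float, count=lattice.shape[0])
        lattice = lattice[d >= clearance]

    points = np.vstack([boundary_pts, lattice])
    tri = Delaunay(points)
    cells = tri.simplices
    centroids = points[cells].mean(axis=1)
    inside = np.fromiter((wall_prep.contains(Point(c)) for c in centroids),
                         bool, count=centroids.shape[0])
    cells = cells[inside]
    if cells.size == 0:
        raise MeshingError("triangulation produced no wall elements")

    # enforce CCW orientation
    a, b, c = (points[cells[:, i]] for i in range(3))
    areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    flip = areas < 0
    cells[flip] = cells[flip][:, [0, 2, 1]]
    if np.any(np.abs(areas) < 1e-14):
        raise MeshingError("degenerate (zero-area) triangle produced")

    # compact node numbering
    used = np.unique(cells)
    remap = -np.ones(points.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = points[used]
    cells = remap[cells]

    # conformity audit: every contour segment must be an element edge
    edge_set = set()
    for t_ in cells:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            edge_set.add((min(t_[i], t_[j]), max(t_[i], t_[j])))
    for r in range(len(rings)):
        lo, hi = ring_start[r], ring_start[r + 1]
        for k in range(lo, hi):
            u, v = remap[k], remap[lo + (k - lo + 1) % (hi - lo)]
            if u < 0 or v < 0 or (min(u, v), max(u, v)) not in edge_set:
                raise MeshingError(
                    f"mesh does not conform to contour {r} near segment {k - lo}")

    # labels from centroid point-in-polygon
    centroids = nodes[cells].mean(axis=1)
    labels = np.array(["fibrotic"] * cells.shape[0], dtype=object)
    counters = {"lipid": 0, "calcification": 0}
    for (kind, _), r in zip(geom.inclusion_contours, range(2, len(rings))):
        counters[kind] += 1
        name = f"{kind}_{counters[kind]}"
        poly_prep = prep(Polygon(rings[r]))
        inside_inc = np.fromiter((poly_prep.contains(Point(p)) for p in centroids),
                                 bool, count=centroids.shape[0])
        labels[inside_inc] = name

    lumen_idx = set(remap[ring_start[1]:ring_start[2]].tolist())
    outer_idx = remap[ring_start[0]:ring_start[1]]

    mesh = LabeledMesh(
        nodes=nodes, triangles=cells, labels=labels,
        lumen_edges=np.empty((0, 2), dtype=np.int64),
        outer_nodes=outer_idx,
        fixed_nodes=_fixed_node_choice(nodes, outer_idx),
    )
    bnd = mesh.boundary_edges()
    on_lumen = np.array([e[0] in lumen_idx and e[1] in lumen_idx for e in bnd])
    mesh.lumen_edges = bnd[on_lumen]
    mesh.audit()

    layers = _cap_layers(mesh)
    if layers is not None and layers < 3:
        raise MeshingError(
            f"fibrous cap resolved by only {layers} element layers (< 3); "
            "decrease target_edge_length")
    return mesh


# --------------------------------------------------------------------------
# structured annulus mesh (analytic-oracle geometry)
# --------------------------------------------------------------------------

def annulus_mesh(a: float, b: float, n_r: int = 12, n_theta: int = 64,
                 crossed: bool = True, label: str = "fibrotic") -> LabeledMesh:
    """Structured annulus mesh (inner radius a, outer b), single tissue.

    With ``crossed=True`` each quad is split into four triangles at its
    centroid — a pattern that behaves well under near-incompressibility and
    is used for comparisons against the thick-walled-cylinder solutions.
    """
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    r = np.linspace(a, b, n_r + 1)
    th = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    ring_nodes = np.array([[ri * math.cos(t), ri * math.sin(t)]
                           for ri in r for t in th])
    idx = lambda i, j: i * n_theta + (j % n_theta)
    nodes = [ring_nodes]
    tris = []
    nxt = ring_nodes.shape[0]
    for i in range(n_r):
        for j in range(n_theta):
            q = [idx(i, j), idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)]
            if crossed:
                quad_pts = np.vstack([nodes[0][k] for k in q])
                nodes.append(quad_pts.mean(axis=0, keepdims=True))
                ctr = nxt
                nxt += 1
                for k in range(4):
                    tris.append([q[k], q[(k + 1) % 4], ctr])
            else:
                tris.append([q[0], q[1], q[2]])
                tris.append([q[0], q[2], q[3]])
    nodes = np.vstack(nodes)
    tris = np.asarray(tris, dtype=np.int64)

    labels = np.array([label] * tris.shape[0], dtype=object)
    outer_idx = np.arange(n_r * n_theta, (n_r + 1) * n_theta, dtype=np.int64)
    mesh = LabeledMesh(nodes, tris, labels,
                       lumen_edges=np.empty((0, 2), dtype=np.int64),
                       outer_nodes=outer_idx,
                       fixed_nodes=_fixed_node_choice(nodes, outer_idx))
    bnd = mesh.boundary_edges()
    rad = np.linalg.norm(nodes[bnd[:, 0]], axis=1)
    mesh.lumen_edges = bnd[rad < 0.5 * (a + b)]
    mesh.audit()
    return mesh
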