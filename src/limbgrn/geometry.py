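"""Synthetic growing limb-bud domain.

The real mouse limb-bud growth map (derived from clonal fate maps and a
morphometric shape database) is not distributed, so this module generates a
stylized stand-in that preserves the two geometric facts the downstream
analysis relies on: a *straight* proximal RA source line (the embryo flank)
and a *curved* distal FGF source arc (the AER).  The domain at hour ``h`` is a
half-ellipse attached to a flank baseline at x = 0; the proximodistal (PD)
semi-axis grows much faster than the anteroposterior (AP) one, giving
anisotropic, distally biased growth.  The tissue is fully remeshed at 1-hour
intervals, and mass-conserving transfer maps redistribute per-element amounts
from each mesh into the next.

Coordinate convention: PD coordinate = x (um, flank at x = 0), AP coordinate
= y (um, posterior = negative y).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: per-element region labels
MESENCHYME = 0
FLANK_SOURCE = 1
AER_SOURCE = 2
AER_FGF4_SOURCE = 3

REGION_NAMES = {
    MESENCHYME: "mesenchyme",
    FLANK_SOURCE: "flank_source",
    AER_SOURCE: "aer_source",
    AER_FGF4_SOURCE: "aer_fgf4_source",
}


class MeshError(ValueError):
    """Raised for invalid outlines or degenerate triangulations."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the parametric limb-bud outline.

    Units are um and hours.  Defaults give an initial PD extent of 350 um
    growing to ~1100 um over 36 h, with a slowly widening flank, so distal
    expansion is much faster than proximal/lateral expansion (anisotropy).
    """

    initial_pd_extent: float = 350.0
    final_pd_extent: float = 1100.0
    growth_hours: float = 36.0
    flank_half_width: float = 300.0
    flank_widening_rate: float = 2.0  # um/h added to the half-width
    #: posterior fraction of the AER arc expressing FGF4 at hour 0 ...
    fgf4_initial_fraction: float = 0.3
    #: ... expanding linearly to the whole arc by this hour
    fgf4_full_hour: float = 18.0
    #: AER occupies |angle| <= aer_angular_extent * (pi/2) of the distal arc
    #: (the ridge is the distal rim, not the full margin down to the flank)
    aer_angular_extent: float = 0.75

    def pd_extent(self, hour: float) -> float:
        frac = hour / self.growth_hours
        return self.initial_pd_extent + (self.final_pd_extent - self.initial_pd_extent) * frac

    def half_width(self, hour: float) -> float:
        return self.flank_half_width + self.flank_widening_rate * hour

    def fgf4_fraction(self, hour: float) -> float:
        f = self.fgf4_initial_fraction
        return min(1.0, f + (1.0 - f) * hour / self.fgf4_full_hour)


def build_limb_outline(hour: float, params: GeometryParams | None = None,
                       n_arc: int = 96) -> Polygon:
    """Closed polygon outline of the bud at ``hour``.

    The boundary is the half-ellipse x = L cos(t), y = b sin(t) for
    t in [-pi/2, pi/2] (distal arc) closed by the straight flank segment at
    x = 0.  Arc vertices are spaced uniformly in arc length.
    """
    params = params or GeometryParams()
    L = params.pd_extent(hour)
    b = params.half_width(hour)
    if L <= 0 or b <= 0:
        raise MeshError(f"degenerate outline at hour {hour}: L={L}, b={b}")
    # uniform-arc-length sampling of the half ellipse
    t_fine = np.linspace(-np.pi / 2, np.pi / 2, 20 * n_arc)
    pts_fine = np.column_stack([L * np.cos(t_fine), b * np.sin(t_fine)])
    seg = np.linalg.norm(np.diff(pts_fine, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_target = np.linspace(0.0, s[-1], n_arc + 1)
    t_arc = np.interp(s_target, s, t_fine)
    arc = np.column_stack([L * np.cos(t_arc), b * np.sin(t_arc)])
    arc[0] = (0.0, -b)
    arc[-1] = (0.0, b)
    poly = Polygon(arc)  # flank chord closes the ring
    if not poly.is_valid or poly.area <= 0:
        raise MeshError(f"self-intersecting or empty outline at hour {hour} "
                        f"(L={L:.1f}, b={b:.1f})")
    return poly


def _triangle_quality(v: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Radius-ratio quality 2*r_in/r_circ in (0, 1], 1 for equilateral."""
    p0, p1, p2 = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    a = np.linalg.norm(p1 - p2, axis=1)
    b = np.linalg.norm(p0 - p2, axis=1)
    c = np.linalg.norm(p0 - p1, axis=1)
    area = 0.5 * np.abs(((p1 - p0)[:, 0] * (p2 - p0)[:, 1] - (p1 - p0)[:, 1] * (p2 - p0)[:, 0]))
    s = 0.5 * (a + b + c)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_in = area / s
        r_circ = a * b * c / (4.0 * np.maximum(area, 1e-300))
        q = 2.0 * r_in / r_circ
    return np.nan_to_num(q)


@dataclass
class TriMesh:
    """A conforming triangulation of one hourly domain snapshot.

    ``adjacency`` rows are interior edges: (element_i, element_j) with the
    shared edge length and centroid-to-centroid distance (um).  Each interior
    edge appears exactly once.
    """

    vertices: np.ndarray          # (nv, 2) um
    triangles: np.ndarray         # (nt, 3) int, CCW
    element_area: np.ndarray      # (nt,) um^2
    edge_elements: np.ndarray     # (ne, 2) int
    edge_length: np.ndarray       # (ne,) um
    edge_dist: np.ndarray         # (ne,) um  centroid-to-centroid
    region_labels: np.ndarray     # (nt,) int8
    hour: float = 0.0
    centroids: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.centroids is None:
            self.centroids = self.vertices[self.triangles].mean(axis=1)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.element_area.sum())

    def elements_in_region(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.region_labels == label)

    def element_polygons(self) -> list[Polygon]:
        return [Polygon(self.vertices[t]) for t in self.triangles]

    def min_quality(self) -> float:
        return float(_triangle_quality(self.vertices, self.triangles).min())


def _hex_lattice(xmin, xmax, ymin, ymax, spacing, offset=0.0):
    dy = spacing * math.sqrt(3.0) / 2.0
    rows = []
    y = ymin + offset * dy
    row = 0
    while y <= ymax:
        x0 = xmin + (spacing / 2.0 if row % 2 else 0.0)
        xs = np.arange(x0, xmax + 1e-9, spacing)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def triangulate(outline: Polygon, target_edge: float, *, hour: float = 0.0,
                params: GeometryParams | None = None,
                quality_floor: float = 0.08,
                lattice_offset: float = 0.0) -> TriMesh:
    """Triangulate ``outline`` with edges near ``target_edge`` um.

    Boundary vertices are placed at ~target_edge spacing along the flank and
    the distal arc; interior vertices come from a hexagonal lattice clipped
    away from the boundary; the Delaunay triangulation of the union is then
    restricted to triangles whose centroid lies inside the outline.  Region
    labels are assigned from boundary geometry (see module docstring).
    """
    params = params or GeometryParams()
    if target_edge <= 0:
        raise MeshError("target_edge must be positive")
    coords = np.asarray(outline.exterior.coords[:-1])
    b = params.half_width(hour)
    L = params.pd_extent(hour)
    if target_edge > min(L, 2 * b) / 2.5:
        raise MeshError(f"target_edge {target_edge} too large for feature size "
                        f"min(L, 2b)={min(L, 2 * b):.1f}")

    # boundary points: resample outline ring at ~target_edge spacing
    ring = outline.exterior
    n_b = max(8, int(round(ring.length / target_edge)))
    bpts = np.array([ring.interpolate(i * ring.length / n_b).coords[0]
                     for i in range(n_b)])

    for offset in (lattice_offset, lattice_offset + 0.33,
                   lattice_offset + 0.67):
        inner = outline.buffer(-0.55 * target_edge)
        lat = _hex_lattice(coords[:, 0].min(), coords[:, 0].max(),
                           coords[:, 1].min(), coords[:, 1].max(),
                           target_edge, offset)
        if inner.is_empty or len(lat) == 0:
            ipts = np.empty((0, 2))
        else:
            keep = shapely.contains_xy(inner, lat[:, 0], lat[:, 1])
            ipts = lat[keep]
        pts = np.vstack([bpts, ipts])
        tri = Delaunay(pts)
        simplices = tri.simplices
        cent = pts[simplices].mean(axis=1)
        inside = shapely.contains_xy(outline, cent[:, 0], cent[:, 1])
        simplices = simplices[inside]
        # enforce CCW orientation
        v0, v1, v2 = (pts[simplices[:, k]] for k in range(3))
        cross = ((v1 - v0)[:, 0] * (v2 - v0)[:, 1]
             - (v1 - v0)[:, 1] * (v2 - v0)[:, 0])
        flip = cross < 0
        simplices[flip, 1], simplices[flip, 2] = \
            simplices[flip, 2].copy(), simplices[flip, 1].copy()
        area = 0.5 * np.abs(cross)
        good = area > 1e-9 * target_edge ** 2
        simplices, area = simplices[good], area[good]
        q = _triangle_quality(pts, simplices)
        if len(simplices) and q.min() >= quality_floor:
            break
    else:
        raise MeshError(f"triangulation quality below floor {quality_floor} "
                        f"at hour {hour} (min q={q.min():.3f}); relax target_edge")

    mesh = _finalize_mesh(pts, simplices, area, hour, params, L, b)
    return mesh


def _finalize_mesh(pts, simplices, area, hour, params, L, b) -> TriMesh:
    # adjacency: map sorted vertex-pair -> incident elements
    edge_map: dict[tuple[int, int], list[int]] = {}
    for e, t in enumerate(simplices):
        for a_, b_ in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (a_, b_) if a_ < b_ else (b_, a_)
            edge_map.setdefault(key, []).append(e)

    centroids = pts[simplices].mean(axis=1)
    interior, lengths, dists = [], [], []
    boundary_edges: list[tuple[tuple[int, int], int]] = []
    for key, els in edge_map.items():
        if len(els) == 2:
            i, j = els
            elen = float(np.linalg.norm(pts[key[0]] - pts[key[1]]))
            d = float(np.linalg.norm(centroids[i] - centroids[j]))
            if d <= 0:
                raise MeshError("zero centroid distance on interior edge")
            interior.append((i, j))
            lengths.append(elen)
            dists.append(d)
        elif len(els) == 1:
            boundary_edges.append((key, els[0]))

    labels = np.zeros(len(simplices), dtype=np.int8)
    f_frac = params.fgf4_fraction(hour)
    amax = params.aer_angular_extent * (np.pi / 2)
    for (va, vb), el in boundary_edges:
        mid = 0.5 * (pts[va] + pts[vb])
        if pts[va][0] < 1e-6 * L and pts[vb][0] < 1e-6 * L:
            labels[el] = FLANK_SOURCE
        else:
            phi = math.atan2(mid[1] / b, mid[0] / L)
            if abs(phi) <= amax:
                # posterior fraction of the AER arc expresses FGF4
                if phi <= -amax + f_frac * 2 * amax:
                    labels[el] = AER_FGF4_SOURCE
                else:
                    labels[el] = AER_SOURCE

    return TriMesh(
        vertices=pts, triangles=simplices, element_area=area,
        edge_elements=np.asarray(interior, dtype=np.int64).reshape(-1, 2),
        edge_length=np.asarray(lengths), edge_dist=np.asarray(dists),
        region_labels=labels, hour=hour,
    )


@dataclass
class TransferMap:
    """Mass-conserving redistribution of element amounts between meshes.

    ``matrix`` is (n_new, n_old); column i distributes old element i's amount
    over the new elements it overlaps after being pushed forward by the growth
    displacement, so every column sums to 1 and total amount is conserved.
    """

    matrix: csr_matrix
    source_hour: float
    target_hour: float

    def remap_amounts(self, amounts: np.ndarray) -> np.ndarray:
        return self.matrix @ amounts

    def remap_concentration(self, conc: np.ndarray, old: TriMesh,
                            new: TriMesh) -> np.ndarray:
        """Remap concentrations; ``conc`` may be (n_old,) or (S, n_old)."""
        amounts = conc * old.element_area
        new_amounts = (self.matrix @ amounts.T).T
        return new_amounts / new.element_area


def growth_displacement(params: GeometryParams, h_from: float, h_to: float):
    """Material displacement of the synthetic growth law between two hours.

    The growth map is affine: a material point scales with the domain
    semi-axes, (x, y) -> (x * L'/L, y * b'/b).  Distal points therefore move
    farther than proximal points (PD-biased elongation).
    """
    sx = params.pd_extent(h_to) / params.pd_extent(h_from)
    sy = params.half_width(h_to) / params.half_width(h_from)

    def displace(xy: np.ndarray) -> np.ndarray:
        out = np.array(xy, dtype=float)
        out[..., 0] *= sx
        out[..., 1] *= sy
        return out

    return displace


def compute_transfer_map(old: TriMesh, new: TriMesh,
                         displace=None) -> TransferMap:
    """Build the transfer map from exact area overlaps of displaced elements.

    Each old element triangle is pushed forward by ``displace`` (identity if
    None) and clipped against the new elements (shapely exact clipping).  The
    overlap matrix is column-normalized so each old element's amount is fully
    redistributed; an old element with no overlap at all is assigned to the
    nearest new element (conservation takes priority over locality).
    """
    new_polys = new.element_polygons()
    tree = STRtree(new_polys)
    disp_vertices = displace(old.vertices) if displace is not None else old.vertices
    rows, cols, vals = [], [], []
    lost = []
    for i, t in enumerate(old.triangles):
        p = Polygon(disp_vertices[t])
        cand = tree.query(p, predicate="intersects")
        total = 0.0
        entries = []
        for j in cand:
            a = p.intersection(new_polys[j]).area
            if a > 0:
                entries.append((int(j), a))
                total += a
        if total <= 0:
            lost.append(i)
            continue
        for j, a in entries:
            rows.append(j)
            cols.append(i)
            vals.append(a / total)
    if lost:
        kd = cKDTree(new.centroids)
        disp_cent = disp_vertices[old.triangles[lost]].mean(axis=1)
        _, nearest = kd.query(disp_cent)
        for i, j in zip(lost, np.atleast_1d(nearest)):
            rows.append(int(j))
            cols.append(int(i))
            vals.append(1.0)
        logger.warning("transfer map %s->%s: %d element(s) had no overlap; "
                       "assigned to nearest new element",
                       old.hour, new.hour, len(lost))
    T = csr_matrix((vals, (rows, cols)),
                   shape=(new.n_elements, old.n_elements))
    return TransferMap(matrix=T, source_hour=old.hour, target_hour=new.hour)


def stage_of_hour(hour: int, start_day: int = 10, start_hour: int = 9) -> str:
    """Limb staging label for a simulation hour (hour 0 = mE10:09).

    The notation mE<day>:<hh> means mouse embryonic day <day> plus <hh> hours;
    the counter rolls over to the next day at 24 h.
    """
    total = start_hour + int(hour)
    return f"mE{start_day + total // 24}:{total % 24:02d}"


@dataclass
class GrowthSeries:
    """Ordered hourly meshes plus the transfer maps linking them."""

    meshes: list[TriMesh]
    transfer_maps: list[TransferMap]
    params: GeometryParams
    target_edge: float

    @property
    def n_hours(self) -> int:
        return len(self.meshes) - 1

    def stage_of_hour(self, hour: int) -> str:
        return stage_of_hour(hour)

    def stages(self) -> list[str]:
        return [stage_of_hour(h) for h in range(len(self.meshes))]


def build_growth_series(n_hours: int = 36,
                        params: GeometryParams | None = None,
                        target_edge: float = 45.0) -> GrowthSeries:
    """Meshes for hours 0..n_hours with transfer maps between consecutive pairs."""
    if n_hours < 1:
        raise ValueError("n_hours must be >= 1")
    params = params or GeometryParams()
    meshes = []
    for h in range(n_hours + 1):
        try:
            outline = build_limb_outline(h, params)
            meshes.append(triangulate(outline, target_edge, hour=h, params=params))
        except MeshError as exc:
            raise MeshError(f"growth series construction failed at hour {h}: {exc}")
    maps = []
    for h in range(n_hours):
        disp = growth_displacement(params, h, h + 1)
        maps.append(compute_transfer_map(meshes[h], meshes[h + 1], disp))
    return GrowthSeries(meshes=meshes, transfer_maps=maps, params=params,
                        target_edge=target_edge)
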