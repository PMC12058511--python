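"""Extrusion of cell tessellations into triangulated membrane meshes.

Each cell footprint on the unrolled chart is triangulated by clipping it with
a structured grid (grid pitch chosen so that no triangle exceeds the requested
area threshold) and ear-clipping every clipped piece.  The footprint
triangulation is instantiated twice — on the abluminal (outer) and luminal
(inner) cylinder surface — and lateral walls connect the two boundary rings,
giving a watertight closed surface per cell.  Walls between adjacent cells
reference one common node set and carry both owner tags, so equal internal
cell pressures cancel exactly on them.

Triangle orientation convention: the stored vertex order makes the geometric
normal point *outward from the first owner cell*.  For the luminal face that
is toward the vessel axis, for the abluminal face away from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, Point, box
from shapely.prepared import prep

from .geometry import CylinderDomain
from .templates import CellTessellation, TessellationError

_SNAP = 1e-6

TAG_LUMINAL = 0
TAG_ABLUMINAL = 1
TAG_LATERAL = 2
TAG_SHARED_LATERAL = 3
TAG_NAMES = {
    TAG_LUMINAL: "luminal",
    TAG_ABLUMINAL: "abluminal",
    TAG_LATERAL: "lateral",
    TAG_SHARED_LATERAL: "shared_lateral",
}


@dataclass
class MembraneMesh:
    """Triangulated membrane surfaces of the extruded cell monolayer."""

    nodes: np.ndarray  # (N, 3) reference coordinates, µm
    node_layer: np.ndarray  # (N,) 0 = outer/abluminal surface, 1 = inner/luminal
    node_chart: np.ndarray  # (N, 2) canonical unrolled (x, z)
    triangles: np.ndarray  # (M, 3) vertex indices
    tags: np.ndarray  # (M,) TAG_* codes
    owners: np.ndarray  # (M, 2) owning cell ids, -1 = none
    thickness: float
    depth: float
    domain: CylinderDomain = None
    outer_radius: float = 0.0
    inner_radius: float = 0.0
    is_reference: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_cells(self) -> int:
        return int(self.owners.max()) + 1

    def triangle_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        p = self.nodes if coords is None else coords
        a = p[self.triangles[:, 0]]
        b = p[self.triangles[:, 1]]
        c = p[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_normals(self, coords: np.ndarray | None = None) -> np.ndarray:
        p = self.nodes if coords is None else coords
        a = p[self.triangles[:, 0]]
        b = p[self.triangles[:, 1]]
        c = p[self.triangles[:, 2]]
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def cell_triangles(self, cell: int) -> np.ndarray:
        return np.where((self.owners[:, 0] == cell) | (self.owners[:, 1] == cell))[0]

    def cell_surface_euler(self, cell: int) -> dict:
        """Euler characteristic and manifoldness of one cell's closed surface."""
        tri = self.triangles[self.cell_triangles(cell)]
        verts = np.unique(tri)
        edges = np.vstack(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        V, E, F = len(verts), len(uniq), len(tri)
        return {
            "V": V,
            "E": E,
            "F": F,
            "euler": V - E + F,
            "closed_manifold": bool(np.all(counts == 2)),
        }

    def boundary_node_mask(self, margin: float = 1e-6) -> np.ndarray:
        """Nodes on the two end rings (z = 0 and z = L)."""
        z = self.node_chart[:, 1]
        L = self.domain.axial_length
        return (z < margin) | (z > L - margin)


# ---------------------------------------------------------------------------
# ear clipping
# ---------------------------------------------------------------------------


def _point_in_tri(p, a, b, c, eps=1e-9):
    d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
    d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
    return d1 >= -eps and d2 >= -eps and d3 >= -eps


def _earclip(pts: np.ndarray) -> list:
    """Triangulate a simple polygon ring (open, any orientation)."""
    n = len(pts)
    if n < 3:
        return []
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    idx = list(range(n)) if signed > 0 else list(range(n - 1, -1, -1))
    tris = []
    stall = 0
    while len(idx) > 3:
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-12:
                continue
            blocked = False
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                if _point_in_tri(pts[j], a, b, c):
                    blocked = True
                    break
            if not blocked:
                tris.append((i0, i1, i2))
                del idx[k]
                clipped = True
                break
        if not clipped:
            # degenerate remainder (collinear sliver): drop the flattest vertex
            stall += 1
            if stall > n:
                return tris
            best_k, best_cross = 0, np.inf
            for k in range(m):
                i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
                a, b, c = pts[i0], pts[i1], pts[i2]
                cr = abs(
                    (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                )
                if cr < best_cross:
                    best_cross, best_k = cr, k
            del idx[best_k]
    if len(idx) == 3:
        tris.append(tuple(idx))
    return tris


def _clean_ring(coords) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > 1e-9:
            keep.append(i)
    if len(keep) > 2 and np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) <= 1e-9:
        keep = keep[:-1]
    return pts[keep]


# ---------------------------------------------------------------------------
# border refinement
# ---------------------------------------------------------------------------


def _subdivide_segments(coords: np.ndarray, max_len: float) -> np.ndarray:
    out = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / max_len)))
        for j in range(1, k + 1):
            out.append(a + (b - a) * (j / k))
    return np.array(out)


def _snap_to_grid(coords: np.ndarray, hx: float, hz: float, tol: float = 0.01):
    """Snap vertices onto grid lines they almost touch (sliver prevention).

    Displacements are bounded by ``tol`` µm — far below any geometric scale of
    the problem — and identical for both cells sharing a border.
    """
    out = coords.copy()
    for dim, h in ((0, hx), (1, hz)):
        g = np.round(out[:, dim] / h) * h
        near = np.abs(out[:, dim] - g) < tol
        out[near, dim] = g[near]
    return out


def _insert_grid_crossings(coords: np.ndarray, hx: float, hz: float) -> np.ndarray:
    """Insert intersections with grid lines x = i*hx and z = j*hz."""
    out = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        ts = []
        for dim, h in ((0, hx), (1, hz)):
            lo, hi = sorted((a[dim], b[dim]))
            i0 = int(np.ceil(lo / h - 1e-12))
            i1 = int(np.floor(hi / h + 1e-12))
            for i in range(i0, i1 + 1):
                v = i * h
                denom = b[dim] - a[dim]
                if abs(denom) < 1e-15:
                    continue
                t = (v - a[dim]) / denom
                if 1e-9 < t < 1 - 1e-9:
                    ts.append(t)
        for t in sorted(set(np.round(ts, 12))):
            p = a + (b - a) * t
            if np.linalg.norm(p - out[-1]) > 1e-9:
                out.append(p)
        if np.linalg.norm(b - out[-1]) > 1e-9:
            out.append(b)
    return np.array(out)


# ---------------------------------------------------------------------------
# main meshing operation
# ---------------------------------------------------------------------------


class _NodeRegistry:
    def __init__(self, domain: CylinderDomain, depth: float):
        self.domain = domain
        self.depth = depth
        self.index: dict = {}
        self.coords3d: list = []
        self.layer: list = []
        self.chart: list = []
        self._qP = round(domain.circumference / _SNAP)

    def key(self, x: float, z: float, layer: int):
        qx = round((x % self.domain.circumference) / _SNAP) % self._qP
        return (layer, qx, round(z / _SNAP))

    def get(self, x: float, z: float, layer: int) -> int:
        k = self.key(x, z, layer)
        if k in self.index:
            return self.index[k]
        i = len(self.coords3d)
        self.index[k] = i
        r = (
            self.domain.radius
            if layer == 0
            else self.domain.radius - self.depth
        )
        p3 = self.domain.to_3d(x, z, r)
        self.coords3d.append(p3)
        self.layer.append(layer)
        self.chart.append((x % self.domain.circumference, z))
        return i


def extrude_and_mesh(
    tess: CellTessellation,
    depth: float = 2.0,
    max_triangle_area: float = 4.0,
) -> MembraneMesh:
    """Extrude a tessellation inward and triangulate all membrane surfaces.

    ``depth`` is the radial cell depth in µm (default 2 µm), and
    ``max_triangle_area`` the triangle area threshold in µm² (default 4 µm²).
    """
    if depth <= 0 or max_triangle_area <= 0:
        raise ValueError("depth and max_triangle_area must be positive")
    domain = tess.domain
    if depth >= domain.radius:
        raise ValueError(
            f"extrusion depth {depth} µm >= vessel radius {domain.radius} µm"
        )
    P, L = domain.circumference, domain.axial_length

    h = np.sqrt(2.0 * max_triangle_area)
    hx = P / int(np.ceil(P / h))
    hz = L / int(np.ceil(L / h))

    # refine borders: wall-segment cap + grid crossings, shared by both cells
    wall_seg_cap = 2.0 * max_triangle_area / depth
    refined = []
    for b in tess.borders:
        c = _subdivide_segments(np.asarray(b.coords, float), min(wall_seg_cap, h))
        c[1:-1] = _snap_to_grid(c[1:-1], hx, hz)  # endpoints are shared nodes
        c = _insert_grid_crossings(c, hx, hz)
        refined.append(c)
    tref = tess.with_border_coords(refined)

    reg = _NodeRegistry(domain, depth)
    tri_list: list = []
    tag_list: list = []
    owner_list: list = []

    # --- faces
    for ci, ring in enumerate(tref.cells):
        poly = Polygon(ring)
        if not poly.is_valid:
            raise TessellationError(f"cell {ci}: invalid footprint polygon")
        prepared = prep(poly)
        xmin, zmin, xmax, zmax = poly.bounds
        i0, i1 = int(np.floor(xmin / hx)), int(np.ceil(xmax / hx))
        j0, j1 = int(np.floor(zmin / hz)), int(np.ceil(zmax / hz))
        pieces_2d: list = []
        for i in range(i0, i1):
            for j in range(j0, j1):
                cellbox = box(i * hx, j * hz, (i + 1) * hx, (j + 1) * hz)
                if not prepared.intersects(cellbox):
                    continue
                if prepared.contains_properly(cellbox):
                    sq = np.array(
                        [
                            [i * hx, j * hz],
                            [(i + 1) * hx, j * hz],
                            [(i + 1) * hx, (j + 1) * hz],
                            [i * hx, (j + 1) * hz],
                        ]
                    )
                    pieces_2d.append((sq, [(0, 1, 2), (0, 2, 3)]))
                    continue
                inter = poly.intersection(cellbox)
                geoms = (
                    inter.geoms if inter.geom_type == "MultiPolygon" else [inter]
                )
                for g in geoms:
                    if g.geom_type != "Polygon" or g.area < 1e-9:
                        continue
                    ringpts = _clean_ring(np.asarray(g.exterior.coords))
                    if len(ringpts) < 3:
                        continue
                    pieces_2d.append((ringpts, _earclip(ringpts)))
        for layer, tag in ((0, TAG_ABLUMINAL), (1, TAG_LUMINAL)):
            for pts, tris in pieces_2d:
                nid = [reg.get(p[0], p[1], layer) for p in pts]
                for (a, b, c) in tris:
                    t = (nid[a], nid[b], nid[c])
                    if len(set(t)) < 3:
                        continue
                    if layer == 1:
                        t = (t[0], t[2], t[1])  # luminal outward = toward axis
                    tri_list.append(t)
                    tag_list.append(tag)
                    owner_list.append((ci, -1))

    # --- lateral walls
    for b in tref.borders:
        c0 = b.cells[0]
        c1 = b.cells[1]
        tag = TAG_SHARED_LATERAL if c1 is not None else TAG_LATERAL
        # outward side of owner cell c0, sampled at the border midpoint
        loop = next(
            (bid, fwd, dx)
            for (bid, fwd, dx) in tess.cell_loops[c0]
            if bid == b.id
        )
        _, _, dx0 = loop
        mididx = len(b.coords) // 2
        if mididx == len(b.coords) - 1:
            mididx -= 1
        a2, b2 = b.coords[mididx], b.coords[mididx + 1]
        t2 = b2 - a2
        t2 = t2 / max(np.linalg.norm(t2), 1e-12)
        n2 = np.array([-t2[1], t2[0]])
        mid = 0.5 * (a2 + b2)
        probe = mid + 0.05 * n2 + np.array([dx0, 0.0])
        poly0 = Polygon(tess.cell_polygon(c0))
        inside = poly0.contains(Point(probe))
        # outward-of-c0 2D direction at the midpoint
        out2 = -n2 if inside else n2
        theta_mid = 2.0 * np.pi * (mid[0] % P) / P
        tx3 = np.array([-np.sin(theta_mid), np.cos(theta_mid), 0.0])
        out3 = out2[0] * tx3 + out2[1] * np.array([0.0, 0.0, 1.0])

        for a2d, b2d in zip(b.coords[:-1], b.coords[1:]):
            oa = reg.get(a2d[0], a2d[1], 0)
            ob = reg.get(b2d[0], b2d[1], 0)
            ia = reg.get(a2d[0], a2d[1], 1)
            ib = reg.get(b2d[0], b2d[1], 1)
            for t in ((oa, ob, ib), (oa, ib, ia)):
                pa, pb, pc = (reg.coords3d[t[0]], reg.coords3d[t[1]], reg.coords3d[t[2]])
                nvec = np.cross(pb - pa, pc - pa)
                if np.linalg.norm(nvec) < 1e-12:
                    continue
                if np.dot(nvec, out3) < 0:
                    t = (t[0], t[2], t[1])
                tri_list.append(t)
                tag_list.append(tag)
                owner_list.append((c0, c1 if c1 is not None else -1))

    mesh = MembraneMesh(
        nodes=np.array(reg.coords3d),
        node_layer=np.array(reg.layer, dtype=np.int8),
        node_chart=np.array(reg.chart),
        triangles=np.array(tri_list, dtype=np.int64),
        tags=np.array(tag_list, dtype=np.int8),
        owners=np.array(owner_list, dtype=np.int64),
        thickness=0.1,
        depth=depth,
        domain=domain,
        outer_radius=domain.radius,
        inner_radius=domain.radius - depth,
    )
    return mesh


# ---------------------------------------------------------------------------
# structured plain tube (validation geometry)
# ---------------------------------------------------------------------------


def cylinder_shell_mesh(
    radius: float,
    length: float,
    n_theta: int = 48,
    n_z: int = 40,
    tag: int = TAG_LUMINAL,
) -> MembraneMesh:
    """A plain single-surface cylindrical tube (no cell walls).

    Used as a closed-form validation geometry: under an internal (lumen)
    pressure its mid-tube hoop stress approaches ``p * r / t``.  Triangles are
    oriented toward the axis (the "lumen side"), matching the luminal-face
    convention of extruded meshes.
    """
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(0.0, length, n_z + 1)
    nodes = []
    chart = []
    for z in zs:
        for th in thetas:
            nodes.append([radius * np.cos(th), radius * np.sin(th), z])
            chart.append([radius * th, z])
    nodes = np.array(nodes)

    def nid(i, j):
        return j * n_theta + (i % n_theta)

    tris = []
    for j in range(n_z):
        for i in range(n_theta):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            tris.extend([(a, c, b), (a, d, c)])  # inward-facing orientation
    tris = np.array(tris, dtype=np.int64)
    # enforce inward orientation programmatically
    p = nodes
    ctr = (p[tris[:, 0]] + p[tris[:, 1]] + p[tris[:, 2]]) / 3.0
    nvec = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
    radial = ctr.copy()
    radial[:, 2] = 0.0
    flip = np.einsum("ij,ij->i", nvec, radial) > 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    dom = CylinderDomain(diameter=2 * radius, axial_length=length)
    return MembraneMesh(
        nodes=nodes,
        node_layer=np.zeros(len(nodes), dtype=np.int8),
        node_chart=np.array(chart),
        triangles=tris,
        tags=np.full(len(tris), tag, dtype=np.int8),
        owners=np.full((len(tris), 2), -1, dtype=np.int64),
        thickness=0.1,
        depth=0.0,
        domain=dom,
        outer_radius=radius,
        inner_radius=radius,
    )
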