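"""Cell tessellations of the cylindrical vessel wall.

A :class:`CellTessellation` partitions the periodic unrolled chart of a
:class:`~lecmech.geometry.CylinderDomain` into cells.  Cells are stored as
closed polylines assembled from shared *borders* (junction-to-junction
polylines), so that perturbing or straightening a border updates both incident
cells consistently and the partition property (disjoint interiors, full
coverage) is preserved by construction.

The puzzle-cell generator seeds a Voronoi tessellation of the periodic
rectangle and displaces every interior border by a windowed sinusoid along its
normal, producing interdigitating convex/concave lobes; the simple-shaped
derivative reconnects the junction points of the same tessellation with
straight segments, preserving cell count and neighbour connectivity exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Polygon, box

from .curves import (
    laplacian_smooth_open,
    resample_polyline,
    ring_area,
    total_absolute_turning,
)
from .geometry import CylinderDomain

_SNAP = 1e-5  # µm; coordinate snapping tolerance for node identification


class PointIndex:
    """Tolerance-based registry of 2-D points, periodic in x.

    Quantized-bucket lookup with 3x3 neighbour search, so points closer than
    ``tol`` are identified regardless of where they fall relative to bucket
    boundaries (plain rounding can split such pairs).
    """

    def __init__(self, period: float, tol: float = _SNAP):
        self.P = float(period)
        self.tol = float(tol)
        self._map: dict = {}
        self.points: list = []

    def find(self, p) -> int | None:
        x = p[0] % self.P
        z = float(p[1])
        for xx in (x, x - self.P, x + self.P):
            qx = math.floor(xx / self.tol)
            qz = math.floor(z / self.tol)
            for dx in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for i, px, pz in self._map.get((qx + dx, qz + dz), ()):
                        if abs(px - xx) < self.tol and abs(pz - z) < self.tol:
                            return i
        return None

    def add(self, p) -> int:
        i = self.find(p)
        if i is not None:
            return i
        x = p[0] % self.P
        z = float(p[1])
        i = len(self.points)
        self.points.append((x, z))
        key = (math.floor(x / self.tol), math.floor(z / self.tol))
        self._map.setdefault(key, []).append((i, x, z))
        return i


class TessellationError(ValueError):
    """Raised when a tessellation violates its construction preconditions."""


@dataclass
class PuzzleParams:
    """Parameters of the synthetic puzzle-cell generator.

    ``lobe_amplitude`` (µm) and ``lobe_wavelength`` (µm) control the windowed
    sinusoidal displacement applied to every interior cell border; amplitude 0
    yields a simple (straight-edged, Voronoi-like) tessellation.
    """

    n_cells: int = 12
    lobe_amplitude: float = 4.0
    lobe_wavelength: float = 16.0
    smoothing_iterations: int = 2
    boundary_resolution: float = 0.75
    seed_jitter: float = 0.22
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lobe_amplitude < 0:
            raise ValueError("lobe_amplitude must be >= 0")
        if self.lobe_wavelength <= 0:
            raise ValueError("lobe_wavelength must be > 0")
        if self.boundary_resolution <= 0:
            raise ValueError("boundary_resolution must be > 0")


@dataclass
class Border:
    """A junction-to-junction boundary polyline shared by one or two cells."""

    id: int
    cells: tuple
    node_ids: tuple
    coords: np.ndarray
    on_domain_edge: bool = False


@dataclass
class CellTessellation:
    """Cells as closed curves partitioning the periodic cylinder surface."""

    domain: CylinderDomain
    nodes: np.ndarray
    node_cells: list
    borders: list
    cell_loops: list
    _polygons: list = field(default=None, repr=False)

    # ----- assembly -------------------------------------------------------

    def _assemble(self) -> None:
        P = self.domain.circumference
        polys = []
        for loop in self.cell_loops:
            pts = []
            for border_id, forward, dx in loop:
                c = self.borders[border_id].coords
                c = c if forward else c[::-1]
                c = c + np.array([dx, 0.0])
                pts.append(c[:-1])
            ring = np.vstack(pts)
            polys.append(ring)
        self._polygons = polys

    def cell_polygon(self, i: int) -> np.ndarray:
        """Closed outline of cell ``i`` as an open ring on the unrolled chart."""
        if self._polygons is None:
            self._assemble()
        return self._polygons[i]

    @property
    def cells(self) -> list:
        """All cell outlines (open rings, unrolled chart coordinates)."""
        if self._polygons is None:
            self._assemble()
        return self._polygons

    @property
    def n_cells(self) -> int:
        return len(self.cell_loops)

    # ----- derived quantities --------------------------------------------

    @property
    def areas(self) -> np.ndarray:
        return np.array([abs(ring_area(r)) for r in self.cells])

    @property
    def perimeters(self) -> np.ndarray:
        out = []
        for r in self.cells:
            ring = np.vstack([r, r[:1]])
            out.append(np.linalg.norm(np.diff(ring, axis=0), axis=1).sum())
        return np.array(out)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def adjacency(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        for b in self.borders:
            if b.cells[1] is not None:
                g.add_edge(b.cells[0], b.cells[1])
        return g

    def _interior_node_mask(self) -> np.ndarray:
        L = self.domain.axial_length
        z = self.nodes[:, 1]
        return (z > 1e-6) & (z < L - 1e-6)

    @property
    def tricellular_points(self) -> np.ndarray:
        """Interior junction points incident to exactly three cells."""
        mask = self._interior_node_mask()
        deg = np.array([len(c) for c in self.node_cells])
        return self.nodes[mask & (deg == 3)]

    @property
    def interior_junction_degrees(self) -> np.ndarray:
        mask = self._interior_node_mask()
        return np.array([len(c) for c, m in zip(self.node_cells, mask) if m])

    def validate(self, strict_tricellular: bool = True, area_rtol: float = 5e-3):
        """Check partition invariants; raises :class:`TessellationError`."""
        for i, ring in enumerate(self.cells):
            poly = Polygon(ring)
            if not poly.is_valid or poly.area <= 0:
                raise TessellationError(
                    f"cell {i} outline is self-intersecting or degenerate"
                )
        total = self.total_area
        target = self.domain.lateral_area
        if abs(total - target) > area_rtol * target:
            raise TessellationError(
                f"area not conserved: cells sum to {total:.3f} µm², "
                f"domain lateral area {target:.3f} µm²"
            )
        if not nx.is_connected(self.adjacency):
            raise TessellationError("cell adjacency graph is not connected")
        if strict_tricellular:
            deg = self.interior_junction_degrees
            if deg.size and not np.all(deg == 3):
                raise TessellationError(
                    f"interior junctions with degree != 3: "
                    f"{np.unique(deg[deg != 3]).tolist()}"
                )
        return self

    def with_border_coords(self, new_coords: list) -> "CellTessellation":
        """Rebuild the tessellation with replaced border polylines.

        Endpoints of every border must be unchanged.
        """
        borders = []
        for b, c in zip(self.borders, new_coords):
            c = np.asarray(c, dtype=float)
            if (
                np.linalg.norm(c[0] - b.coords[0]) > 1e-6
                or np.linalg.norm(c[-1] - b.coords[-1]) > 1e-6
            ):
                raise TessellationError(
                    f"border {b.id}: endpoint moved during coordinate replacement"
                )
            borders.append(
                Border(b.id, b.cells, b.node_ids, c, b.on_domain_edge)
            )
        return CellTessellation(
            domain=self.domain,
            nodes=self.nodes,
            node_cells=self.node_cells,
            borders=borders,
            cell_loops=self.cell_loops,
        )


# ---------------------------------------------------------------------------
# construction from vertex-matched cell rings
# ---------------------------------------------------------------------------


def _build_tessellation(domain: CylinderDomain, rings: list) -> CellTessellation:
    """Build a border-shared tessellation from vertex-matched cell rings.

    ``rings`` are open closed-cell outlines on the unrolled chart.  Adjacent
    cells must trace their common boundary through identical vertices (up to a
    shift by the period and snapping tolerance).
    """
    P = domain.circumference
    L = domain.axial_length

    # --- register every ring vertex; junction nodes are vertices incident to
    # >=3 cells or lying on the z edges of the domain
    index = PointIndex(P)
    vids = [np.array([index.add(p) for p in ring]) for ring in rings]
    incident: dict = {}
    for ci, vv in enumerate(vids):
        for v in vv:
            incident.setdefault(int(v), set()).add(ci)

    def _is_node(v: int) -> bool:
        z = index.points[v][1]
        on_zedge = abs(z) < 1e-5 or abs(z - L) < 1e-5
        return len(incident[v]) >= 3 or on_zedge

    node_of_vid: dict = {}
    nodes_list: list = []
    node_cells: list = []
    for v in sorted(incident):
        if _is_node(v):
            node_of_vid[v] = len(nodes_list)
            x, z = index.points[v]
            if abs(z) < 1e-5:
                z = 0.0
            elif abs(z - L) < 1e-5:
                z = L
            nodes_list.append((x, z))
            node_cells.append(set(incident[v]))
    nodes = np.array(nodes_list, dtype=float)

    # --- split each ring at its junction nodes into border pieces
    borders: list = []
    border_lookup: dict = {}
    cell_loops: list = []

    for ci, ring in enumerate(rings):
        n = len(ring)
        vv = vids[ci]
        node_pos = [i for i in range(n) if int(vv[i]) in node_of_vid]
        if len(node_pos) < 2:
            raise TessellationError(
                f"cell {ci} has fewer than two junction vertices"
            )
        loop = []
        m = len(node_pos)
        for j in range(m):
            i0, i1 = node_pos[j], node_pos[(j + 1) % m]
            if i1 > i0:
                piece = ring[i0 : i1 + 1]
                piece_vids = vv[i0 : i1 + 1]
            else:
                piece = np.vstack([ring[i0:], ring[: i1 + 1]])
                piece_vids = np.concatenate([vv[i0:], vv[: i1 + 1]])
            na = node_of_vid[int(vv[i0])]
            nb = node_of_vid[int(vv[i1])]
            # orientation-independent identity: endpoints + interior vertices
            bkey = (
                tuple(sorted((na, nb))),
                frozenset(int(v) for v in piece_vids[1:-1]),
            )
            if bkey in border_lookup:
                bid = border_lookup[bkey]
                b = borders[bid]
                if b.cells[1] is not None or b.cells[0] == ci:
                    raise TessellationError(
                        f"border between nodes {na},{nb} shared by >2 cells"
                    )
                borders[bid] = Border(
                    bid, (b.cells[0], ci), b.node_ids, b.coords, b.on_domain_edge
                )
                # orientation/offset relative to stored coords
                if na == nb:
                    raise TessellationError(
                        f"border {bid} connects node {na} to itself; "
                        "tessellation too coarse for the periodic domain"
                    )
                forward = na == b.node_ids[0]
                ref = b.coords[0] if forward else b.coords[-1]
                dx = piece[0][0] - ref[0]
            else:
                bid = len(borders)
                border_lookup[bkey] = bid
                zs = piece[:, 1]
                on_edge = bool(
                    np.all(np.abs(zs) < 1e-5) or np.all(np.abs(zs - L) < 1e-5)
                )
                coords = piece.copy()
                if on_edge:
                    coords[:, 1] = 0.0 if abs(zs[0]) < 1e-5 else L
                borders.append(Border(bid, (ci, None), (na, nb), coords, on_edge))
                forward = True
                dx = 0.0
            dx = round(dx / P) * P
            loop.append((bid, forward, dx))
        cell_loops.append(loop)

    tess = CellTessellation(
        domain=domain,
        nodes=nodes,
        node_cells=node_cells,
        borders=borders,
        cell_loops=cell_loops,
    )
    return tess


# ---------------------------------------------------------------------------
# puzzle generator
# ---------------------------------------------------------------------------


def _grid_shape(n_cells: int, P: float, L: float) -> tuple:
    """Columns x rows factorization of n_cells closest to the domain aspect.

    At least three columns are required so that no cell is its own neighbour
    across the periodic seam.
    """
    best = None
    for cols in range(3, n_cells + 1):
        if n_cells % cols:
            continue
        rows = n_cells // cols
        # want P/cols ~ L/rows
        mismatch = abs(math.log((P / cols) / (L / rows)))
        if best is None or mismatch < best[0]:
            best = (mismatch, cols, rows)
    if best is None:
        raise TessellationError(
            f"infeasible packing: need at least 3 cells around the "
            f"circumference, got n_cells={n_cells}"
        )
    return best[1], best[2]


def _voronoi_rings(domain: CylinderDomain, params: PuzzleParams, rng) -> list:
    from scipy.spatial import Voronoi

    P, L = domain.circumference, domain.axial_length
    cols, rows = _grid_shape(params.n_cells, P, L)
    sx, sz = P / cols, L / rows
    if min(sx, sz) < max(4.0 * params.boundary_resolution, 2.0):
        raise TessellationError(
            f"infeasible packing: {params.n_cells} cells give "
            f"{sx:.2f} x {sz:.2f} µm spacing on a "
            f"{P:.1f} x {L:.1f} µm domain"
        )
    gx, gz = np.meshgrid(
        (np.arange(cols) + 0.5) * sx, (np.arange(rows) + 0.5) * sz
    )
    seeds = np.column_stack([gx.ravel(), gz.ravel()])
    jit = params.seed_jitter
    seeds[:, 0] += rng.uniform(-jit * sx, jit * sx, len(seeds))
    seeds[:, 1] += rng.uniform(-jit * sz, jit * sz, len(seeds))

    # periodic copies in x, mirror copies in z close every base region
    pts = []
    for dx in (-P, 0.0, P):
        for mode in ("o", "m0", "mL"):
            s = seeds.copy()
            s[:, 0] += dx
            if mode == "m0":
                s[:, 1] = -s[:, 1]
            elif mode == "mL":
                s[:, 1] = 2 * L - s[:, 1]
            pts.append(s)
    # base copy (dx=0, unmirrored; list index 3) first so base seeds keep
    # indices 0..n-1
    order = [3, 0, 1, 2, 4, 5, 6, 7, 8]
    allpts = np.vstack([pts[i] for i in order])
    vor = Voronoi(allpts)

    rings = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise TessellationError("unbounded Voronoi region (internal error)")
        verts = vor.vertices[region]
        ang = np.arctan2(verts[:, 1] - seeds[i, 1], verts[:, 0] - seeds[i, 0])
        verts = verts[np.argsort(ang)]  # CCW; regions are convex
        rings.append(verts)
    return rings


def _perturb_border(coords, amplitude, wavelength, phase, resolution):
    pts = resample_polyline(coords, resolution)
    if len(pts) < 3 or amplitude == 0.0:
        return pts
    seg = np.diff(pts, axis=0)
    slen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(slen)])
    S = s[-1]
    if S <= 0:
        return pts
    # normal by rotating the chord direction: borders are near-straight here
    tang = (pts[-1] - pts[0]) / np.linalg.norm(pts[-1] - pts[0])
    normal = np.array([-tang[1], tang[0]])
    disp = (
        amplitude
        * np.sin(2.0 * np.pi * s / wavelength + phase)
        * np.sin(np.pi * s / S)
    )
    return pts + disp[:, None] * normal


def generate_puzzle_tessellation(
    domain: CylinderDomain, params: PuzzleParams
) -> CellTessellation:
    """Generate a lobate (puzzle-cell) tessellation of the vessel wall.

    A seeded Voronoi tessellation of the periodic rectangle is built from a
    jittered grid of seeds (columns x rows chosen to match the domain aspect,
    three columns for the default 12-cell, 45 x 200 µm domain), and every
    interior border is displaced by a sinusoid of the requested amplitude and
    wavelength, windowed to vanish at the junction points.  Deterministic for
    a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    rings = _voronoi_rings(domain, params, rng)
    tess = _build_tessellation(domain, rings)

    new_coords = []
    for b in tess.borders:
        if b.on_domain_edge:
            new_coords.append(resample_polyline(b.coords, params.boundary_resolution))
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi)
        c = _perturb_border(
            b.coords,
            params.lobe_amplitude,
            params.lobe_wavelength,
            phase,
            params.boundary_resolution,
        )
        c = laplacian_smooth_open(c, params.smoothing_iterations)
        new_coords.append(c)
    out = tess.with_border_coords(new_coords)
    try:
        out.validate(strict_tricellular=True)
    except TessellationError as err:
        raise TessellationError(
            f"lobe perturbation produced an invalid tessellation "
            f"(amplitude {params.lobe_amplitude} µm too large?): {err}"
        ) from err
    return out


def derive_simple_tessellation(puzzle: CellTessellation) -> CellTessellation:
    """Straighten every border into the junction-to-junction chord.

    The simple-shaped template keeps the cell count, junction points and the
    adjacency graph of the puzzle template and replaces each boundary polyline
    by the straight segment between its endpoints (a geodesic chord on the
    unrolled developable surface).
    """
    if len(puzzle.tricellular_points) == 0:
        raise TessellationError(
            "tessellation has no tricellular junction annotation; "
            "cannot derive a simple template"
        )
    new_coords = [np.array([b.coords[0], b.coords[-1]]) for b in puzzle.borders]
    out = puzzle.with_border_coords(new_coords)
    out.validate(strict_tricellular=True)
    return out


# ---------------------------------------------------------------------------
# projection of externally supplied outlines
# ---------------------------------------------------------------------------


def project_outlines_to_cylinder(
    outlines: list,
    domain: CylinderDomain,
    smoothing_iterations: int = 0,
    tol_area: float = 1.0,
) -> CellTessellation:
    """Project planar closed outlines tiling the unrolled rectangle.

    ``outlines`` must tile the rectangle ``[0, circumference] x [0,
    axial_length]`` with vertex-matched common boundaries; the two vertical
    rectangle edges are identified (periodic seam).  Optional smoothing runs
    endpoint-pinned local averaging on every interior border, which never
    increases the total absolute boundary curvature.

    Raises :class:`TessellationError` listing offending cells when the tiling
    leaves gaps or overlaps larger than ``tol_area`` (µm²).
    """
    P, L = domain.circumference, domain.axial_length
    rings = [np.asarray(o, dtype=float) for o in outlines]
    rings = [r[:-1] if np.allclose(r[0], r[-1]) else r for r in rings]

    from shapely.affinity import translate
    from shapely.ops import unary_union

    polys = [Polygon(r) for r in rings]
    for i, p in enumerate(polys):
        if not p.is_valid:
            raise TessellationError(f"outline {i} is not a simple closed curve")
    # periodic copies so seam-crossing outlines are handled consistently
    polys_ext = [
        unary_union([p, translate(p, P, 0), translate(p, -P, 0)]) for p in polys
    ]
    bad_pairs = []
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].intersection(polys_ext[j]).area
            if inter > tol_area:
                bad_pairs.append((i, j, inter))
    if bad_pairs:
        raise TessellationError(f"overlapping outlines: {bad_pairs}")

    union = unary_union(polys_ext)
    gap = box(0, 0, P, L).difference(union)
    if gap.area > tol_area:
        offenders = [
            i for i, p in enumerate(polys) if p.distance(gap) < 1e-6
        ]
        raise TessellationError(
            f"tiling leaves {gap.area:.3f} µm² of gaps; offending cells "
            f"adjacent to gaps: {offenders}"
        )

    tess = _build_tessellation(domain, rings)
    tess.validate(strict_tricellular=False)
    if smoothing_iterations > 0:
        new_coords = [
            b.coords
            if b.on_domain_edge
            else laplacian_smooth_open(b.coords, smoothing_iterations)
            for b in tess.borders
        ]
        tess = tess.with_border_coords(new_coords)
        tess.validate(strict_tricellular=False)
    return tess


# ---------------------------------------------------------------------------
# morphometric helpers
# ---------------------------------------------------------------------------


def cells_per_circumference(
    tess: CellTessellation, n_stations: int = 100
) -> float:
    """Mean number of distinct cells cut by circumferential cross-sections."""
    L = tess.domain.axial_length
    xs = [r[:, 0] for r in tess.cells]
    xmin = min(x.min() for x in xs) - 1.0
    xmax = max(x.max() for x in xs) + 1.0
    zs = np.linspace(0.0, L, n_stations + 2)[1:-1]
    polys = [Polygon(r) for r in tess.cells]
    counts = []
    for z in zs:
        line = LineString([(xmin, z), (xmax, z)])
        counts.append(sum(1 for p in polys if p.intersects(line)))
    return float(np.mean(counts))


def boundary_total_curvature(tess: CellTessellation) -> float:
    """Sum of total absolute turning over all cell outlines (rad)."""
    return float(
        sum(total_absolute_turning(r, closed=True) for r in tess.cells)
    )
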