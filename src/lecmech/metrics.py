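"""Quantification operators for LEC shape and junction measurements.

These implement the study's morphometric readouts on labeled inputs:

* overlap geometry of a pair of binary cell masks (perpendicular width via
  transects normal to the medial axis, and area);
* the junction linearity index (contour length over chord length);
* rule-based five-way junction classification from adhesion-marker
  (VE-cadherin-like) coverage profiles and lobe-marker (LYVE1-like) status;
* lobe counting and concave/convex microtubule-anchoring statistics on cell
  outline curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import (
    arc_length,
    cumulative_arclength,
    resample_polyline,
    resample_ring,
    ring_area,
    signed_curvature_ring,
    smooth_ring,
)

JUNCTION_LABELS = (
    "button",
    "curvilinear",
    "double",
    "lyve1neg_curvilinear",
    "zipper",
)
UNCLASSIFIABLE = "unclassifiable"


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class CellMaskPair:
    """Two binary raster masks of neighbouring cells on a common grid."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    pixel_size: float  # µm per pixel
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask_a = np.asarray(self.mask_a, dtype=bool)
        self.mask_b = np.asarray(self.mask_b, dtype=bool)
        if self.mask_a.shape != self.mask_b.shape:
            raise ValueError("masks must share raster dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class OverlapMeasurement:
    mean_width: float  # µm; nan when undefined
    area: float  # µm²
    width_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    width_cap: float | None = None
    n_capped: int = 0
    disjoint: bool = False
    width_defined: bool = True
    diagnostic: str = ""


@dataclass
class JunctionProfile:
    """Marker profile of one lobe/overlap (or whole-cell junction context).

    ``border_coverage`` holds the adhesion-marker covered fraction of each of
    the two overlap borders; ``neck_segment_length`` the length (µm) of the
    deposit at the lobe neck (0 = none); ``whole_cell_coverage`` the covered
    fraction of the whole cell perimeter; ``lobe_marker`` whether the
    lobe/overlap marker (LYVE1-like) is present.
    """

    border_coverage: tuple
    neck_segment_length: float
    lobe_marker: bool
    whole_cell_coverage: float = 0.0

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.border_coverage)
        if len(c) != 2 or not all(0.0 <= v <= 1.0 for v in c):
            raise ValueError("border_coverage must be two fractions in [0, 1]")
        self.border_coverage = c
        if not (0.0 <= self.whole_cell_coverage <= 1.0):
            raise ValueError("whole_cell_coverage must be in [0, 1]")


@dataclass
class ClassifierThresholds:
    """Explicit stand-ins for by-eye annotation criteria; all configurable."""

    punctate_max: float = 1.5  # µm; neck deposits shorter than this are punctate
    border_min: float = 0.3  # coverage fraction counting a border as covered
    continuity_min: float = 0.9  # whole-cell coverage fraction for a zipper


@dataclass
class JunctionCall:
    label: str
    rule_trace: str = ""


@dataclass
class OutlineCurve:
    """A simple closed cell outline, stored CCW so that positive curvature
    means convex (bulging away from the cell interior)."""

    points: np.ndarray
    smoothing_sigma: float = 1.0  # µm of arc length, for curvature estimates

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 4:
            raise ValueError("outline needs at least 4 distinct points")
        from shapely.geometry import LinearRing

        if not LinearRing(pts).is_simple:
            raise ValueError("outline is self-intersecting")
        if ring_area(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def perimeter(self) -> float:
        return arc_length(self.points, closed=True)

    def smoothed(self) -> np.ndarray:
        if self.smoothing_sigma > 0:
            return smooth_ring(self.points, self.smoothing_sigma)
        per = self.perimeter
        return resample_ring(self.points, max(64, int(per / 0.25)))

    def curvature_samples(self):
        """(points, signed curvature, ds) on the smoothed resampled outline."""
        ring = self.smoothed()
        kappa = signed_curvature_ring(ring)
        per = arc_length(ring, closed=True)
        ds = per / len(ring)
        return ring, kappa, ds


# ---------------------------------------------------------------------------
# overlap morphometry
# ---------------------------------------------------------------------------


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray | None:
    """Longest geodesic path through a skeleton, as (k, 2) pixel coordinates."""
    import networkx as nx

    pix = np.argwhere(skel)
    if len(pix) < 3:
        return None
    index = {tuple(p): i for i, p in enumerate(pix)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pix)))
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    start = next(iter(comp))
    d0 = nx.single_source_dijkstra_path_length(sub, start)
    u = max(d0, key=d0.get)
    d1, paths = nx.single_source_dijkstra(sub, u)
    v = max(d1, key=d1.get)
    return pix[paths[v]]


def _transect_width(
    mask: np.ndarray, pos: np.ndarray, normal: np.ndarray, step: float = 0.25
) -> float:
    """Extent of the mask along +-normal from pos, in pixels."""
    h, w = mask.shape

    def march(direction):
        dist = 0.0
        p = pos.astype(float).copy()
        while True:
            p = p + step * direction
            r, c = int(round(p[0])), int(round(p[1]))
            if r < 0 or c < 0 or r >= h or c >= w or not mask[r, c]:
                # midpoint estimate of the sub-pixel boundary crossing
                return dist + 0.5 * step

            dist += step

    return march(normal) + march(-normal)


def measure_overlap(
    pair: CellMaskPair,
    width_cap: float | None = None,
    sample_step: float = 0.5,
    min_component_px: int = 9,
) -> OverlapMeasurement:
    """Perpendicular width and area of the overlap of a cell mask pair.

    The overlap region's medial axis is extracted per connected component;
    the longest skeleton path is resampled every ``sample_step`` µm and at each
    sample the local mask extent perpendicular to the path tangent is taken as
    a width sample (samples within one local half-width of the path ends are
    trimmed).  With ``width_cap`` set, samples exceeding the cap are excluded
    (the TEM-comparison mode uses 4 µm).
    """
    from scipy.ndimage import distance_transform_edt, label
    from skimage.morphology import skeletonize

    px = pair.pixel_size
    inter = pair.mask_a & pair.mask_b
    area = float(inter.sum()) * px * px
    if not inter.any():
        return OverlapMeasurement(
            mean_width=np.nan,
            area=0.0,
            disjoint=True,
            width_defined=False,
            width_cap=width_cap,
            diagnostic="masks are disjoint",
        )

    lab, ncomp = label(inter)
    samples = []
    for ci in range(1, ncomp + 1):
        comp = lab == ci
        if comp.sum() < min_component_px:
            continue
        skel = skeletonize(comp)
        path = _skeleton_longest_path(skel)
        if path is None or len(path) < 3:
            continue
        edt = distance_transform_edt(comp)
        pts = path.astype(float)
        # smooth the path so tangents are not dominated by pixel jitter
        for _ in range(8):
            if len(pts) < 3:
                break
            pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
        res = resample_polyline(pts, sample_step / px)
        if len(res) < 3:
            continue
        tang = np.gradient(res, axis=0)
        nrm = np.linalg.norm(tang, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        tang = tang / nrm
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        s = cumulative_arclength(res)
        trim0 = edt[tuple(path[0])] * 1.2
        trim1 = edt[tuple(path[-1])] * 1.2
        for k in range(len(res)):
            if s[k] < trim0 or s[-1] - s[k] < trim1:
                continue
            wpx = _transect_width(comp, res[k], normal[k])
            samples.append(wpx * px)

    samples = np.asarray(samples)
    if samples.size == 0:
        return OverlapMeasurement(
            mean_width=np.nan,
            area=area,
            width_defined=False,
            width_cap=width_cap,
            diagnostic="no resolvable medial axis in the overlap region",
        )
    n_capped = 0
    if width_cap is not None:
        n_capped = int(np.sum(samples > width_cap))
        samples = samples[samples <= width_cap]
    if samples.size == 0:
        return OverlapMeasurement(
            mean_width=np.nan,
            area=area,
            width_defined=False,
            width_cap=width_cap,
            n_capped=n_capped,
            diagnostic="all width samples exceeded the cap",
        )
    return OverlapMeasurement(
        mean_width=float(samples.mean()),
        area=area,
        width_samples=samples,
        width_cap=width_cap,
        n_capped=n_capped,
    )


# ---------------------------------------------------------------------------
# junction linearity index
# ---------------------------------------------------------------------------


def junction_linearity_index(border: np.ndarray) -> float:
    """Ratio of junction contour length to straight-line endpoint distance.

    Always >= 1; exactly 1 for a straight junction.
    """
    pts = np.asarray(border, dtype=float)
    if len(pts) < 2:
        raise ValueError("border needs at least two points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-12:
        raise ValueError("coincident endpoints: closed loop has no chord")
    return arc_length(pts) / chord


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------


def classify_junction(
    profile: JunctionProfile,
    thresholds: ClassifierThresholds | None = None,
) -> JunctionCall:
    """Rule-based call into the five junction categories.

    Decision order: zipper (whole-cell continuity without the lobe marker),
    LYVE1⁻ curvilinear (no lobe marker, a covered border), button (lobe marker
    with a punctate neck deposit and uncovered borders), curvilinear (one
    covered border), double (both borders covered).  Profiles matching no rule
    are explicitly unclassifiable.
    """
    t = thresholds or ClassifierThresholds()
    c1, c2 = profile.border_coverage
    covered1, covered2 = c1 >= t.border_min, c2 >= t.border_min

    if not profile.lobe_marker and profile.whole_cell_coverage >= t.continuity_min:
        return JunctionCall("zipper", "no lobe marker; whole-cell continuity")
    if not profile.lobe_marker and (covered1 or covered2):
        return JunctionCall(
            "lyve1neg_curvilinear", "no lobe marker; covered cell-cell border"
        )
    if profile.lobe_marker:
        punctate = 0.0 < profile.neck_segment_length < t.punctate_max
        if punctate and not covered1 and not covered2:
            return JunctionCall(
                "button",
                f"lobe marker; punctate neck ({profile.neck_segment_length:.2f} "
                f"µm < {t.punctate_max}); borders uncovered",
            )
        if covered1 != covered2:
            return JunctionCall("curvilinear", "lobe marker; one border covered")
        if covered1 and covered2:
            return JunctionCall("double", "lobe marker; both borders covered")
    return JunctionCall(UNCLASSIFIABLE, "no rule matched")


def tabulate_junction_frequencies(calls, grouping=None):
    """Frequency table of junction calls as percentages.

    Unclassifiable calls are excluded from the percentages and reported in a
    separate column.  With ``grouping`` (one group id per call, e.g. animal),
    per-group rows are emitted plus a ``pooled`` row and a ``group_mean`` row
    (the weighted per-group average, weights = classified calls per group).
    """
    import pandas as pd

    labels = [c.label if isinstance(c, JunctionCall) else str(c) for c in calls]
    if len(labels) == 0:
        raise ValueError("no junction calls to tabulate")
    df = pd.DataFrame({"label": labels})
    df["group"] = list(grouping) if grouping is not None else "all"

    def _row(sub):
        cls = sub[sub.label != UNCLASSIFIABLE]
        n = len(cls)
        out = {
            lab: (100.0 * (cls.label == lab).sum() / n if n else np.nan)
            for lab in JUNCTION_LABELS
        }
        out["n_classified"] = n
        out["n_unclassifiable"] = int((sub.label == UNCLASSIFIABLE).sum())
        return pd.Series(out)

    table = df.groupby("group").apply(_row, include_groups=False)
    pooled = _row(df)
    pooled.name = "pooled"
    w = table["n_classified"].to_numpy(dtype=float)
    gm = pd.Series(
        {
            lab: (
                np.average(table[lab].to_numpy(dtype=float), weights=w)
                if w.sum()
                else np.nan
            )
            for lab in JUNCTION_LABELS
        },
        name="group_mean",
    )
    gm["n_classified"] = w.sum()
    gm["n_unclassifiable"] = table["n_unclassifiable"].sum()
    return pd.concat([table, pooled.to_frame().T, gm.to_frame().T])


# ---------------------------------------------------------------------------
# lobe counting
# ---------------------------------------------------------------------------


def _circular_runs(mask: np.ndarray):
    """Maximal runs of True in a circular boolean array, as (start, length)."""
    n = len(mask)
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then find linear runs
    shift = int(np.argmin(mask))
    rolled = np.roll(mask, -shift)
    runs = []
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((start + shift) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + shift) % n, n - start))
    return runs


def count_lobes(
    outline: OutlineCurve | np.ndarray,
    amplitude_min: float = 1.0,
    arc_min: float = 2.0,
) -> int:
    """Number of lobes: maximal convex arcs separated by concave arcs.

    A convex (positive-curvature) arc counts as a lobe when its arc length is
    at least ``arc_min`` µm and its apex rises at least ``amplitude_min`` µm
    above the chord connecting the arc endpoints.  Everywhere-convex outlines
    (circle, ellipse) have zero lobes.
    """
    oc = outline if isinstance(outline, OutlineCurve) else OutlineCurve(outline)
    ring, kappa, ds = oc.curvature_samples()
    convex = kappa > 0
    if convex.all() or not convex.any():
        return 0
    count = 0
    n = len(ring)
    for start, length in _circular_runs(convex):
        if length * ds < arc_min:
            continue
        idx = (start + np.arange(length)) % n
        arcpts = ring[idx]
        a, b = arcpts[0], arcpts[-1]
        chord = b - a
        cl = np.linalg.norm(chord)
        if cl < 1e-9:
            amp = np.linalg.norm(arcpts - a, axis=1).max()
        else:
            t = chord / cl
            nvec = np.array([-t[1], t[0]])
            amp = np.abs((arcpts - a) @ nvec).max()
        if amp >= amplitude_min:
            count += 1
    return count


# ---------------------------------------------------------------------------
# microtubule anchoring
# ---------------------------------------------------------------------------


@dataclass
class MtAnchoring:
    fraction_concave: float
    fraction_convex: float
    density_concave: float  # endpoints per µm of concave cortex
    density_convex: float
    n_assigned: int
    n_rejected: int
    arc_concave: float  # µm
    arc_convex: float


def mt_anchoring(
    outline: OutlineCurve | np.ndarray,
    endpoints: np.ndarray,
    capture_distance: float = 2.0,
) -> MtAnchoring:
    """Assign microtubule endpoints to concave vs convex cortex arcs.

    Each endpoint is attributed to the curvature class of the nearest point of
    the (smoothed) outline; endpoints farther than ``capture_distance`` µm
    from the cortex are rejected and tallied.  Densities are endpoints per µm
    of arc length of each class.
    """
    from scipy.spatial import cKDTree

    oc = outline if isinstance(outline, OutlineCurve) else OutlineCurve(outline)
    ring, kappa, ds = oc.curvature_samples()
    concave = kappa < 0
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("endpoints must be (n, 2)")
    tree = cKDTree(ring)
    dist, idx = tree.query(pts)
    ok = dist <= capture_distance
    n_rej = int((~ok).sum())
    assigned = idx[ok]
    if assigned.size == 0:
        raise ValueError("no endpoints within capture distance of the cortex")
    is_conc = concave[assigned]
    n_conc = int(is_conc.sum())
    n_conv = int((~is_conc).sum())
    arc_conc = float(concave.sum() * ds)
    arc_conv = float((~concave).sum() * ds)
    n = n_conc + n_conv
    return MtAnchoring(
        fraction_concave=n_conc / n,
        fraction_convex=n_conv / n,
        density_concave=n_conc / arc_conc if arc_conc > 0 else np.nan,
        density_convex=n_conv / arc_conv if arc_conv > 0 else np.nan,
        n_assigned=n,
        n_rejected=n_rej,
        arc_concave=arc_conc,
        arc_convex=arc_conv,
    )
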