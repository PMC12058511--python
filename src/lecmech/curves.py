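"""Polyline and closed-curve helpers shared by templates and metrics.

Conventions: curves are ``(N, 2)`` float arrays in µm.  Closed curves ("rings")
are stored *open* — the segment from the last vertex back to the first is
implied.  Signed curvature is positive where the curve turns left while
traversing it counterclockwise, i.e. positive = convex for a CCW-oriented cell
outline.
"""

from __future__ import annotations

import numpy as np


def arc_length(points: np.ndarray, closed: bool = False) -> float:
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample an open polyline at roughly uniform arc-length spacing.

    Endpoints are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    s = cumulative_arclength(pts)
    total = s[-1]
    if total == 0.0:
        return pts.copy()
    n = max(1, int(np.ceil(total / step)))
    snew = np.linspace(0.0, total, n + 1)
    x = np.interp(snew, s, pts[:, 0])
    y = np.interp(snew, s, pts[:, 1])
    return np.column_stack([x, y])


def resample_ring(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed ring to exactly ``n`` uniformly spaced vertices."""
    pts = np.asarray(points, dtype=float)
    ring = np.vstack([pts, pts[:1]])
    s = cumulative_arclength(ring)
    snew = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(snew, s, ring[:, 0])
    y = np.interp(snew, s, ring[:, 1])
    return np.column_stack([x, y])


def ring_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed ring (positive if CCW)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def turning_angles(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Exterior turning angle at each vertex of a polyline.

    For closed curves one angle per vertex; for open curves the two endpoints
    carry no turning.
    """
    pts = np.asarray(points, dtype=float)
    if closed:
        d = np.diff(np.vstack([pts[-1:], pts, pts[:1]]), axis=0)
    else:
        d = np.diff(pts, axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    turn = np.diff(ang)
    return (turn + np.pi) % (2.0 * np.pi) - np.pi


def total_absolute_turning(points: np.ndarray, closed: bool = True) -> float:
    """Total absolute curvature (integral of |kappa| ds) of a polyline."""
    return float(np.abs(turning_angles(points, closed=closed)).sum())


def total_turning(points: np.ndarray, closed: bool = True) -> float:
    return float(turning_angles(points, closed=closed).sum())


def signed_curvature_ring(points: np.ndarray) -> np.ndarray:
    """Discrete signed curvature at each vertex of a closed ring.

    Turning angle divided by the mean of the two adjacent segment lengths;
    sign follows the traversal orientation (positive = left turn).
    """
    pts = np.asarray(points, dtype=float)
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    l_in = np.linalg.norm(pts - prv, axis=1)
    l_out = np.linalg.norm(nxt - pts, axis=1)
    ds = 0.5 * (l_in + l_out)
    ds[ds == 0.0] = np.inf
    return turning_angles(pts, closed=True) / ds


def smooth_ring(points: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing of a closed ring in arc length (periodic).

    The ring is resampled uniformly before filtering; ``sigma`` is in µm.
    """
    from scipy.ndimage import gaussian_filter1d

    pts = np.asarray(points, dtype=float)
    per = arc_length(pts, closed=True)
    n = max(64, int(np.ceil(per / (0.25 * max(sigma, 1e-6)))))
    n = min(n, 8192)
    res = resample_ring(pts, n)
    ds = per / n
    sig_px = sigma / ds
    out = np.column_stack(
        [
            gaussian_filter1d(res[:, 0], sig_px, mode="wrap"),
            gaussian_filter1d(res[:, 1], sig_px, mode="wrap"),
        ]
    )
    return out


def laplacian_smooth_open(points: np.ndarray, iterations: int) -> np.ndarray:
    """Endpoint-pinned local averaging of an open polyline."""
    pts = np.asarray(points, dtype=float).copy()
    for _ in range(iterations):
        if len(pts) < 3:
            break
        pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
    return pts


def is_simple_ring(points: np.ndarray) -> bool:
    from shapely.geometry import LinearRing

    try:
        return LinearRing(points).is_simple
    except Exception:
        return False
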