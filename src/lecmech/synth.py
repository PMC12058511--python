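"""Seeded synthetic-data generators emulating the measured distributions.

Every generator is a bit-reproducible function of its configuration and seed,
and each records the ground truth it sampled so that the estimators in
:mod:`lecmech.metrics` can be validated in closed generator–estimator loops.

Overlap mask pairs: two cell masks meeting along a gently sinusoidal interface
share an overlap band of controlled perpendicular width and area; width and
area are drawn from truncated normal distributions (the measured summaries are
mean ± s.d., so a zero-truncated normal is the minimal assumption — the
truncation introduces a small positive bias at large coefficients of
variation).  Presets carry the control, fluid-injected and TEM-comparison
distribution parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    JUNCTION_LABELS,
    CellMaskPair,
    JunctionProfile,
    OutlineCurve,
)

# ---------------------------------------------------------------------------
# overlap mask pairs
# ---------------------------------------------------------------------------

#: measured (mean, s.d.) of perpendicular overlap width (µm) and area (µm²)
OVERLAP_PRESETS = {
    "control": {"width": (2.3, 0.8), "area": (123.0, 52.6), "n": 26},
    "fluid_injected": {"width": (1.7, 0.7), "area": (83.4, 52.0), "n": 35},
    "tem": {"width": (1.8, 0.9), "area": None, "n": 34},
}


@dataclass
class OverlapGenConfig:
    n: int = 26
    width_mean: float = 2.3
    width_sd: float = 0.8
    area_mean: float | None = 123.0
    area_sd: float | None = 52.6
    pixel_size: float = 0.1  # µm per pixel, ~confocal sampling
    rng_seed: int = 0
    condition: str = "control"
    interface_amplitude: float = 1.0  # µm, sinusoidal interface waviness
    interface_wavelength: float = 12.0  # µm
    strip_length_mean: float = 50.0  # µm; used when area stats are absent
    strip_length_sd: float = 15.0
    min_strip_length: float = 5.0
    max_strip_length: float = 250.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.width_mean <= 0 or self.width_sd < 0:
            raise ValueError("width mean must be > 0 and s.d. >= 0")
        if self.area_mean is not None and self.area_mean <= 0:
            raise ValueError("area mean must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @classmethod
    def preset(cls, name: str, n: int | None = None, rng_seed: int = 0):
        if name not in OVERLAP_PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; options: {sorted(OVERLAP_PRESETS)}"
            )
        p = OVERLAP_PRESETS[name]
        wm, ws = p["width"]
        if p["area"] is not None:
            am, asd = p["area"]
        else:
            am = asd = None
        return cls(
            n=n if n is not None else p["n"],
            width_mean=wm,
            width_sd=ws,
            area_mean=am,
            area_sd=asd,
            rng_seed=rng_seed,
            condition=name,
        )


def _trunc_normal(rng, mean, sd, low=0.0):
    """Draw one truncated-normal sample by rejection (sd may be 0)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return v
    raise RuntimeError("truncated-normal rejection failed")


def _rasterize_pair(width, length, cfg, rng):
    """Two masks sharing an overlap band of perpendicular width ``width`` and
    arc length ``length`` along a sinusoidal interface."""
    from scipy.spatial import cKDTree

    px = cfg.pixel_size
    amp, lam = cfg.interface_amplitude, cfg.interface_wavelength
    margin = 2.0
    body = 4.0  # µm of cell body on each side of the interface

    # choose the window x-extent so the interface arc length equals `length`
    Lx = length / np.sqrt(1 + (2 * np.pi * amp / lam) ** 2 / 2)
    phase = rng.uniform(0, 2 * np.pi)

    W = Lx + 2 * margin
    H = width + 2 * body + 2 * margin + 2 * amp
    ncol = int(np.ceil(W / px))
    nrow = int(np.ceil(H / px))
    xs = (np.arange(ncol) + 0.5) * px
    ys = (np.arange(nrow) + 0.5) * px
    yc = H / 2.0

    x0, x1 = margin, margin + Lx
    xw = np.linspace(x0, x1, max(64, int(np.ceil(Lx / 0.05))))
    curve_y = yc + amp * np.sin(2 * np.pi * xw / lam + phase)
    curve = np.column_stack([xw, curve_y])
    # realized arc length (refine Lx once so |band| tracks the target length)
    arc = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
    if arc > 0:
        Lx *= length / arc
        x1 = x0 + Lx
        xw = np.linspace(x0, x1, max(64, int(np.ceil(Lx / 0.05))))
        curve_y = yc + amp * np.sin(2 * np.pi * xw / lam + phase)
        curve = np.column_stack([xw, curve_y])
        arc = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()

    X, Y = np.meshgrid(xs, ys)  # (nrow, ncol)
    cy_of_x = yc + amp * np.sin(2 * np.pi * np.clip(X, x0, x1) / lam + phase)
    side = Y - cy_of_x  # >0 above the interface

    cand = np.abs(side) <= (width / 2 + 3 * px)
    dist = np.full(X.shape, np.inf)
    if cand.any():
        tree = cKDTree(curve)
        d, _ = tree.query(np.column_stack([X[cand], Y[cand]]))
        dist[cand] = d
    in_window = (X >= x0) & (X <= x1)
    band = (dist <= width / 2) & in_window

    mask_lower = (side <= 0) | band
    mask_upper = ((side >= 0) & in_window) | band
    # trim cell bodies to plausible extents
    mask_lower &= Y >= margin / 2
    mask_upper &= Y <= H - margin / 2

    overlap_px = int((mask_lower & mask_upper).sum())
    return (
        CellMaskPair(mask_lower, mask_upper, px, provenance=cfg.condition),
        arc,
        overlap_px * px * px,
    )


def gen_overlap_pairs(config: OverlapGenConfig):
    """Generate mask pairs with overlap widths/areas from the configured
    truncated-normal distributions.

    Returns ``(pairs, truth)`` where ``truth`` is a DataFrame with the drawn
    width/area, the strip length used, the realized rasterized overlap area,
    and a count of infeasible draws that had to be resampled.
    """
    rng = np.random.default_rng(config.rng_seed)
    pairs = []
    rows = []
    for i in range(config.n):
        n_resampled = 0
        for _ in range(200):
            w = _trunc_normal(rng, config.width_mean, config.width_sd)
            if config.area_mean is not None:
                a = _trunc_normal(rng, config.area_mean, config.area_sd or 0.0)
                length = a / w
            else:
                length = _trunc_normal(
                    rng,
                    config.strip_length_mean,
                    config.strip_length_sd,
                    low=config.min_strip_length,
                )
                a = w * length
            feasible = (
                w >= 3 * config.pixel_size
                and config.min_strip_length <= length <= config.max_strip_length
            )
            if feasible:
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw a feasible width/area pair")
        pair, arc, realized_area = _rasterize_pair(w, length, config, rng)
        pairs.append(pair)
        rows.append(
            {
                "pair": i,
                "width_true": w,
                "area_true": a,
                "length_true": length,
                "arc_realized": arc,
                "area_realized": realized_area,
                "n_resampled": n_resampled,
            }
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# junction profile mixtures
# ---------------------------------------------------------------------------

#: category mixture; buttons are ~20% of lobes in a capillary end, and the
#: linear (curvilinear/double) configurations are the most frequent ones.
DEFAULT_JUNCTION_MIX = {
    "button": 0.20,
    "curvilinear": 0.35,
    "double": 0.25,
    "lyve1neg_curvilinear": 0.10,
    "zipper": 0.10,
}

# pre-noise archetype profiles, built to satisfy each classification rule
# with a comfortable margin at the default thresholds
_ARCHETYPES = {
    "button": dict(
        border_coverage=(0.05, 0.05),
        neck_segment_length=0.7,
        lobe_marker=True,
        whole_cell_coverage=0.35,
    ),
    "curvilinear": dict(
        border_coverage=(0.75, 0.08),
        neck_segment_length=0.8,
        lobe_marker=True,
        whole_cell_coverage=0.45,
    ),
    "double": dict(
        border_coverage=(0.75, 0.80),
        neck_segment_length=0.8,
        lobe_marker=True,
        whole_cell_coverage=0.55,
    ),
    "lyve1neg_curvilinear": dict(
        border_coverage=(0.70, 0.05),
        neck_segment_length=0.0,
        lobe_marker=False,
        whole_cell_coverage=0.45,
    ),
    "zipper": dict(
        border_coverage=(0.90, 0.90),
        neck_segment_length=0.0,
        lobe_marker=False,
        whole_cell_coverage=0.97,
    ),
}


@dataclass
class JunctionMixConfig:
    proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_MIX)
    )
    n: int = 1785
    noise: float = 0.05  # s.d. of the jitter on coverage fractions
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.proportions) != set(JUNCTION_LABELS):
            raise ValueError(
                f"proportions must cover exactly {JUNCTION_LABELS}"
            )
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def gen_junction_dataset(config: JunctionMixConfig):
    """Draw junction profiles from the category mixture.

    Returns ``(profiles, truth_labels)``.  With ``noise=0`` every profile
    satisfies its category's classification rule exactly.
    """
    rng = np.random.default_rng(config.rng_seed)
    labels = rng.choice(
        list(JUNCTION_LABELS),
        size=config.n,
        p=[config.proportions[lab] for lab in JUNCTION_LABELS],
    )
    profiles = []
    for lab in labels:
        a = _ARCHETYPES[lab]
        c1, c2 = a["border_coverage"]
        if config.noise > 0:
            c1 = float(np.clip(c1 + rng.normal(0, config.noise), 0, 1))
            c2 = float(np.clip(c2 + rng.normal(0, config.noise), 0, 1))
            wc = float(
                np.clip(
                    a["whole_cell_coverage"] + rng.normal(0, config.noise), 0, 1
                )
            )
            neck = a["neck_segment_length"]
            if neck > 0:
                neck = float(
                    max(0.05, neck + rng.normal(0, 2.0 * config.noise))
                )
        else:
            wc = a["whole_cell_coverage"]
            neck = a["neck_segment_length"]
        profiles.append(
            JunctionProfile(
                border_coverage=(c1, c2),
                neck_segment_length=neck,
                lobe_marker=a["lobe_marker"],
                whole_cell_coverage=wc,
            )
        )
    return profiles, list(labels)


# ---------------------------------------------------------------------------
# lobed outlines
# ---------------------------------------------------------------------------


def gen_lobed_outlines(
    n: int,
    lobe_count_distribution=(0, 3, 5, 7),
    amplitude: float = 4.0,
    seed: int = 0,
    radius: float = 15.0,
):
    """Rosette-type outlines r(θ) = R(1 + a sin kθ) with known lobe counts.

    ``lobe_count_distribution`` is a sequence of candidate counts (sampled
    uniformly) or a ``{count: probability}`` dict.  Count 0 gives a circle;
    counts must be 0 or >= 2 (a k=1 rosette has no concave neck).  Returns
    ``(outlines, truth_counts)``.
    """
    if isinstance(lobe_count_distribution, dict):
        ks = np.array(list(lobe_count_distribution), dtype=int)
        ps = np.array(list(lobe_count_distribution.values()), dtype=float)
        ps = ps / ps.sum()
    else:
        ks = np.asarray(list(lobe_count_distribution), dtype=int)
        ps = None
    if np.any((ks < 0) | (ks == 1)):
        raise ValueError("lobe counts must be 0 or >= 2")
    a_rel = amplitude / radius
    if a_rel >= 1.0:
        raise ValueError("amplitude must be smaller than the radius")
    # concavity at the necks requires a k² > 1 − a
    for k in ks[ks >= 2]:
        if a_rel * k * k <= 1.0 - a_rel:
            raise ValueError(
                f"amplitude {amplitude} µm too small to produce concave necks "
                f"for k={k} at radius {radius} µm"
            )
    rng = np.random.default_rng(seed)
    outlines, truth = [], []
    for _ in range(n):
        k = int(rng.choice(ks, p=ps))
        phase = rng.uniform(0, 2 * np.pi)
        th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        r = radius * (1 + (a_rel * np.sin(k * th + phase) if k else 0.0))
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        outlines.append(OutlineCurve(pts))
        truth.append(k)
    return outlines, truth


# ---------------------------------------------------------------------------
# microtubule endpoints
# ---------------------------------------------------------------------------

#: default anchoring fraction from the measured per-class endpoint counts
#: (156 concave vs 56 convex)
DEFAULT_FRAC_CONCAVE = 156.0 / (156.0 + 56.0)


def gen_mt_endpoints(
    outline: OutlineCurve | np.ndarray,
    frac_concave: float = DEFAULT_FRAC_CONCAVE,
    n: int = 212,
    seed: int = 0,
    jitter: float = 0.3,
):
    """Place cortical endpoints on concave/convex arcs at a set fraction.

    Exactly ``round(frac_concave * n)`` endpoints go to concave arcs (chosen
    uniformly in arc length within the class) and the rest to convex arcs,
    with isotropic positional jitter of s.d. ``jitter`` µm.  Returns
    ``(endpoints, truth_classes)`` with classes ``"concave"``/``"convex"``.
    """
    if not (0.0 <= frac_concave <= 1.0):
        raise ValueError("frac_concave must be in [0, 1]")
    oc = outline if isinstance(outline, OutlineCurve) else OutlineCurve(outline)
    ring, kappa, ds = oc.curvature_samples()
    concave_idx = np.where(kappa < 0)[0]
    convex_idx = np.where(kappa >= 0)[0]
    n_conc = int(round(frac_concave * n))
    n_conv = n - n_conc
    if n_conc > 0 and concave_idx.size == 0:
        raise ValueError("outline has no concave arcs but frac_concave > 0")
    if n_conv > 0 and convex_idx.size == 0:
        raise ValueError("outline has no convex arcs but frac_concave < 1")
    rng = np.random.default_rng(seed)
    pts, classes = [], []
    for cls, count, idx in (
        ("concave", n_conc, concave_idx),
        ("convex", n_conv, convex_idx),
    ):
        if count == 0:
            continue
        chosen = rng.choice(idx, size=count)
        p = ring[chosen] + rng.normal(0, jitter, size=(count, 2))
        pts.append(p)
        classes.extend([cls] * count)
    return np.vstack(pts), classes
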