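"""Scenario driver: puzzle vs. simple monolayers under pressure.

A scenario builds a seeded tessellation, optionally straightens it into its
simple-shaped derivative (matched seed by construction), meshes it, solves the
membrane equilibrium and summarizes lumen opening and stress.  "Cell-level"
stress is the area-weighted mean of element stress traces per cell (shared
walls contribute to both owners); "tissue-level" is the area-weighted mean
over all elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fem import (
    EquilibriumState,
    LoadCase,
    MaterialParams,
    SolverOptions,
    solve_equilibrium,
)
from .geometry import CylinderDomain
from .meshing import MembraneMesh, extrude_and_mesh
from .templates import (
    PuzzleParams,
    derive_simple_tessellation,
    generate_puzzle_tessellation,
)


@dataclass
class LumenMetrics:
    stations: np.ndarray  # axial positions, µm
    fractions: np.ndarray  # open area / reference area, per station
    min_fraction: float
    bulge_luminal: float  # max inward radial excursion of the luminal wall, µm
    bulge_abluminal: float  # max outward excursion of the abluminal wall, µm
    self_intersecting: bool = False


@dataclass
class ScenarioConfig:
    domain: CylinderDomain = field(default_factory=CylinderDomain)
    puzzle: PuzzleParams = field(default_factory=PuzzleParams)
    depth: float = 2.0
    max_triangle_area: float = 4.0
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    n_stations: int = 50
    end_margin: float = 10.0


@dataclass
class ScenarioResult:
    template_kind: str
    load: LoadCase
    lumen: LumenMetrics
    min_lumen_fraction: float
    bulge_luminal: float
    bulge_abluminal: float
    cell_mean_stress: np.ndarray  # kPa, per cell
    cell_max_stress: np.ndarray
    tissue_mean_stress: float
    converged: bool
    provenance: dict = field(default_factory=dict)
    mesh: MembraneMesh = None  # retained for field export
    state: EquilibriumState = None


def _station_polygon_area(theta_centers, theta, r) -> float:
    # innermost trace: per angular bin the minimum radius, then shoelace
    nb = len(theta_centers)
    bins = np.floor((theta % (2 * np.pi)) / (2 * np.pi / nb)).astype(int) % nb
    rbin = np.full(nb, np.inf)
    np.minimum.at(rbin, bins, r)
    missing = ~np.isfinite(rbin)
    if missing.all():
        return np.nan
    if missing.any():
        # periodic linear interpolation over missing bins
        idx = np.arange(nb)
        good = ~missing
        rbin = np.interp(
            idx, idx[good], rbin[good], period=nb
        )
    rbin = np.clip(rbin, 0.0, None)
    px = rbin * np.cos(theta_centers)
    py = rbin * np.sin(theta_centers)
    return 0.5 * abs(
        np.dot(px, np.roll(py, -1)) - np.dot(py, np.roll(px, -1))
    )


def lumen_metrics(
    state: EquilibriumState,
    mesh: MembraneMesh,
    n_stations: int = 50,
    end_margin: float = 10.0,
    n_theta_bins: int = 72,
) -> LumenMetrics:
    """Lumen open-area profile along the axis and radial bulge amplitudes.

    The open area at each axial station is the area enclosed by the innermost
    wall trace (per angular bin, the minimum radius of nearby luminal nodes),
    normalized by the same construction evaluated on the reference mesh so the
    unloaded state has fraction exactly 1.
    """
    L = mesh.domain.axial_length
    inner_mask = mesh.node_layer == 1
    if not inner_mask.any():
        inner_mask = np.ones(mesh.n_nodes, dtype=bool)
    zref = mesh.node_chart[:, 1]
    xr = mesh.nodes
    xd = mesh.nodes + state.displacements

    stations = np.linspace(end_margin, L - end_margin, n_stations)
    # station band: wide enough to catch a ring of nodes
    inner_z = np.sort(np.unique(np.round(zref[inner_mask], 3)))
    dz_node = np.median(np.diff(inner_z)) if len(inner_z) > 1 else 1.0
    band = max(
        (stations[1] - stations[0]) / 2 if n_stations > 1 else L,
        1.5 * dz_node,
    )
    theta_centers = (np.arange(n_theta_bins) + 0.5) * 2 * np.pi / n_theta_bins

    fractions = np.empty(n_stations)
    selfint = False
    for k, zs in enumerate(stations):
        sel = inner_mask & (np.abs(zref - zs) <= band)
        if not sel.any():
            fractions[k] = np.nan
            continue
        th_d = np.arctan2(xd[sel, 1], xd[sel, 0])
        r_d = np.hypot(xd[sel, 0], xd[sel, 1])
        th_r = np.arctan2(xr[sel, 1], xr[sel, 0])
        r_r = np.hypot(xr[sel, 0], xr[sel, 1])
        a_def = _station_polygon_area(theta_centers, th_d, r_d)
        a_ref = _station_polygon_area(theta_centers, th_r, r_r)
        if np.any(r_d <= 0):
            selfint = True
        fractions[k] = a_def / a_ref if a_ref > 0 else np.nan

    interior = (zref >= end_margin) & (zref <= L - end_margin)
    r_def = np.hypot(xd[:, 0], xd[:, 1])
    r_ref = np.hypot(xr[:, 0], xr[:, 1])
    lum = inner_mask & interior
    ab = (~inner_mask if (mesh.node_layer == 1).any() else inner_mask) & interior
    bulge_lum = float(np.max(r_ref[lum] - r_def[lum], initial=0.0))
    bulge_ab = float(np.max(r_def[ab] - r_ref[ab], initial=0.0))

    return LumenMetrics(
        stations=stations,
        fractions=fractions,
        min_fraction=float(np.nanmin(fractions)),
        bulge_luminal=bulge_lum,
        bulge_abluminal=bulge_ab,
        self_intersecting=selfint,
    )


def stress_summaries(state: EquilibriumState, mesh: MembraneMesh):
    """Per-cell and tissue-level area-weighted stress-trace summaries (kPa)."""
    areas = mesh.triangle_areas()
    tr = state.stress_trace
    ncells = mesh.n_cells if mesh.owners.max() >= 0 else 0
    cell_mean = np.zeros(ncells)
    cell_max = np.zeros(ncells)
    for c in range(ncells):
        sel = mesh.cell_triangles(c)
        w = areas[sel]
        cell_mean[c] = np.average(tr[sel], weights=w)
        cell_max[c] = tr[sel].max()
    tissue = float(np.average(tr, weights=areas))
    return cell_mean, cell_max, tissue


def run_scenario(
    template_kind: str,
    load: LoadCase,
    config: ScenarioConfig | None = None,
) -> ScenarioResult:
    """Full pipeline: template -> mesh -> equilibrium -> lumen/stress summaries.

    ``template_kind`` is ``"puzzle"`` or ``"simple"``; the simple template is
    derived from the identical seeded puzzle tessellation, so a puzzle/simple
    pair with the same config is matched by construction.
    """
    if template_kind not in ("puzzle", "simple"):
        raise ValueError(f"unknown template kind {template_kind!r}")
    cfg = config or ScenarioConfig()
    tess = generate_puzzle_tessellation(cfg.domain, cfg.puzzle)
    if template_kind == "simple":
        tess = derive_simple_tessellation(tess)
    mesh = extrude_and_mesh(tess, cfg.depth, cfg.max_triangle_area)
    mesh.thickness = cfg.material.thickness
    state = solve_equilibrium(mesh, cfg.material, load, cfg.solver)
    lum = lumen_metrics(state, mesh, cfg.n_stations, cfg.end_margin)
    cell_mean, cell_max, tissue = stress_summaries(state, mesh)
    return ScenarioResult(
        template_kind=template_kind,
        load=load,
        lumen=lum,
        min_lumen_fraction=lum.min_fraction,
        bulge_luminal=lum.bulge_luminal,
        bulge_abluminal=lum.bulge_abluminal,
        cell_mean_stress=cell_mean,
        cell_max_stress=cell_max,
        tissue_mean_stress=tissue,
        converged=state.converged,
        mesh=mesh,
        state=state,
        provenance={
            "template_kind": template_kind,
            "rng_seed": cfg.puzzle.rng_seed,
            "n_cells": cfg.puzzle.n_cells,
            "lobe_amplitude": cfg.puzzle.lobe_amplitude,
            "lobe_wavelength": cfg.puzzle.lobe_wavelength,
            "depth": cfg.depth,
            "max_triangle_area": cfg.max_triangle_area,
            "load": asdict(load),
        },
    )


@dataclass
class ComparisonReport:
    tissue_stress_ratio: float  # puzzle / simple
    cell_stress_ratio: float  # mean over cells, puzzle / simple
    lumen_fraction_difference: float  # puzzle - simple
    puzzle_open: bool
    simple_more_collapsed: bool
    puzzle_lower_stress: bool


def compare_templates(
    puzzle: ScenarioResult, simple: ScenarioResult
) -> ComparisonReport:
    """Compare matched puzzle/simple scenario results.

    Flags the three qualitative outcomes expected of lobate monolayers:
    the puzzle vessel stays open, the simple vessel is more collapsed, and the
    puzzle monolayer carries lower tissue-level stress.
    """
    if puzzle.load != simple.load:
        raise ValueError("scenario results have mismatched load cases")
    tissue_ratio = (
        puzzle.tissue_mean_stress / simple.tissue_mean_stress
        if simple.tissue_mean_stress != 0
        else 1.0
    )
    cm_p = float(np.mean(puzzle.cell_mean_stress))
    cm_s = float(np.mean(simple.cell_mean_stress))
    cell_ratio = cm_p / cm_s if cm_s != 0 else 1.0
    return ComparisonReport(
        tissue_stress_ratio=tissue_ratio,
        cell_stress_ratio=cell_ratio,
        lumen_fraction_difference=(
            puzzle.min_lumen_fraction - simple.min_lumen_fraction
        ),
        puzzle_open=puzzle.min_lumen_fraction > 0.0,
        simple_more_collapsed=(
            simple.min_lumen_fraction < puzzle.min_lumen_fraction
        ),
        puzzle_lower_stress=(
            puzzle.tissue_mean_stress < simple.tissue_mean_stress
        ),
    )
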