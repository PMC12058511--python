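"""Build a puzzle-cell vessel template and its simple-shaped derivative.

Generates the default 12-cell lobate tessellation of a 45 µm x 200 µm
cylindrical capillary wall, derives the straight-edged template by connecting
the tricellular junctions, and meshes both for finite-element analysis.
"""

import numpy as np

from lecmech import (
    CylinderDomain,
    PuzzleParams,
    derive_simple_tessellation,
    extrude_and_mesh,
    generate_puzzle_tessellation,
)
from lecmech.templates import cells_per_circumference

domain = CylinderDomain()  # 45 µm diameter, 200 µm long
params = PuzzleParams(rng_seed=0)  # 12 cells, 4 µm lobes every ~16 µm

puzzle = generate_puzzle_tessellation(domain, params)
simple = derive_simple_tessellation(puzzle)

print(f"domain: {domain.diameter} µm diameter x {domain.axial_length} µm")
print(f"cells: {puzzle.n_cells}, tricellular junctions: "
      f"{len(puzzle.tricellular_points)}")
print(f"cells per circumferential cross-section: "
      f"{cells_per_circumference(puzzle):.2f}  (the vessel is ~3 cells around)")
print(f"mean cell area: {puzzle.areas.mean():.0f} µm² (conserved: "
      f"{puzzle.total_area:.0f} vs {domain.lateral_area:.0f} µm² lateral area)")
print(f"mean perimeter, puzzle vs simple: {puzzle.perimeters.mean():.1f} vs "
      f"{simple.perimeters.mean():.1f} µm "
      "(straightening always shortens borders)")

mesh = extrude_and_mesh(puzzle, depth=2.0, max_triangle_area=4.0)
print(f"membrane mesh: {mesh.n_nodes} nodes, {mesh.n_triangles} triangles, "
      f"max triangle area {mesh.triangle_areas().max():.2f} µm²")
euler = mesh.cell_surface_euler(0)
print(f"cell 0 surface: V-E+F = {euler['euler']} "
      f"(closed manifold: {euler['closed_manifold']})")
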