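"""Validate the membrane solver against the thin-wall hoop-stress formula.

A plain cylindrical tube (radius 22.5 µm, wall 0.2 µm) is pressurized from
inside with 0.001 kPa; membrane theory predicts a mid-tube hoop stress of
p*r/t = 0.1125 kPa.
"""

import numpy as np

from lecmech import LoadCase, MaterialParams, solve_equilibrium
from lecmech.fem import stress_component
from lecmech.meshing import cylinder_shell_mesh

radius, thickness, pressure = 22.5, 0.2, 0.001
tube = cylinder_shell_mesh(radius, 200.0, n_theta=48, n_z=48)
material = MaterialParams(thickness=thickness)

state = solve_equilibrium(
    tube, material, LoadCase(cell_pressure=0.0, lumen_pressure=pressure)
)
print(f"converged: {state.converged}, residual {state.residual_norm:.2e} nN")
print(f"max radial displacement: {state.max_displacement * 1e3:.1f} nm")

centers = tube.nodes[tube.triangles].mean(axis=1)
hoop_dir = np.cross([0.0, 0.0, 1.0], centers)
hoop_dir /= np.linalg.norm(hoop_dir, axis=1, keepdims=True)
hoop = stress_component(tube, state, hoop_dir)
mid = np.abs(centers[:, 2] - 100.0) < 15.0
expected = pressure * radius / thickness
print(f"mid-tube hoop stress: {np.nanmean(hoop[mid]):.4f} kPa "
      f"(thin-wall formula p*r/t = {expected:.4f} kPa)")
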