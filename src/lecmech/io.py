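"""Serialization: tessellations as CSV+JSON, meshes as legacy VTK / PLY,
masks as TIFF with JSON sidecars, configs as YAML round-trips."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CylinderDomain
from .meshing import MembraneMesh
from .templates import CellTessellation


# ---------------------------------------------------------------------------
# tessellations
# ---------------------------------------------------------------------------


def save_tessellation(tess: CellTessellation, out_dir, name: str = "template"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, ring in enumerate(tess.cells):
        for vi, (x, z) in enumerate(ring):
            rows.append({"cell": ci, "vertex": vi, "x": x, "z": z})
    pd.DataFrame(rows).to_csv(out / f"{name}_cells.csv", index=False)
    sidecar = {
        "domain": {
            "diameter": tess.domain.diameter,
            "axial_length": tess.domain.axial_length,
        },
        "n_cells": tess.n_cells,
        "n_tricellular_points": int(len(tess.tricellular_points)),
    }
    (out / f"{name}_meta.json").write_text(json.dumps(sidecar, indent=2))
    return out / f"{name}_cells.csv"


def load_tessellation_cells(csv_path):
    """Load cell outlines saved by :func:`save_tessellation` (rings only)."""
    df = pd.read_csv(csv_path)
    return [
        g.sort_values("vertex")[["x", "z"]].to_numpy()
        for _, g in df.groupby("cell")
    ]


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def write_vtk(
    mesh: MembraneMesh,
    path,
    displacements: np.ndarray | None = None,
    cell_data: dict | None = None,
):
    """Legacy ASCII VTK (POLYDATA) writer for the membrane mesh.

    ``cell_data`` maps array names (e.g. ``"stress_trace_kPa"``) to
    per-triangle scalars.
    """
    path = Path(path)
    pts = mesh.nodes if displacements is None else mesh.nodes + displacements
    tri = mesh.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        "lecmech membrane mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
    ]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in pts]
    lines.append(f"POLYGONS {len(tri)} {4 * len(tri)}")
    lines += [f"3 {t[0]} {t[1]} {t[2]}" for t in tri]
    data = {"face_tag": mesh.tags.astype(float), "owner_cell": mesh.owners[:, 0].astype(float)}
    if cell_data:
        data.update(cell_data)
    lines.append(f"CELL_DATA {len(tri)}")
    for nm, arr in data.items():
        lines.append(f"SCALARS {nm} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(arr, dtype=float)]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ply(mesh: MembraneMesh, path, displacements: np.ndarray | None = None):
    import trimesh

    pts = mesh.nodes if displacements is None else mesh.nodes + displacements
    tm = trimesh.Trimesh(vertices=pts, faces=mesh.triangles, process=False)
    tm.export(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def save_mask_pair(pair, out_dir, stem: str):
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pa = out / f"{stem}_a.tif"
    pb = out / f"{stem}_b.tif"
    tifffile.imwrite(pa, pair.mask_a.astype(np.uint8) * 255)
    tifffile.imwrite(pb, pair.mask_b.astype(np.uint8) * 255)
    (out / f"{stem}.json").write_text(
        json.dumps(
            {"pixel_size_um": pair.pixel_size, "provenance": pair.provenance}
        )
    )
    return pa, pb


def load_mask_pair(out_dir, stem: str):
    import tifffile

    from .metrics import CellMaskPair

    out = Path(out_dir)
    meta = json.loads((out / f"{stem}.json").read_text())
    a = tifffile.imread(out / f"{stem}_a.tif") > 0
    b = tifffile.imread(out / f"{stem}_b.tif") > 0
    return CellMaskPair(a, b, meta["pixel_size_um"], meta.get("provenance", ""))


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_config(config, path):
    """Write any (nested-dataclass) config as YAML; lossless round-trip."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))
    return Path(path)


def load_config_dict(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def scenario_config_from_dict(d: dict):
    from .experiments import ScenarioConfig
    from .fem import MaterialParams, SolverOptions
    from .templates import PuzzleParams

    return ScenarioConfig(
        domain=CylinderDomain(**d.get("domain", {})),
        puzzle=PuzzleParams(**d.get("puzzle", {})),
        depth=d.get("depth", 2.0),
        max_triangle_area=d.get("max_triangle_area", 4.0),
        material=MaterialParams(**d.get("material", {})),
        solver=SolverOptions(**d.get("solver", {})),
        n_stations=d.get("n_stations", 50),
        end_margin=d.get("end_margin", 10.0),
    )
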