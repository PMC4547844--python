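"""On-disk formats: legacy-VTK meshes, CSV/JSON datasets and trajectories.

Meshes are written as ASCII legacy VTK unstructured grids (cell data holds
region labels and any number of per-element fields), one file per hour, with
a JSON manifest listing hours, stages and file names.  Transfer maps are
written in Matrix Market coordinate format.  Expression datasets are a
directory of per-observation CSV files plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

from .geometry import (GeometryParams, GrowthSeries, TransferMap, TriMesh,
                       stage_of_hour)
from .models import SPECIES
from .solver import FieldTrajectory
from .synth import ExpressionDataset, Observation


def write_vtk(path, mesh: TriMesh, cell_data: dict | None = None) -> None:
    """Write one mesh as an ASCII legacy VTK unstructured grid."""
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region_label", mesh.region_labels.astype(float))
    nv, nt = len(mesh.vertices), len(mesh.triangles)
    lines = ["# vtk DataFile Version 3.0",
             f"limbgrn mesh hour={mesh.hour}", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {nv} double"]
    lines += [f"{x:.10g} {y:.10g} 0" for x, y in mesh.vertices]
    lines.append(f"CELLS {nt} {4 * nt}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    lines.append(f"CELL_TYPES {nt}")
    lines += ["5"] * nt
    lines.append(f"CELL_DATA {nt}")
    for name, values in cell_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.10g}" for v in np.asarray(values, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read back a mesh written by :func:`write_vtk`.

    Returns (vertices, triangles, cell_data dict).
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    vertices = triangles = None
    cell_data: dict[str, np.ndarray] = {}
    n_cells = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = [tokens[i + 1 + k].split() for k in range(n)]
            vertices = np.array([[float(v[0]), float(v[1])] for v in vals])
            i += n + 1
        elif line.startswith("CELLS"):
            n_cells = int(line.split()[1])
            vals = [tokens[i + 1 + k].split() for k in range(n_cells)]
            triangles = np.array([[int(v[1]), int(v[2]), int(v[3])]
                                  for v in vals])
            i += n_cells + 1
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [float(tokens[i + 2 + k]) for k in range(n_cells)]
            cell_data[name] = np.asarray(vals)
            i += n_cells + 2
        else:
            i += 1
    if vertices is None or triangles is None:
        raise ValueError(f"{path} is not a limbgrn VTK mesh")
    return vertices, triangles, cell_data


def write_series(outdir, series: GrowthSeries) -> Path:
    """Export a growth series: one VTK per hour, transfer maps, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for h, mesh in enumerate(series.meshes):
        name = f"mesh_{h:03d}.vtk"
        write_vtk(outdir / name, mesh)
        entries.append({"hour": h, "stage": stage_of_hour(h), "file": name,
                        "n_elements": mesh.n_elements,
                        "area": mesh.total_area})
    for h, tmap in enumerate(series.transfer_maps):
        mmwrite(str(outdir / f"transfer_{h:03d}_{h + 1:03d}.mtx"), tmap.matrix)
    manifest = {
        "n_hours": series.n_hours,
        "target_edge": series.target_edge,
        "geometry_params": vars(series.params),
        "meshes": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def load_series(outdir) -> GrowthSeries:
    """Rebuild a growth series from an exported directory.

    Adjacency, areas and labels are reconstructed from the stored vertices,
    triangles and label cell data.
    """
    from .geometry import _finalize_mesh  # reuse adjacency construction

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    params = GeometryParams(**manifest["geometry_params"])
    meshes = []
    for entry in manifest["meshes"]:
        v, t, cd = read_vtk(outdir / entry["file"])
        hour = entry["hour"]
        p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        area = 0.5 * np.abs(((p1 - p0)[:, 0] * (p2 - p0)[:, 1] - (p1 - p0)[:, 1] * (p2 - p0)[:, 0]))
        mesh = _finalize_mesh(v, t, area, hour, params,
                              params.pd_extent(hour), params.half_width(hour))
        if "region_label" in cd:
            mesh.region_labels = cd["region_label"].astype(np.int8)
        meshes.append(mesh)
    tmaps = []
    for h in range(manifest["n_hours"]):
        m = mmread(str(outdir / f"transfer_{h:03d}_{h + 1:03d}.mtx")).tocsr()
        tmaps.append(TransferMap(matrix=m, source_hour=h, target_hour=h + 1))
    return GrowthSeries(meshes=meshes, transfer_maps=tmaps, params=params,
                        target_edge=manifest["target_edge"])


def write_trajectory(outdir, traj: FieldTrajectory, series: GrowthSeries,
                     csv: bool = True) -> Path:
    """Export a trajectory: VTK per output time plus a long-format CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    entries = []
    for i, (t, mh, f) in enumerate(zip(traj.times_min, traj.mesh_hours,
                                       traj.fields)):
        name = f"state_{i:04d}.vtk"
        write_vtk(outdir / name, series.meshes[mh],
                  {s: f[k] for k, s in enumerate(SPECIES)})
        entries.append({"index": i, "time_min": t, "mesh_hour": mh,
                        "file": name})
        if csv:
            for k, s in enumerate(SPECIES):
                for e, v in enumerate(f[k]):
                    records.append((e, t, s, v))
    if csv:
        pd.DataFrame(records, columns=["element", "time_min", "species",
                                       "value"]
                     ).to_csv(outdir / "trajectory.csv", index=False)
    manifest = {"h0": traj.h0, "provenance": traj.provenance,
                "states": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return outdir


def write_dataset(outdir, dataset: ExpressionDataset) -> Path:
    """Export an expression dataset (per-observation CSV + manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, o in enumerate(dataset.observations):
        name = f"obs_{i:03d}_{o.gene}.csv"
        df = pd.DataFrame({"element": np.arange(len(o.values)),
                           "value": o.values})
        if o.raw is not None:
            df["raw"] = o.raw
        df.to_csv(outdir / name, index=False)
        entries.append({"gene": o.gene, "hour": o.hour,
                        "mesh_hour": o.mesh_hour, "weight": o.weight,
                        "file": name})
    manifest = {"rescale": dataset.rescale, "provenance": dataset.provenance,
                "observations": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return outdir


def load_dataset(outdir) -> ExpressionDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    obs = []
    for e in manifest["observations"]:
        df = pd.read_csv(outdir / e["file"])
        obs.append(Observation(
            gene=e["gene"], hour=e["hour"], mesh_hour=e["mesh_hour"],
            values=df["value"].to_numpy(), weight=e["weight"],
            raw=df["raw"].to_numpy() if "raw" in df else None))
    return ExpressionDataset(observations=obs, rescale=manifest["rescale"],
                             provenance=manifest.get("provenance", {}))
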