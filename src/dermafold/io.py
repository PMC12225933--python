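"""File I/O: meshes (legacy VTK, PLY), phantoms (TIFF + JSON), curves (CSV).

Conventions
-----------
* Tetrahedral meshes are written as legacy ASCII VTK unstructured grids.
  Layer labels live in the cell-data array ``layer`` (0 bone, 1 dermis,
  2 epidermis), growth normals in ``surface_normal``; boundary tags in the
  point-data array ``boundary_tag`` (0 free, 1 bone_fixed, 2 lateral) and
  sliding-plane projectors flattened in ``constraint``.
* Triangulated surfaces go to PLY (ASCII) via trimesh, with per-vertex
  scalars saved in a JSON sidecar ``<name>.scalars.json`` (PLY has no
  standard slot for arbitrary vertex fields).
* Image phantoms are multi-page TIFF plus a JSON sidecar holding voxel
  size and the analytic ground truth; axis order z-slowest, voxel-centred,
  0-based coordinates.
* Indentation curves are CSV with columns ``displacement_um, force_uN``
  plus a JSON header file with probe metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .indentation import IndentationCurve
from .meshing import LayeredMesh
from .surfaces import TriSurface


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
# legacy VTK unstructured grid
# --------------------------------------------------------------------------

def write_vtk_mesh(path, mesh: LayeredMesh,
                   positions: np.ndarray | None = None) -> Path:
    """Write a layered tet mesh (optionally with deformed positions)."""
    pos = mesh.nodes if positions is None else positions
    cell_data = {
        "layer": mesh.layer.astype(float),
    }
    vec_cell = {"surface_normal": mesh.surface_normal}
    point_data = {"boundary_tag": mesh.boundary_tags.astype(float)}
    return write_vtk_unstructured(
        path, pos, mesh.tets, cell_data=cell_data,
        cell_vectors=vec_cell, point_data=point_data,
    )


def write_vtk_unstructured(path, points, tets, cell_data=None,
                           point_data=None, cell_vectors=None,
                           point_vectors=None) -> Path:
    path = Path(path)
    points = np.asarray(points, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("dermafold unstructured grid\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} double\n")
        np.savetxt(f, points, fmt="%.10g")
        f.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        cells = np.column_stack([np.full(len(tets), 4), tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(f, np.full(len(tets), 10), fmt="%d")  # VTK_TETRA
        if cell_data or cell_vectors:
            f.write(f"CELL_DATA {len(tets)}\n")
            for name, arr in (cell_data or {}).items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.10g")
            for name, arr in (cell_vectors or {}).items():
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.10g")
        if point_data or point_vectors:
            f.write(f"POINT_DATA {len(points)}\n")
            for name, arr in (point_data or {}).items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.10g")
            for name, arr in (point_vectors or {}).items():
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.10g")
    return path


def read_vtk_unstructured(path):
    """Read a legacy ASCII VTK unstructured grid written by this package.

    Returns ``(points, tets, cell_data, point_data)`` where the data dicts
    hold scalar and vector arrays by name.
    """
    tokens: list[str] = []
    with open(path) as f:
        lines = f.readlines()
    points = tets = None
    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    i = 0

    def read_block(start, n, ncols):
        vals = []
        j = start
        while len(vals) < n * ncols:
            vals.extend(lines[j].split())
            j += 1
        return np.array(vals[: n * ncols], dtype=float).reshape(n, ncols), j

    section = None
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            points, i = read_block(i + 1, n, 3)
            continue
        if key == "CELLS":
            n = int(parts[1])
            raw, i = read_block(i + 1, n, 5)
            tets = raw[:, 1:].astype(np.int64)
            continue
        if key == "CELL_TYPES":
            n = int(parts[1])
            _, i = read_block(i + 1, n, 1)
            continue
        if key == "CELL_DATA":
            section = cell_data
            i += 1
            continue
        if key == "POINT_DATA":
            section = point_data
            i += 1
            continue
        if key == "SCALARS" and section is not None:
            name = parts[1]
            n = len(tets) if section is cell_data else len(points)
            arr, i = read_block(i + 2, n, 1)   # skip LOOKUP_TABLE line
            section[name] = arr.ravel()
            continue
        if key == "VECTORS" and section is not None:
            name = parts[1]
            n = len(tets) if section is cell_data else len(points)
            arr, i = read_block(i + 1, n, 3)
            section[name] = arr
            continue
        i += 1
    return points, tets, cell_data, point_data


def read_vtk_mesh(path) -> LayeredMesh:
    """Reassemble a LayeredMesh written by :func:`write_vtk_mesh`.

    Lateral sliding-plane projectors are not stored in VTK; reloaded meshes
    get free/clamped constraints only (sufficient for visualisation and
    re-analysis, not for re-running a rim-constrained simulation).
    """
    points, tets, cell_data, point_data = read_vtk_unstructured(path)
    tags = point_data["boundary_tag"].astype(np.int64)
    constraint = np.tile(np.eye(3), (len(points), 1, 1))
    constraint[tags == 1] = 0.0
    return LayeredMesh(
        nodes=points, tets=tets,
        layer=cell_data["layer"].astype(np.int64),
        surface_normal=cell_data["surface_normal"],
        boundary_tags=tags, constraint=constraint,
        metadata={"source": str(path)},
    )


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

def write_surface_ply(path, surface: TriSurface) -> Path:
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces,
                         process=False)
    path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    scalars = {
        k: _jsonable(v) for k, v in surface.vertex_data.items()
    }
    if scalars:
        sidecar = path.with_suffix(path.suffix + ".scalars.json")
        sidecar.write_text(json.dumps(scalars))
    return path


def read_surface_ply(path) -> TriSurface:
    import trimesh

    path = Path(path)
    tm = trimesh.load(path, file_type="ply", process=False)
    surf = TriSurface(vertices=np.asarray(tm.vertices),
                      faces=np.asarray(tm.faces))
    sidecar = path.with_suffix(path.suffix + ".scalars.json")
    if sidecar.exists():
        for k, v in json.loads(sidecar.read_text()).items():
            surf.vertex_data[k] = np.asarray(v)
    return surf


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

def write_phantom(path, phantom) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, phantom.stack.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "voxel_size": phantom.voxel_size,
        "truth_outer_surface": _jsonable(phantom.truth_outer_surface),
        "truth_inner_surface": _jsonable(phantom.truth_inner_surface),
        "truth_cells": _jsonable(phantom.truth_cells),
        "metadata": _jsonable(phantom.metadata),
    }))
    np.save(path.with_suffix(".bone.npy"), phantom.truth_bone_mask)
    return path


def read_phantom(path):
    import tifffile

    from .synthetic import ImagePhantom

    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    bone_path = path.with_suffix(".bone.npy")
    bone = (np.load(bone_path) if bone_path.exists()
            else np.zeros(stack.shape, dtype=bool))
    return ImagePhantom(
        stack=stack, voxel_size=meta["voxel_size"],
        truth_outer_surface=meta["truth_outer_surface"],
        truth_inner_surface=meta["truth_inner_surface"],
        truth_cells=np.asarray(meta["truth_cells"]).reshape(-1, 3),
        truth_bone_mask=bone, metadata=meta["metadata"],
    )


# --------------------------------------------------------------------------
# indentation curves
# --------------------------------------------------------------------------

def write_curves(directory, curves: list[IndentationCurve]) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for c in curves:
        name = f"{c.curve_id or 'curve'}.csv"
        pd.DataFrame({
            "displacement_um": c.displacement, "force_uN": c.force,
        }).to_csv(directory / name, index=False)
        index.append({
            "file": name, "curve_id": c.curve_id,
            "replicate_id": c.replicate_id,
            "probe_radius_um": c.probe_radius,
            "truth_modulus_pa": c.truth_modulus,
            "grid_position": c.grid_position,
        })
    (directory / "curves.json").write_text(json.dumps(_jsonable(index)))
    return directory


def read_curves(directory) -> list[IndentationCurve]:
    directory = Path(directory)
    index = json.loads((directory / "curves.json").read_text())
    curves = []
    for entry in index:
        df = pd.read_csv(directory / entry["file"])
        curves.append(IndentationCurve(
            displacement=df["displacement_um"].to_numpy(),
            force=df["force_uN"].to_numpy(),
            probe_radius=entry["probe_radius_um"],
            truth_modulus=entry.get("truth_modulus_pa"),
            curve_id=entry.get("curve_id", ""),
            replicate_id=entry.get("replicate_id", ""),
            grid_position=(tuple(entry["grid_position"])
                           if entry.get("grid_position") else None),
        ))
    return curves
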