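"""Field containers on disk.

Displacement and strain fields are exchanged as single-file HDF5 stores with
named datasets (``/values``, ``/grid/n_elems``, ``/grid/h``,
``/grid/origin``) and a JSON sidecar recording units and conventions.
Elasticity tensors export as plain-text Kelvin matrices with a metadata
header.
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .elasticity import ElasticTensor
from .grids import DisplacementField, StrainField, StructuredGrid

__all__ = ["write_field", "read_field", "write_tensor_txt",
           "read_tensor_txt", "write_realization", "read_realization",
           "realization_to_csv", "export_vtk"]

_FIELD_KINDS = {"displacement": DisplacementField, "strain": StrainField}


def write_field(path: "str | pathlib.Path",
                fld: "DisplacementField | StrainField") -> None:
    """Lossless single-file store of a grid field plus a JSON sidecar."""
    path = pathlib.Path(path)
    kind = "displacement" if isinstance(fld, DisplacementField) else "strain"
    meta = {
        "kind": kind,
        "units": "m" if kind == "displacement" else "dimensionless",
        "layout": ("nodes x dim, lexicographic x fastest" if
                   kind == "displacement" else
                   "cells x kelvin components (sqrt2 on shear)"),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fld.values)
        g = f.create_group("grid")
        g.create_dataset("n_elems", data=np.asarray(fld.grid.n_elems))
        g.create_dataset("h", data=np.asarray(fld.grid.h))
        g.create_dataset("origin", data=np.asarray(fld.grid.origin))
        f.attrs["meta"] = json.dumps(meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2))


def read_field(path: "str | pathlib.Path"):
    """Read a field written by :func:`write_field`; raises a clear error on
    truncated or foreign files."""
    path = pathlib.Path(path)
    try:
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            values = np.asarray(f["values"])
            grid = StructuredGrid(
                tuple(int(n) for n in f["grid/n_elems"][()]),
                tuple(float(x) for x in f["grid/h"][()]),
                tuple(float(x) for x in f["grid/origin"][()]))
    except (OSError, KeyError) as exc:
        raise IOError(f"corrupt or unrecognized field container: {path}") \
            from exc
    cls = _FIELD_KINDS.get(meta.get("kind"))
    if cls is None:
        raise IOError(f"unknown field kind in {path}: {meta.get('kind')!r}")
    return cls(grid, values)


def write_tensor_txt(path: "str | pathlib.Path", t: ElasticTensor,
                     units: str = "GPa") -> None:
    """Columnar plain-text export of a Kelvin matrix with a header recording
    (kind, form, units)."""
    header = f"kind={t.kind} form={t.form} units={units} convention=kelvin"
    np.savetxt(path, t.kelvin, header=header)


def read_tensor_txt(path: "str | pathlib.Path") -> ElasticTensor:
    path = pathlib.Path(path)
    header = path.read_text().splitlines()[0].lstrip("# ").split()
    meta = dict(item.split("=", 1) for item in header if "=" in item)
    return ElasticTensor(np.loadtxt(path), kind=meta.get("kind", "stiffness"),
                         form=meta.get("form", "full3d"))


def write_realization(path, realization, spec=None) -> None:
    """Store a random-field realization: datasets ``/kelvin`` (cells x n x
    n), ``/grid/*`` and, when given, the generating ``/spec``."""
    from .random_field import FieldRealization  # noqa: F401  (doc only)

    path = pathlib.Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kelvin", data=realization.values)
        g = f.create_group("grid")
        g.create_dataset("n_elems", data=np.asarray(realization.grid.n_elems))
        g.create_dataset("h", data=np.asarray(realization.grid.h))
        g.create_dataset("origin", data=np.asarray(realization.grid.origin))
        f.attrs["kind"] = realization.kind
        if spec is not None:
            s = f.create_group("spec")
            s.create_dataset("mean", data=spec.mean.kelvin)
            s.attrs["mean_kind"] = spec.mean.kind
            s.attrs["delta"] = spec.delta
            s.create_dataset("ell", data=np.asarray(spec.ell))
            s.attrs["kernel"] = spec.kernel
            s.attrs["seed"] = spec.seed


def read_realization(path):
    from .random_field import FieldRealization

    path = pathlib.Path(path)
    try:
        with h5py.File(path, "r") as f:
            values = np.asarray(f["kelvin"])
            grid = StructuredGrid(
                tuple(int(n) for n in f["grid/n_elems"][()]),
                tuple(float(x) for x in f["grid/h"][()]),
                tuple(float(x) for x in f["grid/origin"][()]))
            kind = f.attrs["kind"]
    except (OSError, KeyError) as exc:
        raise IOError(f"corrupt or unrecognized realization container: "
                      f"{path}") from exc
    return FieldRealization(grid, values, kind=str(kind))


def realization_to_csv(path, realization) -> None:
    """Flat CSV export (one row per cell: centroid coordinates followed by
    the upper-triangle Kelvin entries); intended for small grids."""
    cent = realization.grid.cell_centroids()
    n = realization.values.shape[-1]
    iu = np.triu_indices(n)
    flat = realization.values[:, iu[0], iu[1]]
    header = ",".join([f"x{a + 1}" for a in range(cent.shape[1])]
                      + [f"k{i + 1}{j + 1}" for i, j in zip(*iu)])
    np.savetxt(path, np.hstack([cent, flat]), delimiter=",", header=header,
               comments="")


def export_vtk(path, grid: StructuredGrid,
               point_data: "dict[str, np.ndarray] | None" = None,
               cell_data: "dict[str, np.ndarray] | None" = None) -> None:
    """Legacy-VTK ASCII export of a structured grid with optional nodal and
    per-cell arrays, for visualization in ParaView and friends."""
    path = pathlib.Path(path)
    dim = grid.dim
    nn = grid.n_nodes_axis
    dims = list(nn) + [1] * (3 - dim)
    origin = list(grid.origin) + [0.0] * (3 - dim)
    h = list(grid.h) + [1.0] * (3 - dim)
    lines = ["# vtk DataFile Version 3.0", "mesoid field export", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
             f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
             f"SPACING {h[0]} {h[1]} {h[2]}"]

    def emit(block, name, arr):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        ncomp = arr.shape[1]
        lines.append(f"SCALARS {name} double {ncomp}")
        lines.append("LOOKUP_TABLE default")
        for row in arr:
            lines.append(" ".join(f"{v:.9g}" for v in row))

    if point_data:
        lines.append(f"POINT_DATA {grid.n_nodes}")
        for name, arr in point_data.items():
            emit("POINT_DATA", name, arr)
    if cell_data:
        lines.append(f"CELL_DATA {grid.n_cells}")
        for name, arr in cell_data.items():
            emit("CELL_DATA", name, arr)
    path.write_text("\n".join(lines) + "\n")
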