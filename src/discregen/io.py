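"""Field and grid containers on disk.

Grids and solved fields go to HDF5 (arrays + metadata attributes); voxel
centers and profiles go to flat CSV for inspection.  Loading re-validates
shapes against the stored geometry.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import DiscGeometry, LabeledGrid
from .transport import SteadyStateFields

__all__ = ["save_grid", "load_grid", "save_fields", "load_fields",
           "grid_centers_table"]

_GEO_FIELDS = ("af_semi_lateral", "af_semi_ap", "np_semi_lateral",
               "np_semi_ap", "height")


def save_grid(grid: LabeledGrid, path: str | Path) -> None:
    """Labeled grid -> HDF5 (label array, tag array, spacing, geometry)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.create_dataset("tags", data=grid.tags, compression="gzip")
        f.attrs["spacing"] = grid.spacing
        f.attrs["species"] = grid.geometry.species
        for name in _GEO_FIELDS:
            f.attrs[name] = getattr(grid.geometry, name)


def load_grid(path: str | Path) -> LabeledGrid:
    with h5py.File(path, "r") as f:
        geometry = DiscGeometry(
            species=str(f.attrs["species"]),
            **{name: float(f.attrs[name]) for name in _GEO_FIELDS})
        return LabeledGrid(geometry=geometry, spacing=float(f.attrs["spacing"]),
                           labels=f["labels"][()], tags=f["tags"][()])


def save_fields(fields: SteadyStateFields, grid: LabeledGrid,
                path: str | Path) -> None:
    """Solved fields + their grid -> one HDF5 container."""
    with h5py.File(path, "w") as f:
        for name in ("oxygen", "glucose", "lactate", "ph"):
            f.create_dataset(name, data=getattr(fields, name), compression="gzip")
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.create_dataset("tags", data=grid.tags, compression="gzip")
        f.attrs["spacing"] = grid.spacing
        f.attrs["species"] = grid.geometry.species
        for name in _GEO_FIELDS:
            f.attrs[name] = getattr(grid.geometry, name)
        f.attrs["iterations"] = fields.iterations
        f.attrs["ph_clamped"] = fields.ph_clamped
        for met, val in fields.flux_balance.items():
            f.attrs[f"flux_balance_{met}"] = val
        for met, val in fields.total_consumption.items():
            f.attrs[f"total_consumption_{met}"] = val
        f.attrs["residual_history"] = np.asarray(fields.residual_history)


def load_fields(path: str | Path) -> tuple[SteadyStateFields, LabeledGrid]:
    with h5py.File(path, "r") as f:
        geometry = DiscGeometry(
            species=str(f.attrs["species"]),
            **{name: float(f.attrs[name]) for name in _GEO_FIELDS})
        grid = LabeledGrid(geometry=geometry, spacing=float(f.attrs["spacing"]),
                           labels=f["labels"][()], tags=f["tags"][()])
        mets = ("glucose", "oxygen", "lactate")
        fields = SteadyStateFields(
            oxygen=f["oxygen"][()], glucose=f["glucose"][()],
            lactate=f["lactate"][()], ph=f["ph"][()],
            iterations=int(f.attrs["iterations"]),
            residual_history=tuple(f.attrs["residual_history"]),
            flux_balance={m: float(f.attrs[f"flux_balance_{m}"]) for m in mets},
            total_consumption={m: float(f.attrs[f"total_consumption_{m}"])
                               for m in mets},
            ph_clamped=bool(f.attrs["ph_clamped"]),
        )
    for name in ("oxygen", "glucose", "lactate", "ph"):
        if getattr(fields, name).shape != grid.labels.shape:
            raise ValueError(f"field {name!r} shape does not match the grid")
    return fields, grid


def grid_centers_table(grid: LabeledGrid) -> pd.DataFrame:
    """Flat voxel-center table (x, y, z in mm plus domain label)."""
    nx, ny, nz = grid.shape
    xi, yi, zi = np.meshgrid(grid.centers(0), grid.centers(1), grid.centers(2),
                             indexing="ij")
    names = np.array(["exterior", "np", "af"])
    return pd.DataFrame({
        "x_mm": xi.ravel(), "y_mm": yi.ravel(), "z_mm": zi.ravel(),
        "domain": names[grid.labels.ravel()],
    })
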