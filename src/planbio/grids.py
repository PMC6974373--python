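"""3D dose grids and binary structure masks.

A :class:`DoseGrid` is a plain 3D array of absorbed dose in Gy together with
the voxel spacing in mm; a :class:`StructureMask` is a boolean array congruent
with a grid.  Grids can be round-tripped through a plain-text CSV voxel dump
with a JSON sidecar carrying shape/spacing/origin (DICOM-RT is deliberately
not parsed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CongruenceError, EmptyStructureError

__all__ = ["DoseGrid", "StructureMask", "read_grid_csv", "write_grid_csv"]


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose on a regular 3D voxel lattice.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Dose per voxel in Gy; must be finite and non-negative.
    spacing : tuple of float
        Voxel edge lengths in mm along each axis; all > 0.
    origin : tuple of float
        Spatial offset of the first voxel corner in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(values < 0):
            raise ValueError("dose grid contains negative dose")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm^3 (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Named boolean mask on the same lattice as a :class:`DoseGrid`."""

    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={voxels.ndim}")
        object.__setattr__(self, "voxels", voxels)

    def check_congruent(self, grid: DoseGrid) -> None:
        if self.voxels.shape != grid.shape:
            raise CongruenceError(
                f"mask {self.name!r} shape {self.voxels.shape} does not match "
                f"grid shape {grid.shape}"
            )

    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def volume_cm3(self, grid: DoseGrid) -> float:
        self.check_congruent(grid)
        n = self.voxel_count()
        if n == 0:
            raise EmptyStructureError(f"structure {self.name!r} is empty")
        return n * grid.voxel_volume_cm3


def write_grid_csv(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid as a flat one-column CSV plus a JSON sidecar.

    The sidecar (``<path>.json``) records shape, spacing and origin so the
    dump is self-describing.  Voxels are in C (row-major) order.
    """
    path = Path(path)
    np.savetxt(path, grid.values.ravel(), fmt="%.6g", header="dose_gy", comments="")
    sidecar = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_grid_csv(path: str | Path) -> DoseGrid:
    """Read a grid written by :func:`write_grid_csv`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    flat = np.loadtxt(path, skiprows=1)
    values = flat.reshape(tuple(meta["shape"]))
    return DoseGrid(values, tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]))
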