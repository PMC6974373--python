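"""Dose-volume histograms and the point dose-volume metrics built on them.

The DVH is the central in-memory object of the package: every radiobiological
evaluator (EQD2 conversion, TCP, NTCP, plan addition) consumes a differential
DVH.  Curves carry left-edge dose bins (ascending, not necessarily uniform —
nonlinear per-bin dose transforms such as EQD2 produce non-uniform bins) and
per-bin absolute volumes in cm^3.

Conventions
-----------
* Histogram bins from a grid are half-open ``[edge, edge + width)`` with a
  constant width (default 0.05 Gy) on a contiguous grid starting at 0 Gy, so
  the cumulative curve drops by at most one bin per step and within-bin linear
  interpolation of D(v) is accurate to one bin width.
* ``V(D)`` (volume receiving at least D) counts all bins whose left edge is
  >= D; ``D_min``/``D_max`` are the lowest/highest occupied left edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .errors import EmptyStructureError
from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "cumulative",
    "differential",
    "volume_at_dose",
    "dose_at_hot_volume",
    "d_max",
    "d_min",
    "mean_dose",
    "rescale_doses",
    "read_dvh_csv",
    "write_dvh_csv",
    "plot_dvh",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 0.05  # Gy


@dataclass(frozen=True)
class DVHCurve:
    """A differential or cumulative dose-volume histogram.

    Parameters
    ----------
    dose_bins : ndarray
        Left-edge dose of each bin in Gy, strictly ascending.
    volumes : ndarray
        Differential view: absolute volume (cm^3) in each bin.
        Cumulative view: volume receiving at least ``dose_bins[i]``.
    total_volume : float, optional
        Structure volume in cm^3; defaults to the sum (differential) or the
        first entry (cumulative).
    kind : {"differential", "cumulative"}
    """

    dose_bins: np.ndarray
    volumes: np.ndarray
    total_volume: float | None = None
    kind: Literal["differential", "cumulative"] = "differential"

    def __post_init__(self) -> None:
        bins = np.asarray(self.dose_bins, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        if bins.ndim != 1 or bins.shape != vols.shape or bins.size == 0:
            raise ValueError("dose_bins and volumes must be equal-length 1D arrays")
        if np.any(np.diff(bins) <= 0):
            raise ValueError("dose_bins must be strictly ascending")
        if np.any(bins < 0) or np.any(vols < -1e-12):
            raise ValueError("doses and volumes must be non-negative")
        if self.kind not in ("differential", "cumulative"):
            raise ValueError(f"unknown DVH kind {self.kind!r}")
        vols = np.clip(vols, 0.0, None)
        if self.kind == "cumulative" and np.any(np.diff(vols) > 1e-9 * max(vols[0], 1.0)):
            raise ValueError("cumulative DVH must be non-increasing in dose")
        total = self.total_volume
        if total is None:
            total = float(vols.sum()) if self.kind == "differential" else float(vols[0])
        object.__setattr__(self, "dose_bins", bins)
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "total_volume", float(total))

    @property
    def fractional_volumes(self) -> np.ndarray:
        """Differential volumes as fractions of the structure volume."""
        if self.kind != "differential":
            raise ValueError("fractional_volumes requires a differential curve")
        return self.volumes / self.total_volume


def compute_dvh(
    grid: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    """Differential DVH of ``grid`` over ``mask`` with half-open uniform bins.

    The bin grid is contiguous from 0 Gy to the maximum structure dose; bin
    assignment is ``[edge, edge + bin_width)``.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    mask.check_congruent(grid)
    doses = grid.values[mask.voxels]
    if doses.size == 0:
        raise EmptyStructureError(f"structure {mask.name!r} is empty")
    idx = np.floor(doses / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    bins = np.arange(counts.size) * bin_width
    vols = counts * grid.voxel_volume_cm3
    return DVHCurve(bins, vols, total_volume=doses.size * grid.voxel_volume_cm3)


def cumulative(dvh: DVHCurve) -> DVHCurve:
    """Differential -> cumulative transform.

    The cumulative value at dose D is the volume receiving at least D; the
    value at 0 Gy equals the structure volume.
    """
    if dvh.kind == "cumulative":
        raise ValueError("DVH is already cumulative")
    bins, vols = dvh.dose_bins, dvh.volumes
    if bins[0] > 0:
        bins = np.concatenate([[0.0], bins])
        vols = np.concatenate([[0.0], vols])
    cum = np.cumsum(vols[::-1])[::-1]
    return DVHCurve(bins, cum, total_volume=dvh.total_volume, kind="cumulative")


def differential(dvh: DVHCurve) -> DVHCurve:
    """Cumulative -> differential (inverse of :func:`cumulative`)."""
    if dvh.kind == "differential":
        return dvh
    vols = np.concatenate([-np.diff(dvh.volumes), [dvh.volumes[-1]]])
    return DVHCurve(dvh.dose_bins, vols, total_volume=dvh.total_volume)


class VolumeAtDose(NamedTuple):
    cm3: float
    percent: float


def volume_at_dose(
    dvh: DVHCurve,
    threshold: float,
    relative_to: Literal["absolute", "percent"] = "absolute",
    prescription: float | None = None,
) -> VolumeAtDose:
    """Volume receiving at least a dose threshold (V_x metrics).

    ``relative_to="percent"`` interprets ``threshold`` as a percentage of
    ``prescription`` (e.g. V_95%).  Returns both cm^3 and percent of the
    structure volume.
    """
    if relative_to == "percent":
        if prescription is None or prescription <= 0:
            raise ValueError("percent threshold requires a positive prescription")
        threshold = threshold / 100.0 * prescription
    if threshold < 0:
        raise ValueError(f"dose threshold must be >= 0, got {threshold}")
    diff = differential(dvh)
    cm3 = float(diff.volumes[diff.dose_bins >= threshold].sum())
    return VolumeAtDose(cm3, 100.0 * cm3 / diff.total_volume)


def dose_at_hot_volume(dvh: DVHCurve, hot_volume: float) -> float:
    """Minimum dose received by the hottest ``hot_volume`` cm^3 (D_2cm3 etc.).

    Bins are treated as point masses at their left edge (doses are already
    quantised to the bin grid, so sub-bin interpolation would add no
    information): the result is the highest bin dose D with at least
    ``hot_volume`` receiving >= D.  Exact for uniform doses; within one bin
    width of a voxel-level sort for histogrammed grids.  ``hot_volume`` equal
    to the structure volume returns D_min; ``hot_volume -> 0`` returns D_max.
    """
    diff = differential(dvh)
    total = diff.total_volume
    if hot_volume > total * (1 + 1e-9):
        raise ValueError(f"hot_volume {hot_volume} cm3 exceeds structure volume {total} cm3")
    occupied = diff.dose_bins[diff.volumes > 0]
    if occupied.size == 0:
        raise EmptyStructureError("DVH holds no volume")
    if hot_volume <= 0:
        return float(occupied[-1])
    cum = cumulative(diff)
    e, c = cum.dose_bins, cum.volumes
    i = int(np.nonzero(c >= min(hot_volume, total) - 1e-12 * max(total, 1.0))[0][-1])
    return float(e[i])


def d_max(dvh: DVHCurve) -> float:
    """Highest occupied bin dose."""
    return dose_at_hot_volume(dvh, 0.0)


def d_min(dvh: DVHCurve) -> float:
    """Lowest occupied bin dose."""
    return dose_at_hot_volume(dvh, differential(dvh).total_volume)


def mean_dose(dvh: DVHCurve) -> float:
    diff = differential(dvh)
    return float(np.sum(diff.dose_bins * diff.fractional_volumes))


def rescale_doses(dvh: DVHCurve, factor: float) -> DVHCurve:
    """Scale every bin dose by a positive factor; volumes unchanged."""
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    diff = differential(dvh)
    return DVHCurve(diff.dose_bins * factor, diff.volumes, total_volume=diff.total_volume)


# ---------------------------------------------------------------------------
# plain-text I/O: header dose_gy,volume_cm3,kind


def write_dvh_csv(dvh: DVHCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "dose_gy": dvh.dose_bins,
            "volume_cm3": dvh.volumes,
            "kind": dvh.kind,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_dvh_csv(path: str | Path | io.StringIO) -> DVHCurve:
    """Read a DVH CSV; cumulative input is auto-converted to differential."""
    df = pd.read_csv(path)
    required = {"dose_gy", "volume_cm3", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"DVH CSV must have columns {sorted(required)}")
    kinds = set(df["kind"].unique())
    if len(kinds) != 1 or kinds - {"differential", "cumulative"}:
        raise ValueError(f"DVH CSV kind column must be uniformly one of differential/cumulative, got {kinds}")
    kind = kinds.pop()
    curve = DVHCurve(df["dose_gy"].to_numpy(), df["volume_cm3"].to_numpy(), kind=kind)
    return differential(curve)


def plot_dvh(dvhs: dict[str, DVHCurve], ax=None, relative: bool = True):
    """Plot cumulative DVHs (matplotlib imported lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, dvh in dvhs.items():
        cum = cumulative(differential(dvh)) if dvh.kind == "differential" else dvh
        y = cum.volumes
        if relative:
            y = 100.0 * y / cum.total_volume
        ax.step(cum.dose_bins, y, where="post", label=label)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)" if relative else "volume (cm$^3$)")
    ax.legend()
    return ax
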