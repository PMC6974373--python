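"""Plan-quality indices: RTOG conformity index and conformation number.

With TV the target volume, V_RI the volume enclosed by the prescription
isodose and TV_RI their intersection (all cm^3):

* ``CI = V_RI / TV`` (RTOG convention; > 1 means healthy tissue is included,
  < 1 means the prescription isodose is smaller than the target),
* ``coverage_fraction = TV_RI / TV`` (the alternative reading of CI found in
  parts of the literature),
* ``CN = (TV_RI/TV) x (TV_RI/V_RI)`` in [0, 1]; 1 means the reference isodose
  covers exactly the target with no spill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "ConformityInputs",
    "conformity_inputs_from_grid",
    "conformity_index",
    "coverage_fraction",
    "conformation_number",
]


@dataclass(frozen=True)
class ConformityInputs:
    """Target volume, prescription-isodose volume and their overlap (cm^3)."""

    tv: float
    v_ri: float
    tv_ri: float

    def __post_init__(self) -> None:
        if self.tv <= 0:
            raise ValueError(f"target volume must be > 0, got {self.tv}")
        if self.v_ri < 0 or self.tv_ri < 0:
            raise ValueError("volumes must be >= 0")
        if self.tv_ri > min(self.tv, self.v_ri) * (1 + 1e-9):
            raise ValueError(
                f"overlap {self.tv_ri} exceeds min(TV, V_RI) = {min(self.tv, self.v_ri)}"
            )


def conformity_inputs_from_grid(
    grid: DoseGrid, target: StructureMask, prescription: float
) -> ConformityInputs:
    """Voxel-count evaluation of TV, V_RI and TV_RI at a prescription dose."""
    if prescription <= 0:
        raise ValueError(f"prescription must be > 0, got {prescription}")
    target.check_congruent(grid)
    vv = grid.voxel_volume_cm3
    ri = grid.values >= prescription
    return ConformityInputs(
        tv=target.volume_cm3(grid),
        v_ri=float(ri.sum()) * vv,
        tv_ri=float(np.logical_and(ri, target.voxels).sum()) * vv,
    )


def conformity_index(c: ConformityInputs) -> float:
    """RTOG conformity index CI = V_RI / TV."""
    return c.v_ri / c.tv


def coverage_fraction(c: ConformityInputs) -> float:
    """Fraction of the target enclosed by the prescription isodose, TV_RI / TV."""
    return c.tv_ri / c.tv


def conformation_number(c: ConformityInputs) -> float:
    """CN = (TV_RI/TV) x (TV_RI/V_RI); 0 is returned (with a warning) if V_RI = 0."""
    if c.v_ri == 0:
        warnings.warn("prescription isodose encloses no volume; CN = 0", stacklevel=2)
        return 0.0
    return (c.tv_ri / c.tv) * (c.tv_ri / c.v_ri)
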