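"""Whole-treatment assessment: per-bin EQD2 transform and DVH-level plan sum.

The external-beam course and the boost are planned on geometries that cannot
be deformably registered, so plans are summed at the DVH level ("parameter
adding"): both cumulative curves are resampled on a common volume-fraction
axis and doses are added at equal cumulative-volume fractions (rank-matched
addition — the conservative assumption that the hot regions of the two plans
coincide spatially).  An alternative "uniform-background" mode adds the
boost's structure-mean dose to every bin instead.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .conformity import (
    conformation_number,
    conformity_index,
    conformity_inputs_from_grid,
    coverage_fraction,
)
from .dvh import (
    DEFAULT_BIN_WIDTH,
    DVHCurve,
    compute_dvh,
    d_max,
    d_min,
    differential,
    dose_at_hot_volume,
    mean_dose,
    rescale_doses,
    volume_at_dose,
)
from .errors import CombinationError
from .fractionation import FractionationScheme, TissueRadiobiology
from .grids import DoseGrid, StructureMask
from .response import LKBParams, lkb_ntcp, tcp_poisson

__all__ = ["dvh_to_eqd2", "add_plans", "whole_treatment_metrics"]


def dvh_to_eqd2(dvh: DVHCurve, n_fractions: int, tissue: TissueRadiobiology) -> DVHCurve:
    """Map each bin dose to its EQD2 assuming the bin shares the plan's fractionation.

    With per-bin dose per fraction ``d_i = D_i / n_fractions``:
    ``D_i -> D_i (d_i + alpha/beta) / (2 + alpha/beta)``.  Volumes are
    unchanged; the transformed bin grid is no longer uniform.
    """
    if n_fractions <= 0:
        raise ValueError(f"n_fractions must be > 0, got {n_fractions}")
    diff = differential(dvh)
    ab = tissue.alpha_beta
    d_i = diff.dose_bins / n_fractions
    new_doses = diff.dose_bins * (d_i + ab) / (2.0 + ab)
    return DVHCurve(new_doses, diff.volumes, total_volume=diff.total_volume)


def add_plans(
    dvh_a: DVHCurve,
    dvh_b: DVHCurve,
    n_points: int = 1000,
    bin_width: float = DEFAULT_BIN_WIDTH,
    mode: Literal["rank", "uniform-background"] = "rank",
) -> DVHCurve:
    """Sum two EQD2-domain DVHs of the same structure.

    mode="rank"
        Doses added at equal cumulative-volume fractions (worst-case spatial
        correlation of hot regions).
    mode="uniform-background"
        Plan B enters as its structure-mean dose added uniformly.

    Total volume is conserved exactly (plan A's volume is carried through).
    """
    a, b = differential(dvh_a), differential(dvh_b)
    if abs(a.total_volume - b.total_volume) > 0.01 * max(a.total_volume, b.total_volume):
        raise CombinationError(
            f"structure volumes differ by more than 1%: {a.total_volume:.3f} vs "
            f"{b.total_volume:.3f} cm3"
        )
    vol_per_point = a.total_volume / n_points
    fractions = (np.arange(n_points) + 0.5) / n_points
    hot_volumes = fractions * a.total_volume
    da = np.array([dose_at_hot_volume(a, hv) for hv in hot_volumes])
    if mode == "rank":
        db = np.array([dose_at_hot_volume(b, hv * b.total_volume / a.total_volume) for hv in hot_volumes])
    elif mode == "uniform-background":
        db = np.full(n_points, mean_dose(b))
    else:
        raise ValueError(f"unknown addition mode {mode!r}")
    summed = da + db
    idx = np.floor(summed / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    bins = np.arange(counts.size) * bin_width
    return DVHCurve(bins, counts * vol_per_point, total_volume=a.total_volume)


def whole_treatment_metrics(
    pelvis_grid: DoseGrid,
    boost_grid: DoseGrid,
    masks: dict[str, StructureMask],
    target_name: str,
    oar_names: list[str],
    pelvis_scheme: FractionationScheme,
    boost_scheme: FractionationScheme,
    tumour: TissueRadiobiology,
    normal: TissueRadiobiology,
    lkb_params: dict[str, LKBParams],
    clonogen_density: float,
    boost_eq_scheme: FractionationScheme | None = None,
    boost_prescription: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    addition_mode: Literal["rank", "uniform-background"] = "rank",
    boost_masks: dict[str, StructureMask] | None = None,
) -> dict[str, dict[str, float]]:
    """Evaluate a pelvis + boost treatment on one structure set.

    Returns ``{structure: {metric: value}}`` with boost-only target coverage
    and conformity, OAR D_2cm3, and whole-treatment (EQD2-summed) TCP/NTCP.

    ``boost_eq_scheme`` is the acutely-fractionated regimen used for the
    radiobiological conversion of the boost DVH (e.g. the stated HDR
    equivalent of a PDR delivery); boost DVH doses are rescaled by the ratio
    of its total dose to the physically delivered total before the per-bin
    EQD2 map.

    ``boost_masks`` optionally overrides structure masks for the boost plan
    only (organs displaced by the applicator during an intracavitary
    session); overridden masks must keep the structure volume so the
    DVH-level plan sum stays well-defined.
    """
    eq = boost_eq_scheme or boost_scheme
    if eq.n_fractions is None:
        raise ValueError("boost radiobiology requires an acutely-fractionated (equivalent) scheme")
    prescription = boost_prescription if boost_prescription is not None else boost_scheme.total_dose
    dose_scale = eq.total_dose / boost_scheme.total_dose
    boost_masks = {**masks, **(boost_masks or {})}

    def combined_eqd2(name: str, tissue: TissueRadiobiology) -> DVHCurve:
        pelvis_dvh = compute_dvh(pelvis_grid, masks[name], bin_width)
        boost_dvh = compute_dvh(boost_grid, boost_masks[name], bin_width)
        pelvis_eq = dvh_to_eqd2(pelvis_dvh, pelvis_scheme.n_fractions, tissue)
        boost_phys = rescale_doses(boost_dvh, dose_scale) if dose_scale != 1.0 else boost_dvh
        boost_eq = dvh_to_eqd2(boost_phys, eq.n_fractions, tissue)
        return add_plans(pelvis_eq, boost_eq, bin_width=bin_width, mode=addition_mode)

    out: dict[str, dict[str, float]] = {}

    target = masks[target_name]
    boost_dvh = compute_dvh(boost_grid, target, bin_width)
    ci_in = conformity_inputs_from_grid(boost_grid, target, prescription)
    combined_t = combined_eqd2(target_name, tumour)
    out[target_name] = {
        "boost_d_max_gy": d_max(boost_dvh),
        "boost_d_min_gy": d_min(boost_dvh),
        "boost_v95_pct": volume_at_dose(boost_dvh, 95.0, "percent", prescription).percent,
        "boost_v85_pct": volume_at_dose(boost_dvh, 85.0, "percent", prescription).percent,
        "boost_ci": conformity_index(ci_in),
        "boost_coverage": coverage_fraction(ci_in),
        "boost_cn": conformation_number(ci_in),
        "whole_tcp": tcp_poisson(
            combined_t, tumour, dose_per_fraction=2.0, clonogen_density=clonogen_density
        ),
        "whole_mean_eqd2_gy": mean_dose(combined_t),
    }

    for name in oar_names:
        boost_oar = compute_dvh(boost_grid, boost_masks[name], bin_width)
        d2cc = dose_at_hot_volume(boost_oar, 2.0)
        row = {
            "boost_d2cm3_gy": d2cc,
            "boost_d2cm3_pct": 100.0 * d2cc / prescription,
        }
        if name in lkb_params:
            combined_o = combined_eqd2(name, normal)
            row["whole_ntcp"] = lkb_ntcp(combined_o, lkb_params[name])
        out[name] = row
    return out
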