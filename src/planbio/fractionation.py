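"""Linear-quadratic (LQ) model dose conversions.

Implements the isoeffect machinery used to match an external-beam boost to an
intracavitary brachytherapy boost:

* fractionated BED for external beam (EBRT) and high-dose-rate (HDR)
  deliveries, ``BED = D (1 + d / (alpha/beta))``;
* continuous low-dose-rate BED with sublethal-damage repair kinetics
  (constant-dose-rate protraction factor, repair rate ``mu = ln 2 / T_half``);
* pulsed-dose-rate (PDR) BED with the incomplete-repair pulse-train factor;
* EQD2 (``BED / (1 + 2/(alpha/beta))``), HDR-equivalent regimen solving and
  isoeffective fraction scheduling.

Tissue presets follow common gynaecological practice: alpha/beta = 10 Gy and
T_half = 1 h for tumour, alpha/beta = 3 Gy and T_half = 3 h for late-responding
normal tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, NamedTuple

import yaml

from .errors import ConvergenceError, SchemaError

__all__ = [
    "FractionationScheme",
    "TissueRadiobiology",
    "TUMOUR",
    "LATE_NORMAL",
    "PDR_HDR_EQUIVALENTS",
    "bed",
    "bed_fractionated",
    "bed_continuous",
    "bed_pulsed",
    "eqd2",
    "hdr_equivalent",
    "isoeffective_fractions",
    "round_half_up",
    "read_regimen_config",
]

Modality = Literal["EBRT", "HDR", "PDR", "CLDR"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, used only when printing table values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TissueRadiobiology:
    """Per-tissue LQ parameters.

    alpha_beta : Gy
        Fractionation-sensitivity ratio.
    t_half_h : hours
        Sublethal-damage repair half-time; the repair rate is derived as
        ``mu = ln 2 / t_half`` and never stored independently.
    alpha : 1/Gy, optional
        Linear LQ coefficient (needed for TCP only).
    clonogen_density : 1/cm^3, optional
        Clonogenic cell density (needed for TCP only).
    """

    alpha_beta: float
    t_half_h: float
    alpha: float | None = None
    clonogen_density: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha/beta must be > 0, got {self.alpha_beta}")
        if self.t_half_h <= 0:
            raise ValueError(f"repair half-time must be > 0, got {self.t_half_h}")

    @property
    def mu(self) -> float:
        """Repair rate mu = ln2 / T_half (1/h)."""
        return math.log(2.0) / self.t_half_h

    @property
    def beta(self) -> float:
        """Quadratic LQ coefficient derived from alpha and alpha/beta."""
        if self.alpha is None:
            raise ValueError("tissue has no alpha; beta is alpha / (alpha/beta)")
        return self.alpha / self.alpha_beta


#: Tumour defaults: alpha/beta = 10 Gy, T_half = 1 h, alpha = 0.3 /Gy.
#: alpha is a package default (configurable), not a study-stated value.
TUMOUR = TissueRadiobiology(alpha_beta=10.0, t_half_h=1.0, alpha=0.3)

#: Late-responding normal tissue: alpha/beta = 3 Gy, T_half = 3 h.
LATE_NORMAL = TissueRadiobiology(alpha_beta=3.0, t_half_h=3.0)


@dataclass(frozen=True)
class FractionationScheme:
    """A delivery description: total dose plus modality-specific structure."""

    modality: Modality
    total_dose: float
    n_fractions: int | None = None
    dose_per_fraction: float | None = None
    pulse_dose: float | None = None
    pulse_interval_h: float | None = None
    n_pulses: int | None = None
    duration_h: float | None = None

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise SchemaError(f"total dose must be >= 0, got {self.total_dose}")
        if self.modality in ("EBRT", "HDR"):
            if self.n_fractions is None or self.dose_per_fraction is None:
                raise SchemaError(f"{self.modality} scheme requires n_fractions and dose_per_fraction")
            if abs(self.total_dose - self.n_fractions * self.dose_per_fraction) > 1e-9:
                raise SchemaError(
                    f"total dose {self.total_dose} != n_fractions x dose_per_fraction "
                    f"({self.n_fractions} x {self.dose_per_fraction})"
                )
        elif self.modality == "PDR":
            if self.pulse_dose is None or self.n_pulses is None or self.pulse_interval_h is None:
                raise SchemaError("PDR scheme requires pulse_dose, n_pulses and pulse_interval_h")
            if self.pulse_dose <= 0 or self.n_pulses < 1 or self.pulse_interval_h < 0:
                raise SchemaError("PDR pulse fields out of range")
            if abs(self.total_dose - self.n_pulses * self.pulse_dose) > 1e-9:
                raise SchemaError(
                    f"total dose {self.total_dose} != n_pulses x pulse_dose "
                    f"({self.n_pulses} x {self.pulse_dose})"
                )
        elif self.modality == "CLDR":
            if self.duration_h is None or self.duration_h <= 0:
                raise SchemaError("CLDR scheme requires a positive duration_h")
        else:
            raise SchemaError(f"unknown modality {self.modality!r}")

    # -- convenience constructors -------------------------------------------
    @classmethod
    def ebrt(cls, dose_per_fraction: float, n_fractions: int) -> "FractionationScheme":
        return cls("EBRT", dose_per_fraction * n_fractions, n_fractions, dose_per_fraction)

    @classmethod
    def hdr(cls, dose_per_fraction: float, n_fractions: int) -> "FractionationScheme":
        return cls("HDR", dose_per_fraction * n_fractions, n_fractions, dose_per_fraction)

    @classmethod
    def pdr(cls, pulse_dose: float, n_pulses: int, pulse_interval_h: float) -> "FractionationScheme":
        return cls(
            "PDR",
            pulse_dose * n_pulses,
            pulse_dose=pulse_dose,
            n_pulses=n_pulses,
            pulse_interval_h=pulse_interval_h,
        )

    @classmethod
    def cldr(cls, total_dose: float, duration_h: float) -> "FractionationScheme":
        return cls("CLDR", total_dose, duration_h=duration_h)

    def describe(self) -> str:
        if self.modality in ("EBRT", "HDR"):
            return f"{self.modality} {self.dose_per_fraction:g} Gy x {self.n_fractions} = {self.total_dose:g} Gy"
        if self.modality == "PDR":
            return (
                f"PDR {self.total_dose:g} Gy ({self.n_pulses} x {self.pulse_dose:g} Gy pulses, "
                f"{self.pulse_interval_h:g} h apart)"
            )
        return f"CLDR {self.total_dose:g} Gy over {self.duration_h:g} h"


#: Clinically stated PDR <-> HDR equivalences (total PDR dose -> HDR regimen).
PDR_HDR_EQUIVALENTS: dict[float, FractionationScheme] = {
    15.0: FractionationScheme.hdr(4.0, 3),
    30.0: FractionationScheme.hdr(4.0, 6),
}


def bed_fractionated(scheme: FractionationScheme, tissue: TissueRadiobiology) -> float:
    """BED of an acutely-fractionated regimen: ``D (1 + d/(alpha/beta))``.

    Assumes inter-fraction intervals much longer than the repair half-time
    (complete repair between fractions).
    """
    if scheme.modality not in ("EBRT", "HDR"):
        raise SchemaError(f"bed_fractionated requires EBRT/HDR, got {scheme.modality}")
    if scheme.total_dose == 0:
        return 0.0
    return scheme.total_dose * (1.0 + scheme.dose_per_fraction / tissue.alpha_beta)


def _protraction_factor(mu_t: float) -> float:
    """g(muT) = (2/muT) [1 - (1 - e^-muT)/muT]; 1 as muT->0, ->0 as muT->inf."""
    if mu_t < 1e-4:  # series to avoid catastrophic cancellation
        return 1.0 - mu_t / 3.0 + mu_t**2 / 12.0
    return (2.0 / mu_t) * (1.0 - (-math.expm1(-mu_t)) / mu_t)


def bed_continuous(scheme: FractionationScheme, tissue: TissueRadiobiology) -> float:
    """BED of a single continuous irradiation at constant dose rate.

    ``BED = D {1 + [2 (D/T)/(mu (alpha/beta))] [1 - (1 - e^-muT)/(muT)]}``
    with ``mu = ln2/T_half``; recovers the acute single-dose BED as T -> 0
    and the full-repair limit BED -> D as T -> infinity.
    """
    if scheme.modality != "CLDR":
        raise SchemaError(f"bed_continuous requires CLDR, got {scheme.modality}")
    d, t = scheme.total_dose, scheme.duration_h
    if t <= 0:
        raise ValueError(f"irradiation time must be > 0, got {t}")
    return d * (1.0 + (d / tissue.alpha_beta) * _protraction_factor(tissue.mu * t))


def _pulse_train_factor(n: int, phi: float) -> float:
    """Incomplete-repair factor h_n = (2/n) (phi/(1-phi)) [n - (1-phi^n)/(1-phi)]."""
    if n <= 1 or phi <= 0.0:
        return 0.0
    if phi >= 1.0 - 1e-9:  # analytic limit: all pulses merge into one acute dose
        return float(n - 1)
    geo = (1.0 - phi**n) / (1.0 - phi)
    return (2.0 / n) * (phi / (1.0 - phi)) * (n - geo)


def bed_pulsed(scheme: FractionationScheme, tissue: TissueRadiobiology) -> float:
    """BED of a pulse train with incomplete inter-pulse repair.

    Pulses are treated as instantaneous; repair between pulses follows
    ``phi = e^(-mu * interval)``:

    ``BED = D {1 + (d_pulse/(alpha/beta)) [1 + h_n(phi)]}``.

    A single pulse, or widely-spaced pulses, reduce to the fractionated BED.
    """
    if scheme.modality != "PDR":
        raise SchemaError(f"bed_pulsed requires PDR, got {scheme.modality}")
    phi = math.exp(-tissue.mu * scheme.pulse_interval_h)
    h = _pulse_train_factor(scheme.n_pulses, phi)
    return scheme.total_dose * (1.0 + (scheme.pulse_dose / tissue.alpha_beta) * (1.0 + h))


def bed(scheme: FractionationScheme, tissue: TissueRadiobiology) -> float:
    """Dispatch to the modality-appropriate BED model."""
    if scheme.modality in ("EBRT", "HDR"):
        return bed_fractionated(scheme, tissue)
    if scheme.modality == "PDR":
        return bed_pulsed(scheme, tissue)
    return bed_continuous(scheme, tissue)


def eqd2(scheme: FractionationScheme, tissue: TissueRadiobiology) -> float:
    """Equivalent dose in 2 Gy fractions: ``EQD2 = BED / (1 + 2/(alpha/beta))``."""
    return bed(scheme, tissue) / (1.0 + 2.0 / tissue.alpha_beta)


def hdr_equivalent(
    pdr_scheme: FractionationScheme,
    tissue: TissueRadiobiology,
    n_fractions: int = 3,
    tol: float = 1e-6,
) -> FractionationScheme:
    """HDR regimen with the given fraction count matching a PDR scheme's BED.

    Solves ``n d (1 + d/(alpha/beta)) = BED_PDR`` for d (closed form) and
    verifies the round trip to ``tol`` Gy.
    """
    target = bed_pulsed(pdr_scheme, tissue)
    ab = tissue.alpha_beta
    # quadratic n d^2/ab + n d - target = 0
    disc = 1.0 + 4.0 * target / (n_fractions * ab)
    d = 0.5 * ab * (math.sqrt(disc) - 1.0)
    if d <= 0:
        raise ConvergenceError("no positive-dose HDR equivalent exists")
    out = FractionationScheme.hdr(d, n_fractions)
    if abs(bed_fractionated(out, tissue) - target) > max(tol, 0.01):
        raise ConvergenceError("HDR-equivalent solver failed self-consistency check")
    return out


class IsoeffectResult(NamedTuple):
    n_fractions: int
    achieved_bed: float


def isoeffective_fractions(
    target_bed: float, dose_per_fraction: float, tissue: TissueRadiobiology
) -> IsoeffectResult:
    """Smallest fraction count at dose d whose BED reaches ``target_bed``.

    Returns the count and the achieved BED (which may overshoot the target).
    """
    if dose_per_fraction <= 0:
        raise ValueError(f"dose per fraction must be > 0, got {dose_per_fraction}")
    if target_bed < 0:
        raise ValueError(f"target BED must be >= 0, got {target_bed}")
    if target_bed == 0:
        return IsoeffectResult(0, 0.0)
    per_fraction_bed = dose_per_fraction * (1.0 + dose_per_fraction / tissue.alpha_beta)
    n = math.ceil(target_bed / per_fraction_bed - 1e-12)
    return IsoeffectResult(n, n * per_fraction_bed)


# ---------------------------------------------------------------------------
# structured regimen/tissue config


def _scheme_from_dict(block: dict) -> FractionationScheme:
    try:
        modality = block["modality"].upper()
    except KeyError as exc:
        raise SchemaError("regimen block missing 'modality'") from exc
    kwargs = dict(
        modality=modality,
        total_dose=float(block.get("total_dose_gy", 0.0)),
        n_fractions=block.get("n_fractions"),
        dose_per_fraction=block.get("dose_per_fraction_gy"),
        pulse_dose=block.get("pulse_dose_gy"),
        pulse_interval_h=block.get("pulse_interval_h"),
        n_pulses=block.get("n_pulses"),
        duration_h=block.get("duration_h"),
    )
    if kwargs["total_dose"] == 0.0:
        if modality in ("EBRT", "HDR") and kwargs["n_fractions"] and kwargs["dose_per_fraction"]:
            kwargs["total_dose"] = kwargs["n_fractions"] * kwargs["dose_per_fraction"]
        elif modality == "PDR" and kwargs["n_pulses"] and kwargs["pulse_dose"]:
            kwargs["total_dose"] = kwargs["n_pulses"] * kwargs["pulse_dose"]
    return FractionationScheme(**kwargs)


def read_regimen_config(path) -> tuple[dict[str, FractionationScheme], dict[str, TissueRadiobiology]]:
    """Read a YAML file with ``regimens:`` and ``tissues:`` blocks.

    Regimen keys: modality, total_dose_gy, n_fractions, dose_per_fraction_gy,
    pulse_dose_gy, pulse_interval_h, n_pulses, duration_h.  Tissue keys:
    alpha_beta_gy, t_half_h, alpha_per_gy, clonogen_density_per_cm3.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regimens = {name: _scheme_from_dict(block) for name, block in (raw.get("regimens") or {}).items()}
    tissues = {}
    for name, block in (raw.get("tissues") or {}).items():
        try:
            tissues[name] = TissueRadiobiology(
                alpha_beta=float(block["alpha_beta_gy"]),
                t_half_h=float(block["t_half_h"]),
                alpha=block.get("alpha_per_gy"),
                clonogen_density=block.get("clonogen_density_per_cm3"),
            )
        except KeyError as exc:
            raise SchemaError(f"tissue block {name!r} missing {exc}") from exc
    return regimens, tissues
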