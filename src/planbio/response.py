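"""Radiobiological outcome models: Poisson TCP and LKB NTCP.

Tumour control probability follows the Poisson model on a differential DVH:
each bin contributes surviving clonogens ``N_i exp(-(alpha + beta d_i) D_i)``
and ``TCP = exp(-sum_i N_i S_i)``.

Normal-tissue complication probability follows the Lyman-Kutcher-Burman
pipeline: the DVH is reduced to a whole-organ equivalent uniform dose
``D_eff = (sum_i v_i D_i^(1/n))^n`` (power-law volume effect
``TD(v) = TD(1) v^-n``), then mapped through the probit dose-response
``NTCP = Phi((D_eff - TD50)/(m TD50))`` evaluated with the complementary
error function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .dvh import DVHCurve, d_max, differential
from .fractionation import TissueRadiobiology

__all__ = [
    "LKBParams",
    "RECTUM_PEETERS",
    "BLADDER_DEFAULT",
    "BOWEL_DEFAULT",
    "clonogen_number",
    "tcp_poisson",
    "kb_effective_dose",
    "lkb_ntcp",
    "LKBFitResult",
    "fit_lkb",
    "simulate_complications",
]


@dataclass(frozen=True)
class LKBParams:
    """Lyman model parameter triple.

    n : volume-effect exponent (0 = purely serial organ);
    m : probit slope parameter;
    td50 : whole-organ tolerance dose for 50% complication probability (Gy).
    """

    n: float
    m: float
    td50: float
    source: str = "user"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"volume exponent n must be >= 0, got {self.n}")
        if self.m <= 0:
            raise ValueError(f"slope m must be > 0, got {self.m}")
        if self.td50 <= 0:
            raise ValueError(f"TD50 must be > 0, got {self.td50}")


#: Rectum (late rectal bleeding): n=0.13, m=0.14, TD50=81 Gy.
RECTUM_PEETERS = LKBParams(n=0.13, m=0.14, td50=81.0, source="study")
#: Bladder and bowel triples are package defaults from the classical Lyman
#: parameter fits; they are NOT study-stated values and reports flag them.
BLADDER_DEFAULT = LKBParams(n=0.5, m=0.11, td50=80.0, source="package-default")
BOWEL_DEFAULT = LKBParams(n=0.15, m=0.16, td50=55.0, source="package-default")


def clonogen_number(volume_cm3: float, density_per_cm3: float) -> float:
    """N = clonogen density x volume."""
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be > 0, got {volume_cm3}")
    if density_per_cm3 < 0:
        raise ValueError(f"density must be >= 0, got {density_per_cm3}")
    return density_per_cm3 * volume_cm3


def tcp_poisson(
    dvh: DVHCurve,
    tissue: TissueRadiobiology,
    n_fractions: int | None = None,
    dose_per_fraction: float | None = None,
    clonogen_density: float | None = None,
) -> float:
    """Poisson TCP from a differential DVH.

    The per-bin dose per fraction is either the constant ``dose_per_fraction``
    (e.g. 2 Gy for an EQD2-domain DVH) or ``D_i / n_fractions`` when the bins
    share the fractionation of the plan.
    """
    if tissue.alpha is None:
        raise ValueError("tissue.alpha is required for TCP")
    density = clonogen_density if clonogen_density is not None else tissue.clonogen_density
    if density is None:
        raise ValueError("clonogen density is required for TCP")
    if (n_fractions is None) == (dose_per_fraction is None):
        raise ValueError("give exactly one of n_fractions or dose_per_fraction")
    diff = differential(dvh)
    doses = diff.dose_bins
    if dose_per_fraction is not None:
        if dose_per_fraction <= 0:
            raise ValueError("dose per fraction must be > 0")
        d_i = np.full_like(doses, dose_per_fraction)
    else:
        if n_fractions <= 0:
            raise ValueError("n_fractions must be > 0")
        d_i = doses / n_fractions
    alpha, beta = tissue.alpha, tissue.beta
    # log-survival per bin; exp underflows harmlessly to 0 for hot bins
    log_s = -(alpha + beta * d_i) * doses
    surviving = density * diff.volumes * np.exp(log_s)
    return float(np.exp(-surviving.sum()))


def kb_effective_dose(dvh: DVHCurve, n: float) -> float:
    """Kutcher-Burman equivalent uniform dose ``(sum v_i D_i^(1/n))^n``.

    ``n = 0`` returns D_max (the analytic limit) with a warning.
    """
    if n < 0:
        raise ValueError(f"volume exponent must be >= 0, got {n}")
    diff = differential(dvh)
    if n == 0:
        warnings.warn("n = 0: effective dose is the maximum dose", stacklevel=2)
        return d_max(diff)
    v = diff.fractional_volumes
    doses = diff.dose_bins
    # factor out the hottest dose for numerical headroom at small n
    occupied = v > 0
    dm = doses[occupied].max()
    if dm == 0:
        return 0.0
    ratio = doses[occupied] / dm
    return float(dm * np.sum(v[occupied] * ratio ** (1.0 / n)) ** n)


def lkb_ntcp(dvh: DVHCurve, params: LKBParams) -> float:
    """LKB NTCP of an EQD2-domain DVH.

    ``t = (D_eff - TD50)/(m TD50)``; ``NTCP = Phi(t)`` via erfc.
    """
    d_eff = kb_effective_dose(dvh, params.n)
    t = (d_eff - params.td50) / (params.m * params.td50)
    return float(0.5 * special.erfc(-t / np.sqrt(2.0)))


def _ntcp_from_deff(d_eff: np.ndarray, m: float, td50: float) -> np.ndarray:
    t = (d_eff - td50) / (m * td50)
    return 0.5 * special.erfc(-t / np.sqrt(2.0))


def simulate_complications(
    dvhs: Sequence[DVHCurve], params: LKBParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw one Bernoulli complication outcome per organ from the LKB model."""
    p = np.array([lkb_ntcp(dvh, params) for dvh in dvhs])
    return rng.random(p.size) < p


@dataclass(frozen=True)
class LKBFitResult:
    """Maximum-likelihood estimates of the Lyman slope and tolerance dose."""

    m: float
    td50: float
    n: float
    neg_log_likelihood: float
    n_organs: int
    converged: bool

    def summary(self) -> str:
        return (
            f"LKB ML fit on {self.n_organs} organs (n fixed at {self.n:g}):\n"
            f"  m    = {self.m:.4f}\n"
            f"  TD50 = {self.td50:.2f} Gy\n"
            f"  -logL = {self.neg_log_likelihood:.2f} (converged={self.converged})"
        )


def fit_lkb(
    dvhs: Sequence[DVHCurve],
    events: Sequence[bool],
    n: float,
    x0: tuple[float, float] = (0.2, 70.0),
) -> LKBFitResult:
    """Maximum-likelihood refit of (m, TD50) with the volume exponent fixed.

    Each organ contributes a Bernoulli likelihood at its Kutcher-Burman
    effective dose.  Nelder-Mead on the negative log-likelihood.
    """
    events = np.asarray(events, dtype=bool)
    if len(dvhs) != events.size:
        raise ValueError("one event flag per organ DVH is required")
    d_eff = np.array([kb_effective_dose(dvh, n) for dvh in dvhs])

    def nll(theta: np.ndarray) -> float:
        m, td50 = theta
        if m <= 1e-4 or td50 <= 1.0:
            return 1e12
        p = np.clip(_ntcp_from_deff(d_eff, m, td50), 1e-12, 1.0 - 1e-12)
        return float(-np.sum(np.where(events, np.log(p), np.log1p(-p))))

    res = optimize.minimize(nll, x0=np.asarray(x0), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    m_hat, td50_hat = res.x
    return LKBFitResult(
        m=float(m_hat),
        td50=float(td50_hat),
        n=float(n),
        neg_log_likelihood=float(res.fun),
        n_organs=int(events.size),
        converged=bool(res.success),
    )
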