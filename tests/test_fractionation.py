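"""LQ-model conversions: regimen table values and dose-rate model oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from planbio.errors import SchemaError
from planbio.fractionation import (
    LATE_NORMAL,
    PDR_HDR_EQUIVALENTS,
    TUMOUR,
    FractionationScheme,
    TissueRadiobiology,
    bed_continuous,
    bed_fractionated,
    bed_pulsed,
    eqd2,
    hdr_equivalent,
    isoeffective_fractions,
    read_regimen_config,
    round_half_up,
)


class TestBedFractionated:
    # (dose/fraction, n, BED at alpha/beta = 10) — the boost conversion grid
    @pytest.mark.parametrize(
        "d, n, expected",
        [
            (5.0, 3, 22.5),
            (1.8, 11, 23.4),
            (4.0, 3, 16.8),
            (1.8, 8, 17.0),
            (4.0, 6, 33.6),
            (1.8, 16, 34.0),
        ],
    )
    def test_boost_regimen_grid(self, d, n, expected):
        scheme = FractionationScheme.hdr(d, n)
        assert round_half_up(bed_fractionated(scheme, TUMOUR)) == expected

    def test_zero_dose(self):
        assert bed_fractionated(FractionationScheme.hdr(0.0, 3), TUMOUR) == 0.0

    def test_bed_at_least_physical_dose(self):
        for d in [0.5, 2.0, 8.0]:
            scheme = FractionationScheme.ebrt(d, 10)
            assert bed_fractionated(scheme, TUMOUR) >= scheme.total_dose


class TestEqd2:
    @pytest.mark.parametrize(
        "d, n, expected",
        [
            (5.0, 3, 18.8),
            (1.8, 11, 19.5),
            (4.0, 3, 14.0),  # the value implied by BED 16.8 Gy
            (1.8, 8, 14.2),
            (4.0, 6, 28.0),
            (1.8, 16, 28.3),
        ],
    )
    def test_boost_eqd2_grid(self, d, n, expected):
        assert round_half_up(eqd2(FractionationScheme.hdr(d, n), TUMOUR)) == expected

    def test_identity_at_2gy_per_fraction(self):
        for n in [1, 10, 25]:
            scheme = FractionationScheme.ebrt(2.0, n)
            assert eqd2(scheme, TUMOUR) == pytest.approx(scheme.total_dose)
            assert eqd2(scheme, LATE_NORMAL) == pytest.approx(scheme.total_dose)


class TestBedContinuous:
    def test_acute_limit(self):
        """T -> 0 recovers the single acute dose BED = D(1 + D/(alpha/beta))."""
        t = TUMOUR.t_half_h / 1e4
        scheme = FractionationScheme.cldr(15.0, t)
        acute = 15.0 * (1 + 15.0 / TUMOUR.alpha_beta)
        assert bed_continuous(scheme, TUMOUR) == pytest.approx(acute, rel=1e-3)

    def test_full_repair_limit(self):
        scheme = FractionationScheme.cldr(15.0, 1e4 * TUMOUR.t_half_h)
        assert bed_continuous(scheme, TUMOUR) == pytest.approx(15.0, rel=1e-3)

    def test_lea_catcheside_double_integral_oracle(self):
        """Protraction factor vs numeric double integral over the dose-rate history."""
        d_tot, t_irr = 15.0, 24.0
        mu = TUMOUR.mu
        nt = 4000
        times = (np.arange(nt) + 0.5) * (t_irr / nt)
        dt = t_irr / nt
        # G = (2/T^2) int_0^T int_0^t exp(-mu (t - t')) dt' dt for constant rate
        diff = times[:, None] - times[None, :]
        g = 2.0 * np.sum(np.tril(np.exp(-mu * diff), k=-1)) * dt**2 / t_irr**2
        oracle = d_tot * (1 + (d_tot / TUMOUR.alpha_beta) * g)
        got = bed_continuous(FractionationScheme.cldr(d_tot, t_irr), TUMOUR)
        assert got == pytest.approx(oracle, rel=2e-3)

    def test_monotone_decreasing_in_duration(self):
        beds = [
            bed_continuous(FractionationScheme.cldr(15.0, t), TUMOUR)
            for t in [0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a > b for a, b in zip(beds, beds[1:]))
        assert all(15.0 <= b <= 15.0 * (1 + 1.5) + 1e-9 for b in beds)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(SchemaError):
            FractionationScheme.cldr(15.0, 0.0)


def pairwise_repair_oracle(doses, interval, tissue):
    """O(n^2) pairwise incomplete-repair BED: D + (1/ab) sum_ij d_i d_j phi^|i-j|."""
    phi = math.exp(-tissue.mu * interval)
    d = np.asarray(doses)
    n = d.size
    ij = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return d.sum() + np.sum(np.outer(d, d) * phi**ij) / tissue.alpha_beta


class TestBedPulsed:
    def test_single_pulse_equals_fraction(self):
        pdr = FractionationScheme.pdr(5.0, 1, 1.0)
        hdr = FractionationScheme.hdr(5.0, 1)
        assert bed_pulsed(pdr, TUMOUR) == pytest.approx(bed_fractionated(hdr, TUMOUR))

    def test_wide_spacing_equals_fractionated(self):
        pdr = FractionationScheme.pdr(0.5, 30, 1e6)
        hdr = FractionationScheme.hdr(0.5, 30)
        assert bed_pulsed(pdr, TUMOUR) == pytest.approx(bed_fractionated(hdr, TUMOUR), rel=1e-9)

    def test_zero_interval_is_single_acute_dose(self):
        pdr = FractionationScheme.pdr(0.5, 30, 0.0)
        assert bed_pulsed(pdr, TUMOUR) == pytest.approx(15.0 * (1 + 15.0 / 10.0))

    def test_hourly_half_gray_train_oracle(self):
        pdr = FractionationScheme.pdr(0.5, 30, 1.0)
        oracle = pairwise_repair_oracle(np.full(30, 0.5), 1.0, TUMOUR)
        assert bed_pulsed(pdr, TUMOUR) == pytest.approx(oracle, rel=1e-12)

    @given(
        n=st.integers(1, 200),
        pulse=st.floats(0.1, 5.0),
        interval=st.floats(0.0, 12.0),
        t_half=st.floats(0.25, 5.0),
    )
    def test_closed_form_matches_pairwise_oracle(self, n, pulse, interval, t_half):
        tissue = TissueRadiobiology(alpha_beta=10.0, t_half_h=t_half)
        pdr = FractionationScheme.pdr(pulse, n, interval)
        oracle = pairwise_repair_oracle(np.full(n, pulse), interval, tissue)
        assert bed_pulsed(pdr, tissue) == pytest.approx(oracle, rel=1e-9)

    def test_missing_pulse_fields_rejected(self):
        with pytest.raises(SchemaError):
            FractionationScheme("PDR", total_dose=15.0)


class TestHdrEquivalent:
    def test_stated_preset_pairs(self):
        """The clinically stated equivalences used for the three boost groups."""
        assert PDR_HDR_EQUIVALENTS[15.0].describe() == "HDR 4 Gy x 3 = 12 Gy"
        assert PDR_HDR_EQUIVALENTS[30.0].describe() == "HDR 4 Gy x 6 = 24 Gy"
        assert bed_fractionated(PDR_HDR_EQUIVALENTS[15.0], TUMOUR) == pytest.approx(16.8)
        assert bed_fractionated(PDR_HDR_EQUIVALENTS[30.0], TUMOUR) == pytest.approx(33.6)

    def test_solver_self_consistency(self):
        pdr = FractionationScheme.pdr(0.5, 30, 1.0)
        out = hdr_equivalent(pdr, TUMOUR, n_fractions=3)
        assert abs(bed_fractionated(out, TUMOUR) - bed_pulsed(pdr, TUMOUR)) < 0.01

    def test_degenerate_pdr_returns_input_doses(self):
        """A PDR train with huge intervals is already an HDR regimen."""
        pdr = FractionationScheme.pdr(4.0, 3, 1e6)
        out = hdr_equivalent(pdr, TUMOUR, n_fractions=3)
        assert out.dose_per_fraction == pytest.approx(4.0, rel=1e-6)


class TestIsoeffectiveFractions:
    @pytest.mark.parametrize(
        "target, expected_n, expected_bed",
        [(22.5, 11, 23.4), (16.8, 8, 17.0), (33.6, 16, 34.0)],
    )
    def test_boost_scheduling(self, target, expected_n, expected_bed):
        res = isoeffective_fractions(target, 1.8, TUMOUR)
        assert res.n_fractions == expected_n
        assert round_half_up(res.achieved_bed) == expected_bed

    def test_zero_target(self):
        assert isoeffective_fractions(0.0, 1.8, TUMOUR).n_fractions == 0

    def test_exact_multiple_not_overshot(self):
        per_fx = 2.0 * (1 + 2.0 / 10.0)
        assert isoeffective_fractions(5 * per_fx, 2.0, TUMOUR).n_fractions == 5


class TestSchemesAndConfig:
    def test_total_dose_consistency_enforced(self):
        with pytest.raises(SchemaError):
            FractionationScheme("HDR", total_dose=14.0, n_fractions=3, dose_per_fraction=5.0)

    def test_tissue_validation(self):
        with pytest.raises(ValueError):
            TissueRadiobiology(alpha_beta=0.0, t_half_h=1.0)
        with pytest.raises(ValueError):
            TissueRadiobiology(alpha_beta=10.0, t_half_h=0.0)

    def test_mu_is_ln2_over_thalf(self):
        t = TissueRadiobiology(alpha_beta=3.0, t_half_h=3.0)
        assert t.mu == pytest.approx(math.log(2) / 3.0)

    def test_regimen_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "regimens.yaml"
        cfg.write_text(
            "regimens:\n"
            "  hdr_boost: {modality: HDR, n_fractions: 3, dose_per_fraction_gy: 5.0}\n"
            "  pdr_boost: {modality: PDR, pulse_dose_gy: 0.5, n_pulses: 30, pulse_interval_h: 1.0}\n"
            "tissues:\n"
            "  tumour: {alpha_beta_gy: 10.0, t_half_h: 1.0, alpha_per_gy: 0.3}\n"
        )
        regimens, tissues = read_regimen_config(cfg)
        assert regimens["hdr_boost"].total_dose == pytest.approx(15.0)
        assert regimens["pdr_boost"].n_pulses == 30
        assert tissues["tumour"].alpha == pytest.approx(0.3)
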