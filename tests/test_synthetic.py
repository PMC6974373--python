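"""Phantom geometry, dose generators and cohort reproducibility."""

import filecmp

import numpy as np
import pytest

from planbio.dvh import compute_dvh, volume_at_dose
from planbio.errors import GeometryError
from planbio.grids import DoseGrid
from planbio.synthetic import (
    PhantomSpec,
    SourceSet,
    dose_box_ebrt,
    dose_brachy,
    dose_conformal_imrt,
    generate_cohort,
    generate_phantom,
    write_cohort,
)


class TestGeneratePhantom:
    def test_boost_volume_in_cohort_range(self, phantom):
        grid = phantom.empty_grid(np.zeros(phantom.shape))
        v = phantom.masks["BOOST_ICBRT"].volume_cm3(grid)
        assert 11.99 <= v <= 87.60

    def test_determinism(self):
        a = generate_phantom(PhantomSpec(seed=7))
        b = generate_phantom(PhantomSpec(seed=7))
        for name in a.masks:
            np.testing.assert_array_equal(a.masks[name].voxels, b.masks[name].voxels)

    def test_margin_ordering_strict_containment(self, phantom):
        icbrt = phantom.masks["BOOST_ICBRT"].voxels
        imrt = phantom.masks["BOOST_IMRT"].voxels
        assert np.all(imrt[icbrt])
        assert imrt.sum() > icbrt.sum()

    def test_displaced_masks_preserve_volume(self, phantom):
        for name, mask in phantom.brachy_masks.items():
            assert mask.voxel_count() == phantom.masks[name].voxel_count()

    def test_volume_statistics_across_seeds(self):
        """Cohort-mean boost volumes stay near the emulated study's ranges."""
        icbrt, imrt, pelvis = [], [], []
        for seed in range(60):
            ph = generate_phantom(PhantomSpec(seed=seed))
            g = ph.empty_grid(np.zeros(ph.shape))
            icbrt.append(ph.masks["BOOST_ICBRT"].volume_cm3(g))
            imrt.append(ph.masks["BOOST_IMRT"].volume_cm3(g))
            pelvis.append(ph.masks["PTV_pelvis"].volume_cm3(g))
        assert abs(np.mean(icbrt) - 37.04) <= 2 * 20.25
        assert abs(np.mean(imrt) - 94.51) <= 2 * 60.41
        assert abs(np.mean(pelvis) - 1291.29) <= 2 * 184.26
        assert np.mean(imrt) > np.mean(icbrt)

    def test_too_small_grid_raises(self):
        with pytest.raises(GeometryError):
            generate_phantom(PhantomSpec(shape=(16, 16, 16), seed=0))


class TestSourceKernel:
    def test_inverse_square_single_source(self):
        s = SourceSet(positions=[[0.0, 0.0, 0.0]], weights=[1.0])
        d10 = s.dose_at(np.array([10.0, 0.0, 0.0]))
        d20 = s.dose_at(np.array([20.0, 0.0, 0.0]))
        assert d20 / d10 == pytest.approx(0.25, rel=1e-12)

    def test_applicator_lateral_gradient(self, phantom):
        """~200% at 10 mm falling to 100% at 20 mm on the point-A axis."""
        z = phantom.prescription_point[2]
        d10 = float(phantom.sources.dose_at(np.array([10.0, 0.0, z])))
        d20 = float(phantom.sources.dose_at(np.array([20.0, 0.0, z])))
        assert d10 / d20 == pytest.approx(2.0, rel=0.10)

    def test_superposition(self, phantom):
        src = phantom.sources
        parts = [
            SourceSet(positions=[p], weights=[w])
            for p, w in zip(src.positions, src.weights)
        ]
        pts = np.array([[12.0, 5.0, 0.0], [30.0, -10.0, 20.0]])
        total = sum(s.dose_at(pts) for s in parts)
        np.testing.assert_allclose(src.dose_at(pts), total, rtol=1e-12)

    def test_attenuation_steepens_falloff(self):
        plain = SourceSet(positions=[[0, 0, 0]], weights=[1.0])
        att = SourceSet(positions=[[0, 0, 0]], weights=[1.0], attenuation_per_mm=0.01)
        p = np.array([30.0, 0.0, 0.0])
        assert att.dose_at(p) < plain.dose_at(p)


class TestDoseGenerators:
    def test_box_covers_ptv(self, phantom):
        grid = dose_box_ebrt(phantom, 45.0)
        dvh = compute_dvh(grid, phantom.masks["PTV_pelvis"])
        assert volume_at_dose(dvh, 95.0, "percent", 45.0).percent >= 95.0

    def test_box_centre_near_prescription(self, phantom):
        grid = dose_box_ebrt(phantom, 45.0)
        centre = tuple(n // 2 for n in phantom.shape)
        assert grid.values[centre] == pytest.approx(45.0, rel=0.04)

    def test_box_out_of_field_low(self, phantom):
        grid = dose_box_ebrt(phantom, 45.0)
        assert grid.values[0, 0, 0] < 0.05 * 45.0

    def test_brachy_normalised_at_prescription_point(self, phantom):
        grid = dose_brachy(phantom, 15.0)
        # the prescription point lies near a voxel centre; check the nearest voxel
        x, y, z = phantom.voxel_centres()
        px, py, pz = phantom.prescription_point
        idx = np.unravel_index(
            np.argmin((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2), phantom.shape
        )
        assert grid.values[idx] == pytest.approx(15.0, rel=0.35)

    def test_brachy_cap(self, phantom):
        grid = dose_brachy(phantom, 15.0, cap_factor=10.0)
        assert grid.values.max() <= 150.0 + 1e-9

    def test_imrt_covers_target(self, phantom):
        grid = dose_conformal_imrt(phantom, "BOOST_IMRT", 19.8)
        dvh = compute_dvh(grid, phantom.masks["BOOST_IMRT"])
        assert volume_at_dose(dvh, 95.0, "percent", 19.8).percent == pytest.approx(100.0)

    def test_imrt_beats_brachy_conformation_on_same_target(self, phantom):
        from planbio.conformity import conformation_number, conformity_inputs_from_grid

        target = phantom.masks["BOOST_ICBRT"]
        br = dose_brachy(phantom, 15.0)
        im = dose_conformal_imrt(phantom, target, 15.0)
        cn_br = conformation_number(conformity_inputs_from_grid(br, target, 15.0))
        cn_im = conformation_number(conformity_inputs_from_grid(im, target, 15.0))
        assert cn_im > cn_br

    def test_imrt_tight_falloff_limit(self, phantom):
        """Vanishing falloff and offset make the prescription isodose hug the target."""
        from planbio.conformity import conformity_index, conformity_inputs_from_grid

        target = phantom.masks["BOOST_IMRT"]
        grid = dose_conformal_imrt(phantom, target, 19.8, falloff_mm=1e-6, penumbra_offset_mm=0.0)
        ci = conformity_index(conformity_inputs_from_grid(grid, target, 19.8))
        assert ci == pytest.approx(1.0, abs=1e-6)

    def test_grids_finite_nonnegative(self, phantom):
        for grid in [
            dose_box_ebrt(phantom, 45.0),
            dose_brachy(phantom, 15.0),
            dose_conformal_imrt(phantom, "BOOST_IMRT", 19.8),
        ]:
            assert np.all(np.isfinite(grid.values))
            assert np.all(grid.values >= 0)


class TestCohort:
    def test_equal_thirds_assignment(self, cohort15):
        groups = [p.group for p in cohort15.patients]
        assert groups.count("I") == groups.count("II") == groups.count("III") == 5

    def test_regimens_by_group(self, cohort15):
        for p in cohort15.patients:
            if p.group == "I":
                assert p.schemes["icbrt"].modality == "HDR"
                assert p.schemes["imrt_boost"].n_fractions == 11
                assert p.clonogen_density == 1e5
            elif p.group == "II":
                assert p.schemes["icbrt"].modality == "PDR"
                assert p.schemes["icbrt"].total_dose == pytest.approx(15.0)
                assert p.schemes["imrt_boost"].n_fractions == 8
            else:
                assert p.schemes["icbrt"].modality == "PDR"
                assert p.schemes["icbrt"].total_dose in (15.0, 30.0)
                assert p.schemes["imrt_boost"].n_fractions in (8, 16)
                assert p.clonogen_density == 1e7

    def test_cohort_csv_outputs_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            write_cohort(generate_cohort(n_patients=2, seed=3), out)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert filecmp.cmp(a / f, b / f, shallow=False), f
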