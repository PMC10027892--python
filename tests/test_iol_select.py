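"""SRK/T formula, toric lens construction, catalogue selection and the
method-comparison utilities."""

import math

import numpy as np
import pytest

from rtiol.eye_model import (CornealModel, EyeBiometry, PseudophakicEye,
                             ZernikeSagSurface, estimated_lens_position)
from rtiol.image_quality import VsotfEngine
from rtiol.iol_select import (ComparisonRecord, IOLCatalogue, build_iol,
                              compare_srkt, paired_ttest, select_iol,
                              srkt_power, tolerance_defocus,
                              tolerance_rotation)
from rtiol.raytrace import WavefrontMap, trace_pseudophakic
from rtiol.rto import optimize_target
from rtiol.synth_corneas import generate_group
from rtiol.zernike import ZernikeExpansion, zernike_to_powervector


def srkt_oracle(k, al, a_const=118.6):
    """Independent step-by-step transcription of the published SRK/T
    emmetropia formula."""
    r = 337.5 / k
    lcor = al if al <= 24.2 else -3.446 + 1.715 * al - 0.0237 * al ** 2
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    h = r - math.sqrt(max(r * r - cw * cw / 4.0, 0.0))
    acd_const = 0.62467 * a_const - 68.747
    acd = h + acd_const - 3.336
    lopt = al + 0.65696 - 0.02029 * al
    na, ncm1 = 1.336, 0.333
    return (1000.0 * na * (na * r - ncm1 * lopt)
            / ((lopt - acd) * (na * r - ncm1 * acd)))


class TestSrkt:
    def test_matches_oracle_on_grid(self):
        for k in np.linspace(38.0, 50.0, 10):
            for al in np.linspace(21.0, 27.0, 10):
                assert srkt_power(k, al) == pytest.approx(
                    srkt_oracle(k, al), abs=0.01)

    def test_longer_eye_needs_less_power(self):
        powers = [srkt_power(44.0, al) for al in np.linspace(21, 30, 12)]
        assert np.all(np.diff(powers) < 0)

    def test_a_constant_sensitivity(self):
        d = srkt_power(44.0, 23.65, 119.6) - srkt_power(44.0, 23.65, 118.6)
        d_oracle = srkt_oracle(44.0, 23.65, 119.6) - srkt_oracle(44.0, 23.65)
        assert d == pytest.approx(d_oracle, abs=0.01)
        assert 0.8 < d < 1.4        # roughly one dioptre per A-constant unit

    def test_myopic_target_raises_power(self):
        assert srkt_power(44.0, 23.65, target_refraction=-1.0) > \
            srkt_power(44.0, 23.65)

    def test_range_check(self):
        with pytest.raises(ValueError):
            srkt_power(44.0, 50.0)


class TestBuildIol:
    def test_spherical_label_contract(self):
        iol = build_iol(20.0, 0.0)
        p1, p2 = iol.meridian_powers()
        assert p1 == pytest.approx(20.0, abs=0.05)
        assert p2 == pytest.approx(20.0, abs=0.05)
        assert iol.front_curvature == pytest.approx(-iol.back_curvature_flat,
                                                    rel=1e-9)

    def test_toric_meridian_difference(self):
        iol = build_iol(20.0, 3.0, 90.0)
        flat, steep = iol.meridian_powers()
        assert steep - flat == pytest.approx(3.0, abs=0.05)

    def test_axis_mod_180(self):
        a = build_iol(18.0, 2.0, 30.0)
        b = build_iol(18.0, 2.0, 210.0)
        assert a.axis == b.axis
        fa, ba = a.surfaces(elp=4.5)
        fb, bb = b.surfaces(elp=4.5)
        x, y = 1.3, -0.6
        assert ba.sag(x, y) == pytest.approx(bb.sag(x, y), abs=1e-12)

    def test_negative_cylinder_rejected(self):
        with pytest.raises(ValueError):
            build_iol(20.0, -1.0)


class TestCatalogue:
    def test_grids(self):
        cat = IOLCatalogue()
        assert cat.spheres()[0] == 1.0 and cat.spheres()[-1] == 35.0
        assert cat.cylinders()[0] == 0.0 and cat.cylinders()[1] == 1.0
        assert cat.has(20.0, 0.0) and cat.has(20.5, 3.0)
        assert not cat.has(20.25, 0.0) and not cat.has(20.0, 11.0)

    def test_csv_roundtrip(self, tmp_path):
        cat = IOLCatalogue(sphere_min=5.0, sphere_max=30.0,
                           cylinder_min=1.0, cylinder_max=6.0)
        f = tmp_path / "catalogue.csv"
        cat.to_csv(f)
        back = IOLCatalogue.from_csv(f)
        assert back == cat


@pytest.fixture(scope="module")
def engine():
    return VsotfEngine(80, 2, pupil_px=48)


@pytest.fixture(scope="module")
def normal_eye():
    return generate_group(0, 1, seed=9)[0]


class TestSelect:
    def test_normal_eye_near_plano_residual(self, engine, normal_eye):
        e = normal_eye
        r = optimize_target(e.wavefront, engine)
        sel = select_iol(r, e.cornea, e.biometry,
                         k_mean=(e.k1 + e.k2) / 2, engine=engine)
        assert sel.available
        for comp in (sel.residual.M - r.optimal_pv.M,
                     sel.residual.J0 - r.optimal_pv.J0,
                     sel.residual.J45 - r.optimal_pv.J45):
            assert abs(comp) < 0.25
        assert sel.vsotf_final is not None and sel.vsotf_final > 0

    def test_extreme_cylinder_not_available(self, engine, normal_eye):
        e = normal_eye
        r = optimize_target(e.wavefront, engine)
        # a catalogue without toric lenses and a coarse sphere grid cannot
        # serve an astigmatic target
        cat = IOLCatalogue(sphere_min=1.0, sphere_max=5.0,
                           cylinder_min=1.0, cylinder_max=1.0)
        sel = select_iol(r, e.cornea, e.biometry, cat,
                         k_mean=(e.k1 + e.k2) / 2, engine=engine)
        assert not sel.available
        assert sel.mismatch > sel.tolerance


class TestTolerances:
    def test_defocus_loss_symmetric_for_even_wavefront(self, engine):
        w = WavefrontMap(ZernikeExpansion({}, 2.0))
        lp, lm = tolerance_defocus(w, engine)
        assert lp == pytest.approx(lm, abs=1e-6)
        assert lp > 0

    def test_losses_nonnegative_at_peak(self, engine, normal_eye):
        # the optimized corneal-stage residual sits at the through-focus
        # peak (up to the 0.25 D grid), so +/-0.5 D can only degrade
        from rtiol.rto import apply_correction
        from rtiol.zernike import powervector_to_sphcyl
        e = normal_eye
        r = optimize_target(e.wavefront, engine)
        resid = apply_correction(e.wavefront,
                                 powervector_to_sphcyl(r.correction_pv))
        lp, lm = tolerance_defocus(resid, engine)
        assert lp > -0.005 and lm > -0.005
        assert max(lp, lm) > 0

    def test_rotation_spherical_iol_is_free(self, engine, normal_eye):
        e = normal_eye
        bio = e.biometry
        eye = PseudophakicEye(e.cornea, build_iol(20.0, 0.0),
                              estimated_lens_position(bio), bio.axial_length)
        assert tolerance_rotation(eye, engine) == (0.0, 0.0)

    def test_rotation_symmetric_for_pure_toric_residual(self, engine):
        cornea = CornealModel(ZernikeSagSurface(1 / 7.8, aperture_radius=3.25),
                              ZernikeSagSurface(1 / 6.5, aperture_radius=3.25))
        bio = EyeBiometry(3.1, 4.5, 23.8)
        eye = PseudophakicEye(cornea, build_iol(20.0, 2.0, 45.0),
                              estimated_lens_position(bio), bio.axial_length)
        lp, lm = tolerance_rotation(eye, engine)
        assert lp == pytest.approx(lm, abs=5e-3)


class TestCompare:
    def test_identical_methods_agree_fully(self):
        recs = [ComparisonRecord(i, 21.0, 0.0, 0.0, 21.0, 0.0, -0.5, True)
                for i in range(5)]
        out = compare_srkt(recs)
        assert out["pct_within_half_D"] == 100.0
        assert out["n_not_available"] == 0

    def test_single_record_arithmetic(self):
        r = ComparisonRecord("e", 22.0, 0.0, 0.0, 21.0, 1.0, -1.0, True)
        assert not r.agreement_within_half_D
        out = compare_srkt([r])
        assert out["pct_within_half_D"] == 0.0
        assert out["pct_power_gt_3D"] == 0.0

    def test_not_available_excluded(self):
        recs = [ComparisonRecord(0, 21.0, 0, 0, 21.0, 0.0, -0.5, True),
                ComparisonRecord(1, math.nan, math.nan, math.nan, 20.0,
                                 math.nan, -6.0, False)]
        out = compare_srkt(recs)
        assert out["n_available"] == 1 and out["n_not_available"] == 1
        assert out["pct_within_half_D"] == 100.0

    def test_paired_ttest(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 0.05, 25)
        t, p = paired_ttest(a + 0.05, a)
        assert p < 0.05 and t > 0
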