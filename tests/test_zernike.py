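"""Zernike machinery: indexing, orthonormality, fitting, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtiol.zernike import (PowerVector, SpheroCylinder, ZernikeExpansion,
                           design_matrix, evaluate, fit, nm_modes, n_terms,
                           noll_index, noll_nm, osa_index, osa_nm,
                           osa_noll_convert, powervector_to_sphcyl,
                           powervector_to_zernike, rms_hoa,
                           sphcyl_to_powervector, sphcyl_to_zernike,
                           zernike_mode, zernike_to_powervector)


def _noll_order_oracle(max_order):
    """Independent enumeration of the Noll ordering from its published
    rules: modes sorted by n, then |m|; within a +/-|m| pair the even
    index goes to the cosine (m > 0) mode."""
    order = {}
    j = 1
    for n in range(max_order + 1):
        for am in sorted({abs(m) for m in range(-n, n + 1, 2)}):
            if am == 0:
                order[j] = (n, 0)
                j += 1
            else:
                if j % 2 == 0:
                    order[j], order[j + 1] = (n, am), (n, -am)
                else:
                    order[j], order[j + 1] = (n, -am), (n, am)
                j += 2
    return order


class TestIndexing:
    def test_term_count_6th_order(self):
        assert n_terms(6) == 28
        assert len(nm_modes(6)) == 28

    @pytest.mark.parametrize("osa_j,noll_j", [(0, 1), (4, 4), (12, 11)])
    def test_known_modes(self, osa_j, noll_j):
        assert osa_noll_convert(osa_j, "osa") == noll_j
        assert osa_noll_convert(noll_j, "noll") == osa_j

    def test_matches_enumeration_oracle(self):
        oracle = _noll_order_oracle(6)
        for j, (n, m) in oracle.items():
            assert noll_nm(j) == (n, m)
            assert noll_index(n, m) == j

    def test_involution_and_bijection(self):
        noll_seen = set()
        for j in range(n_terms(6)):
            jn = osa_noll_convert(j, "osa")
            assert osa_noll_convert(jn, "noll") == j
            noll_seen.add(jn)
        assert noll_seen == set(range(1, 29))

    def test_invalid_indices_raise(self):
        with pytest.raises(ValueError, match="OSA"):
            osa_noll_convert(-1, "osa")
        with pytest.raises(ValueError, match="Noll"):
            osa_noll_convert(0, "noll")
        with pytest.raises(ValueError):
            osa_noll_convert(3, "fringe")


class TestEvaluation:
    def test_piston_constant(self):
        e = ZernikeExpansion({(0, 0): 1.0}, 2.0)
        pts = np.array([0.0, 0.3, -0.5]), np.array([0.0, 0.4, 0.2])
        assert np.allclose(evaluate(e, *pts), 1.0)

    def test_outside_disk_masked(self):
        e = ZernikeExpansion({(2, 0): 1.0}, 2.0)
        vals = evaluate(e, np.array([0.5, 1.5]), np.array([0.0, 0.0]))
        assert np.isfinite(vals[0]) and np.isnan(vals[1])

    def test_orthonormality_quadrature(self):
        ax = np.linspace(-1, 1, 401)
        xx, yy = np.meshgrid(ax, ax)
        inside = xx ** 2 + yy ** 2 <= 1
        rho, th = np.hypot(xx[inside], yy[inside]), np.arctan2(yy[inside],
                                                               xx[inside])
        area_per_pt = 1.0 / inside.sum()
        modes = [(2, 0), (4, 0), (3, -1), (3, 3), (2, 2)]
        for i, (n1, m1) in enumerate(modes):
            z1 = zernike_mode(n1, m1, rho, th)
            for n2, m2 in modes[i:]:
                z2 = zernike_mode(n2, m2, rho, th)
                ip = np.sum(z1 * z2) * area_per_pt
                expected = 1.0 if (n1, m1) == (n2, m2) else 0.0
                assert ip == pytest.approx(expected, abs=5e-3)


class TestFit:
    def grid(self, r=2.0, n=64):
        ax = np.linspace(-r, r, n)
        xx, yy = np.meshgrid(ax, ax)
        keep = np.hypot(xx, yy) <= r
        return xx[keep], yy[keep]

    def test_recovers_own_basis(self):
        x, y = self.grid()
        truth = ZernikeExpansion({(3, -1): 0.5}, 2.0)
        vals = evaluate(truth, x / 2.0, y / 2.0)
        e = fit(vals, x, y, 6, 2.0)
        assert e.get(3, -1) == pytest.approx(0.5, abs=1e-10)
        others = [v for k, v in e.coefficients.items() if k != (3, -1)]
        assert np.max(np.abs(others)) < 1e-10

    def test_paraxial_defocus_map(self):
        # W = M r^2 rho^2 / 2 with M = 1 D, r = 2 mm -> c(2,0) = r^2/(4 sqrt 3)
        x, y = self.grid()
        w = 1.0 * (x ** 2 + y ** 2) / 2.0   # um (D * mm^2 -> um)
        e = fit(w, x, y, 6, 2.0)
        assert e.get(2, 0) == pytest.approx(4.0 / (4 * math.sqrt(3)), abs=1e-9)

    def test_noise_recovery(self):
        rng = np.random.default_rng(7)
        x, y = self.grid()
        vec = rng.normal(0, 0.3, n_terms(6))
        truth = ZernikeExpansion.from_vector(vec, 2.0)
        vals = evaluate(truth, x / 2, y / 2) + rng.normal(0, 1e-6, x.size)
        e = fit(vals, x, y, 6, 2.0)
        assert np.allclose(e.to_vector(), vec, atol=1e-4)

    def test_rank_deficient_raises(self):
        x = np.linspace(-1, 1, 100)          # all on one line
        with pytest.raises(ValueError, match="rank"):
            fit(np.zeros(100), x, np.zeros(100), 6, 2.0)


class TestRmsHoa:
    def test_values(self):
        assert rms_hoa(ZernikeExpansion({(3, 1): 0.10}, 2.0)) == pytest.approx(0.10)
        assert rms_hoa(ZernikeExpansion({(3, 1): 0.3, (4, 0): 0.4}, 2.0)) \
            == pytest.approx(0.5)
        assert rms_hoa(ZernikeExpansion({(2, 0): 1.0, (2, 2): 0.4}, 2.0)) == 0.0

    @pytest.mark.parametrize("angle", [13.0, 45.0, 90.0, 161.5])
    def test_rotation_invariance(self, angle):
        rng = np.random.default_rng(3)
        e = ZernikeExpansion.from_vector(rng.normal(0, 0.2, 28), 2.0)
        assert rms_hoa(e.rotated(angle)) == pytest.approx(rms_hoa(e),
                                                          rel=1e-12)


class TestRefractionConversions:
    def test_plano_and_zero(self):
        assert sphcyl_to_zernike(SpheroCylinder(0, 0, 0), 2.0).to_vector().sum() == 0
        pv = zernike_to_powervector(ZernikeExpansion({}, 2.0))
        assert (pv.M, pv.J0, pv.J45) == (0, 0, 0)

    def test_pure_sphere_magnitude(self):
        e = sphcyl_to_zernike(SpheroCylinder(1.0, 0, 0), 2.0)
        assert abs(e.get(2, 0)) == pytest.approx(1 * 4 / (4 * math.sqrt(3)),
                                                 abs=1e-12)
        # positive (hyperopic) correction -> negative wavefront defocus
        assert e.get(2, 0) < 0

    def test_cylinder_magnitude(self):
        e = sphcyl_to_zernike(SpheroCylinder(0.0, -1.0, 0.0), 2.0)
        assert abs(e.get(2, 2)) == pytest.approx(1 * 4 / (4 * math.sqrt(6)),
                                                 abs=1e-12)
        assert zernike_to_powervector(e).J0 == pytest.approx(0.5, abs=1e-12)

    def test_myopic_sign_convention(self):
        # myopic eye: c(2,0) > 0, refraction M < 0
        pv = zernike_to_powervector(ZernikeExpansion({(2, 0): 0.577}, 2.0))
        assert pv.M == pytest.approx(-1.0, abs=2e-3)

    @pytest.mark.parametrize("pv,expected", [
        (PowerVector(0, 0, 0), (0.0, 0.0, 0.0)),
        (PowerVector(-0.5, 0.5, 0.0), (0.0, -1.0, 0.0)),
        (PowerVector(-0.5, 0.0, 0.5), (0.0, -1.0, 45.0)),
    ])
    def test_powervector_to_sphcyl(self, pv, expected):
        sc = powervector_to_sphcyl(pv)
        assert (sc.sphere, sc.cylinder, sc.axis) == \
            pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(s=st.floats(-10, 10), c=st.floats(-8, -0.01),
           a=st.floats(0, 179.99))
    def test_roundtrip_property(self, s, c, a):
        rx = SpheroCylinder(s, c, a)
        e = sphcyl_to_zernike(rx, 2.0)
        back = powervector_to_sphcyl(zernike_to_powervector(e))
        assert back.sphere == pytest.approx(rx.sphere, abs=1e-9)
        assert back.cylinder == pytest.approx(rx.cylinder, abs=1e-9)
        assert min(abs(back.axis - rx.axis),
                   180 - abs(back.axis - rx.axis)) < 1e-6

    def test_roundtrip_dense_random(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(1000):
            pv = PowerVector(*rng.uniform(-8, 8, 3))
            back = sphcyl_to_powervector(powervector_to_sphcyl(pv))
            worst = max(worst, abs(back.M - pv.M), abs(back.J0 - pv.J0),
                        abs(back.J45 - pv.J45))
        assert worst < 1e-9


class TestInvariants:
    def test_expansion_rejects_bad_modes(self):
        with pytest.raises(ValueError):
            ZernikeExpansion({(2, 1): 0.1}, 2.0)
        with pytest.raises(ValueError):
            ZernikeExpansion({(2, 0): 0.1}, -1.0)

    def test_negative_cylinder_enforced(self):
        with pytest.raises(ValueError):
            SpheroCylinder(0.0, 0.5, 0.0)
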