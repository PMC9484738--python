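import numpy as np
import pytest

from stpe.inversion import (
    ElasticEstimate,
    background_moduli,
    equivalent_inclusion_strain,
    eshelby_tensor,
    eshelby_tensor_sphere,
    eshelby_tensor_spheroid,
    fit_ellipsoid,
    invert_inclusion,
)
from stpe.phantom_forward import MaterialParams, eshelby_forward_strain

from _oracles import (
    equivalent_inclusion_mandel,
    eshelby_components_quadrature,
)


class TestSphereTensor:
    def test_incompressible_limit(self):
        # S_1111 -> (7 - 2.5)/7.5 = 0.6 as nu -> 0.5
        assert eshelby_tensor_sphere(0.5 - 1e-9).components["S1111"] == pytest.approx(
            0.6, abs=1e-6
        )

    def test_dilatational_eigenstrain_factor(self):
        # a pure dilatational eigenstrain is scaled by (1+nu)/(3(1-nu))
        for nu in (0.0, 0.2, 0.3, 0.45):
            S = eshelby_tensor_sphere(nu).normal_block()
            out = S @ np.ones(3)
            expected = (1 + nu) / (3 * (1 - nu))
            assert np.allclose(out, expected, rtol=1e-12)

    def test_index_symmetry(self):
        c = eshelby_tensor_sphere(0.3).components
        assert c["S1122"] == c["S3311"] == c["S1133"]

    @pytest.mark.parametrize("nu", [-0.1, 0.5, 0.7])
    def test_invalid_poisson(self, nu):
        with pytest.raises(ValueError):
            eshelby_tensor_sphere(nu)


class TestSpheroidTensor:
    @pytest.mark.parametrize("aspect", [1 + 1e-6, 1 - 1e-6])
    def test_sphere_continuity(self, aspect):
        s = eshelby_tensor_spheroid(0.3, aspect).components
        ref = eshelby_tensor_sphere(0.3).components
        for k in ref:
            assert s[k] == pytest.approx(ref[k], abs=1e-4)

    def test_paper_geometry_finite(self):
        # the 7.5 mm lateral x 5 mm axial tumour: aspect 2/3, oblate
        c = eshelby_tensor_spheroid(0.3, 5.0 / 7.5).components
        for v in c.values():
            assert np.isfinite(v)

    @pytest.mark.parametrize("aspect", [0.5, 5.0 / 7.5, 1.5, 3.0])
    @pytest.mark.parametrize("nu", [0.1, 0.3, 0.45])
    def test_quadrature_oracle(self, aspect, nu):
        ref = eshelby_components_quadrature(nu, aspect)
        got = eshelby_tensor_spheroid(nu, aspect).components
        for k, v in ref.items():
            assert got[k] == pytest.approx(v, abs=1e-8)

    def test_bad_aspect(self):
        with pytest.raises(ValueError):
            eshelby_tensor_spheroid(0.3, -1.0)


class TestEquivalentInclusion:
    def test_homogeneous_is_remote(self):
        S = eshelby_tensor_sphere(0.3).normal_block()
        eps0 = np.array([0.003, 0.003, -0.01])
        eps_in, estar = equivalent_inclusion_strain(1e4, 0.3, 1e4, 0.3, S, eps0)
        assert np.allclose(estar, 0)
        assert np.allclose(eps_in, eps0)

    def test_stiff_inclusion_strains_less(self):
        ezz_in, _, ezz_bg, _ = eshelby_forward_strain(
            MaterialParams(E=1e4, nu=0.3), MaterialParams(E=2e4, nu=0.3), "sphere", 1e3
        )
        assert abs(ezz_in) < abs(ezz_bg)

    def test_against_tensor_algebra_oracle(self):
        # sphere example from the defining 6x6 equivalency system
        nu_b, E_b, E_i, nu_i, sigma0 = 0.3, 1e4, 2e4, 0.4, 1e3
        tensor = eshelby_tensor_sphere(nu_b)
        eps_zz = -sigma0 / E_b
        eps0_t = np.diag([-nu_b * eps_zz, -nu_b * eps_zz, eps_zz])
        ref = equivalent_inclusion_mandel(E_b, nu_b, E_i, nu_i, tensor.full_tensor(), eps0_t)
        eps_in, _ = equivalent_inclusion_strain(
            E_b, nu_b, E_i, nu_i, tensor.normal_block(), np.diag(eps0_t)
        )
        assert np.allclose(eps_in, np.diag(ref), rtol=1e-10)

    def test_random_draws_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            E_b = rng.uniform(5e3, 5e4)
            E_i = E_b * rng.uniform(0.3, 4.0)
            nu_b = rng.uniform(0.05, 0.45)
            nu_i = rng.uniform(0.05, 0.45)
            aspect = rng.uniform(0.5, 2.0)
            tensor = eshelby_tensor(nu_b, aspect)
            eps_zz = -1e3 / E_b
            eps0 = np.array([-nu_b * eps_zz, -nu_b * eps_zz, eps_zz])
            ref = equivalent_inclusion_mandel(
                E_b, nu_b, E_i, nu_i, tensor.full_tensor(), np.diag(eps0)
            )
            eps_in, _ = equivalent_inclusion_strain(
                E_b, nu_b, E_i, nu_i, tensor.normal_block(), eps0
            )
            assert np.allclose(eps_in, np.diag(ref), rtol=1e-9)


class TestBackgroundModuli:
    def test_uniaxial_definition(self):
        E_b, nu_b = background_moduli(1000.0, 0.1, 0.0)
        assert E_b == pytest.approx(1e4)
        assert nu_b == 0.0

    def test_zero_axial_strain(self):
        with pytest.raises(ValueError):
            background_moduli(1000.0, 0.0, 0.01)

    def test_round_trip_through_forward_model(self):
        bg = MaterialParams(E=1e4, nu=0.3)
        inc = MaterialParams(E=2e4, nu=0.4)
        _, _, ezz_bg, err_bg = eshelby_forward_strain(bg, inc, "sphere", 1e3)
        E_b, nu_b = background_moduli(1e3, ezz_bg, err_bg)
        assert E_b == pytest.approx(1e4, rel=5e-3)
        assert nu_b == pytest.approx(0.3, rel=5e-3)


class TestInvertInclusion:
    @pytest.mark.parametrize("shape", ["sphere", 5.0 / 7.5])
    def test_forward_inverse_round_trip(self, shape):
        bg = MaterialParams(E=1e4, nu=0.3)
        inc = MaterialParams(E=2e4, nu=0.4)
        ezz_in, err_in, ezz_bg, err_bg = eshelby_forward_strain(bg, inc, shape, 1e3)
        est = invert_inclusion((ezz_in, err_in), (ezz_bg, err_bg), 1e4, 0.3, shape)
        assert est.E_i == pytest.approx(2e4, rel=1e-4)
        assert est.nu_i == pytest.approx(0.4, abs=1e-4)

    def test_no_contrast(self):
        est = invert_inclusion((0.1, 0.03), (0.1, 0.03), 1e4, 0.3, "sphere")
        assert est.E_i == pytest.approx(1e4, rel=1e-3)
        assert est.nu_i == pytest.approx(0.3, abs=1e-3)

    def test_recovery_grid(self):
        """Noise-free round trips across the contrast/PR plane."""
        bg = MaterialParams(E=1e4, nu=0.3)
        for contrast in (0.5, 1.2, 2.0, 3.0, 4.0):
            for nu_i in (0.1, 0.2, 0.3, 0.4, 0.45):
                inc = MaterialParams(E=contrast * 1e4, nu=nu_i)
                strains = eshelby_forward_strain(bg, inc, "sphere", 1e3)
                est = invert_inclusion(strains[:2], strains[2:], 1e4, 0.3, "sphere")
                assert est.E_i == pytest.approx(inc.E, rel=1e-3)
                assert est.nu_i == pytest.approx(nu_i, abs=5e-4)
                assert est.cost >= 0
                assert est.cost < 1e-12

    def test_noisy_roi_average_recovery(self):
        """ROI-averaged strains at realistic noise recover the moduli
        to a few percent (fixed-seed Monte Carlo)."""
        rng = np.random.default_rng(7)
        bg = MaterialParams(E=1e4, nu=0.3)
        inc = MaterialParams(E=2e4, nu=0.4)
        ezz_in, err_in, ezz_bg, err_bg = eshelby_forward_strain(bg, inc, "sphere", 1e3)
        n_px = 500  # averaging over an ROI of pixels at 40 dB
        noisy = [
            v * (1 + rng.normal(0, 0.01, n_px)).mean()
            for v in (ezz_in, err_in, ezz_bg, err_bg)
        ]
        E_b, nu_b = background_moduli(1e3, noisy[2], noisy[3])
        est = invert_inclusion(noisy[:2], noisy[2:], E_b, nu_b, "sphere")
        assert est.E_i == pytest.approx(2e4, rel=0.05)
        assert est.nu_i == pytest.approx(0.4, abs=0.02)

    def test_nonfinite_strain_rejected(self):
        with pytest.raises(ValueError):
            invert_inclusion((np.nan, 0.01), (0.1, 0.03), 1e4, 0.3)


class TestElasticEstimate:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ElasticEstimate(E_i=-1.0, nu_i=0.3, E_b=1e4, nu_b=0.3, cost=0.0)
        with pytest.raises(ValueError):
            ElasticEstimate(E_i=1e4, nu_i=0.6, E_b=1e4, nu_b=0.3, cost=0.0)


class TestFitEllipsoid:
    @staticmethod
    def _ellipse_mask(a_row, a_col, angle=0.0, n=201, pitch=0.1):
        c = (n - 1) / 2 * pitch
        r = (np.arange(n) * pitch - c)[:, None]
        q = (np.arange(n) * pitch - c)[None, :]
        rr = r * np.cos(angle) + q * np.sin(angle)
        qq = -r * np.sin(angle) + q * np.cos(angle)
        return (rr / a_row) ** 2 + (qq / a_col) ** 2 <= 1.0

    def test_circle(self):
        mask = self._ellipse_mask(3.75, 3.75)
        l1, l2, _ = fit_ellipsoid(mask, 0.1)
        assert l1 == pytest.approx(3.75, rel=0.02)
        assert l2 == pytest.approx(3.75, rel=0.02)

    def test_paper_ellipse(self):
        mask = self._ellipse_mask(2.5, 3.75)
        l1, l2, _ = fit_ellipsoid(mask, 0.1)
        assert l1 == pytest.approx(2.5, rel=0.03)
        assert l2 == pytest.approx(3.75, rel=0.03)

    def test_rotated_orientation(self):
        angle = 0.4
        mask = self._ellipse_mask(2.5, 3.75, angle=angle)
        _, _, orient = fit_ellipsoid(mask, 0.1)
        diff = (orient - (np.pi / 2 + angle)) % np.pi
        diff = min(diff, np.pi - diff)
        assert diff < np.deg2rad(2.0)

    def test_too_small_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            fit_ellipsoid(mask)
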