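import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stpe.evaluation import lp_for_tau
from stpe.phantom_forward import (
    MaterialParams,
    PhantomSpec,
    StrainFieldSeries,
    add_strain_noise,
    aggregate_modulus,
    eshelby_forward_strain,
    generate_strain_series,
    load_strain_series,
    save_strain_series,
    strain_time_constant,
)
from stpe.temporal_fit import fit_field


class TestAggregateModulus:
    def test_reduces_to_youngs_modulus_at_zero_pr(self):
        assert aggregate_modulus(1.0, 0.0) == 1.0

    def test_confined_compression_value(self):
        assert aggregate_modulus(10_000, 0.3) == pytest.approx(13461.54, abs=0.01)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            aggregate_modulus(5000, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        E=st.floats(1.0, 1e6),
        nu=st.floats(0.0, 0.499, exclude_max=True),
    )
    def test_never_below_youngs_modulus(self, E, nu):
        assert aggregate_modulus(E, nu) >= E * (1 - 1e-12)


class TestStrainTimeConstant:
    def test_known_value(self):
        mat = MaterialParams(E=10_000, nu=0.3, Lp=3.7143e-10)
        assert strain_time_constant(mat, 20_000) == pytest.approx(10.0, rel=1e-4)

    def test_inverse_in_permeability(self):
        m1 = MaterialParams(E=10_000, nu=0.3, Lp=1e-10)
        m2 = MaterialParams(E=10_000, nu=0.3, Lp=2e-10)
        assert strain_time_constant(m1, 2e4) == pytest.approx(
            2 * strain_time_constant(m2, 2e4)
        )

    def test_zero_permeability_is_infinite_tc(self):
        with pytest.raises(ValueError):
            strain_time_constant(MaterialParams(E=1e4, nu=0.3, Lp=0.0), 2e4)

    def test_validity_warning_at_assumption_boundary(self):
        # chi == k/a^2 violates chi >> k/a^2
        a = 3.75e-3
        chi = 1e-10 * 2e4
        k = chi * a**2
        mat = MaterialParams(E=1e4, nu=0.3, Lp=1e-10, k=k)
        with pytest.warns(RuntimeWarning):
            strain_time_constant(mat, 2e4, a)


class TestMaterialAndSpecValidation:
    def test_material_invariants(self):
        with pytest.raises(ValueError):
            MaterialParams(E=-1, nu=0.3)
        with pytest.raises(ValueError):
            MaterialParams(E=1e4, nu=0.55)

    def test_inclusion_must_fit(self):
        with pytest.raises(ValueError):
            PhantomSpec(
                inclusion=MaterialParams(E=2e4, nu=0.4),
                background=MaterialParams(E=1e4, nu=0.3),
                center_mm=(1.0, 20.0),
            )

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            PhantomSpec(
                inclusion=MaterialParams(E=2e4, nu=0.4),
                background=MaterialParams(E=1e4, nu=0.3),
                duration_s=0.5,
                dt_s=0.1,
            )


class TestGenerateStrainSeries:
    def test_exponential_identity_at_one_tc(self, small_series):
        """s(tau) = eta + (alpha - eta)/e, per region."""
        m = small_series.meta
        tau = m["tau_inclusion_s"]
        idx = int(round(tau / small_series.dt))
        mask = small_series.inclusion_mask
        val = small_series.axial[idx][mask].mean()
        expected = m["eta"]["zz_in"] + (m["alpha"]["zz_in"] - m["eta"]["zz_in"]) / np.e
        assert val == pytest.approx(expected, rel=1e-9)

    def test_settles_to_steady_state(self, small_series):
        m = small_series.meta
        final = small_series.axial[-1][small_series.inclusion_mask].mean()
        assert abs(final - m["eta"]["zz_in"]) / abs(m["eta"]["zz_in"]) < 0.003

    def test_mask_area_matches_circle(self):
        spec = PhantomSpec(
            inclusion=MaterialParams(E=2e4, nu=0.4, Lp=1e-10),
            background=MaterialParams(E=1e4, nu=0.3, Lp=1e-10),
            duration_s=2.0,
            dt_s=0.1,
            grid_pixels_per_mm=10.0,
        )
        series = generate_strain_series(spec)
        expected = np.pi * 37.5**2  # radius 3.75 mm at 0.1 mm pixels
        assert series.inclusion_mask.sum() == pytest.approx(expected, rel=0.02)

    def test_contrast_one_phantom_is_homogeneous(self):
        mat = MaterialParams(E=1e4, nu=0.3, Lp=1e-10)
        spec = PhantomSpec(
            inclusion=mat,
            background=mat,
            duration_s=2.0,
            dt_s=0.1,
            grid_pixels_per_mm=2.0,
        )
        series = generate_strain_series(spec)
        for stack in (series.axial, series.lateral):
            img = stack[0]
            assert (img.max() - img.min()) / abs(img).max() < 1e-12

    def test_refit_recovers_generating_parameters(self, small_phantom_spec, small_series):
        """Eq. 1 self-consistency: the fitter recovers (alpha, eta, tau)
        on noise-free generated data."""
        mask = small_series.inclusion_mask
        maps = fit_field(small_series, 60.0, mask=mask, which="axial")
        m = small_series.meta
        assert np.nanmax(np.abs(maps.tau_map[mask] - m["tau_inclusion_s"])) < 1e-3 * m["tau_inclusion_s"]
        assert np.nanmax(np.abs(maps.eta_map[mask] - m["eta"]["zz_in"])) < 1e-3 * abs(m["eta"]["zz_in"])
        assert np.nanmax(np.abs(maps.alpha_map[mask] - m["alpha"]["zz_in"])) < 1e-3 * abs(m["alpha"]["zz_in"])

    def test_spheroid_limit_reproduces_sphere(self):
        def make(shape_kwargs):
            return generate_strain_series(
                PhantomSpec(
                    inclusion=MaterialParams(E=2e4, nu=0.4, Lp=lp_for_tau(2e4, 0.4, 10.0)),
                    background=MaterialParams(E=1e4, nu=0.3, Lp=lp_for_tau(1e4, 0.3, 10.0)),
                    duration_s=2.0,
                    dt_s=0.1,
                    grid_pixels_per_mm=2.0,
                    **shape_kwargs,
                )
            )

        sphere = make({})
        spheroid = make(
            dict(
                inclusion_shape="spheroid",
                semi_axis_lateral_mm=3.75,
                semi_axis_axial_mm=3.75 * (1 + 1e-7),
            )
        )
        rel = np.abs(spheroid.axial[0] - sphere.axial[0]) / np.abs(sphere.axial[0])
        assert rel.max() < 1e-6


class TestAddStrainNoise:
    def test_infinite_snr_is_identity(self, small_series):
        out = add_strain_noise(small_series, np.inf, seed=0)
        assert np.array_equal(out.axial, small_series.axial)

    def test_empirical_snr(self, small_series):
        out = add_strain_noise(small_series, 40.0, seed=1)
        for name in ("axial", "lateral"):
            sig = getattr(small_series, name)
            noise = getattr(out, name) - sig
            snr = 20 * np.log10(
                np.sqrt((sig**2).mean()) / np.sqrt((noise**2).mean())
            )
            assert 39.5 < snr < 40.5

    def test_seed_determinism(self, small_series):
        a = add_strain_noise(small_series, 30.0, seed=5)
        b = add_strain_noise(small_series, 30.0, seed=5)
        assert np.array_equal(a.axial, b.axial)


class TestSeriesContainer:
    def test_shape_validation(self, small_series):
        with pytest.raises(ValueError):
            StrainFieldSeries(
                times=small_series.times,
                axial=small_series.axial,
                lateral=small_series.lateral[:, :-1],
                pixel_spacing_mm=small_series.pixel_spacing_mm,
                inclusion_mask=small_series.inclusion_mask,
            )

    def test_hdf5_round_trip(self, small_series, tmp_path):
        path = tmp_path / "series.h5"
        save_strain_series(path, small_series)
        back = load_strain_series(path)
        assert np.allclose(back.axial, small_series.axial)
        assert np.array_equal(back.inclusion_mask, small_series.inclusion_mask)
        spec = back.meta["spec"]
        assert spec.inclusion.E == small_series.meta["spec"].inclusion.E
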