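import numpy as np
import pytest

from stpe.phantom_forward import MaterialParams, PhantomSpec, generate_strain_series
from stpe.rf_simulation import TransducerSpec, simulate_rf_series, synthesize_rf
from stpe.strain_estimation import (
    DisplacementField,
    dp_integer_displacement,
    hs_refine,
    strain_from_displacement,
    total_displacement,
    track_pair,
    track_series,
)


class TestDpIntegerDisplacement:
    def test_identical_frames_give_zero(self, speckle_frame):
        ia, il = dp_integer_displacement(speckle_frame, speckle_frame, (5, 1))
        assert not ia.any()
        assert not il.any()

    def test_known_integer_shift(self, speckle_field, transducer, speckle_frame):
        """A 7-sample axial shift is recovered everywhere; a global
        cross-correlation oracle confirms the true lag."""
        shifted = speckle_field.copy()
        shifted.positions[:, 1] += 7 * transducer.sample_pitch_mm
        post = synthesize_rf(shifted, transducer, snr_db=np.inf)
        # oracle: lag of the peak of the global cross-correlation
        a = speckle_frame[30]
        b = post[30]
        lags = np.arange(-10, 11)
        xc = [np.dot(a[10:-10], np.roll(b, -k)[10:-10]) for k in lags]
        assert lags[int(np.argmax(xc))] == 7
        ia, il = dp_integer_displacement(speckle_frame, post, (10, 1))
        assert np.all(ia[:, 20:-20] == 7)

    def test_large_regularization_gives_constant_field(self, speckle_frame):
        rng = np.random.default_rng(0)
        noisy_post = speckle_frame + rng.normal(0, speckle_frame.std(), speckle_frame.shape)
        ia, _ = dp_integer_displacement(
            speckle_frame, noisy_post, (4, 1), regularization_weight=1e6
        )
        assert np.unique(ia).size == 1

    def test_invalid_search_range(self, speckle_frame):
        with pytest.raises(ValueError):
            dp_integer_displacement(speckle_frame, speckle_frame, (0, 1))


class TestHsRefine:
    def test_identical_frames_zero_flow(self, speckle_frame):
        u, v = hs_refine(speckle_frame, speckle_frame, 0.25, 50)
        assert np.abs(u).max() < 1e-8
        assert np.abs(v).max() < 1e-8

    def test_subsample_shift_recovered(self, speckle_field, transducer, speckle_frame):
        shifted = speckle_field.copy()
        shifted.positions[:, 1] += 0.3 * transducer.sample_pitch_mm
        post = synthesize_rf(shifted, transducer, snr_db=np.inf)
        u, _ = hs_refine(speckle_frame, post, 4.0, 300)
        assert u[6:-6, 100:-100].mean() == pytest.approx(0.3, abs=0.05)

    def test_infinite_smoothness_gives_uniform_flow(self, speckle_field, transducer, speckle_frame):
        shifted = speckle_field.copy()
        shifted.positions[:, 1] += 0.2 * transducer.sample_pitch_mm
        post = synthesize_rf(shifted, transducer, snr_db=np.inf)
        u, _ = hs_refine(speckle_frame, post, 1e9, 50)
        assert u.std() < 1e-4


class TestTotalDisplacement:
    def test_sample_to_depth_conversion(self, transducer):
        shape = (4, 6)
        ints = (np.full(shape, 7), np.zeros(shape, int))
        subs = (np.full(shape, 0.3), np.zeros(shape))
        disp = total_displacement(ints, subs, spec=transducer)
        expected_mm = 7.3 * 1540.0 / (2 * 40e6) * 1e3
        assert np.allclose(disp.axial_mm, expected_mm)

    def test_zero_displacement(self, transducer):
        z = np.zeros((3, 3))
        disp = total_displacement((z.astype(int), z.astype(int)), (z, z), spec=transducer)
        assert not disp.axial_mm.any() and not disp.lateral_mm.any()

    def test_pure_lateral_uses_line_pitch(self, transducer):
        shape = (3, 3)
        ints = (np.zeros(shape, int), np.ones(shape, int))
        subs = (np.zeros(shape), np.full(shape, 0.5))
        disp = total_displacement(ints, subs, spec=transducer)
        assert np.allclose(disp.lateral_mm, 1.5 * transducer.line_pitch_mm)

    def test_shape_mismatch(self, transducer):
        with pytest.raises(ValueError):
            total_displacement(
                (np.zeros((2, 2), int), np.zeros((2, 2), int)),
                (np.zeros((3, 3)), np.zeros((3, 3))),
                spec=transducer,
            )


class TestStrainFromDisplacement:
    @staticmethod
    def _field(axial_mm, lateral_mm=None):
        if lateral_mm is None:
            lateral_mm = np.zeros_like(axial_mm)
        return DisplacementField(
            axial_mm=axial_mm,
            lateral_mm=lateral_mm,
            axial_spacing_mm=0.02,
            lateral_spacing_mm=0.3,
        )

    def test_linear_ramp_exact(self):
        z = np.arange(500) * 0.02
        disp = self._field(np.tile(-0.01 * z, (20, 1)))
        eps_ax, _ = strain_from_displacement(disp)
        assert np.allclose(eps_ax[:, 50:-50], 0.01, atol=1e-10)

    def test_zero_displacement_zero_strain(self):
        disp = self._field(np.zeros((20, 300)))
        eps_ax, eps_lat = strain_from_displacement(disp)
        assert not eps_ax.any() and not eps_lat.any()

    def test_quadratic_displacement_slope(self):
        """u(z) = c z^2 has strain 2 c z; the moving linear fit is
        unbiased for a parabola at the window centre."""
        c = 1e-3
        z = np.arange(800) * 0.02
        disp = self._field(np.tile(-c * z**2, (10, 1)))
        eps_ax, _ = strain_from_displacement(disp, kernel_len=49, measurement_noise=1e-9)
        mid = 400
        expected = 2 * c * z[mid]
        assert eps_ax[5, mid] == pytest.approx(expected, rel=0.02)

    def test_kernel_validation(self):
        disp = self._field(np.zeros((10, 100)))
        with pytest.raises(ValueError):
            strain_from_displacement(disp, kernel_len=4)
        with pytest.raises(ValueError):
            strain_from_displacement(disp, kernel_len=201)


class TestTrackingPipeline:
    def test_determinism(self, speckle_field, transducer, speckle_frame):
        shifted = speckle_field.copy()
        shifted.positions[:, 1] *= 0.995
        post = synthesize_rf(shifted, transducer, snr_db=np.inf)
        d1 = track_pair(speckle_frame, post, transducer, (8, 0))
        d2 = track_pair(speckle_frame, post, transducer, (8, 0))
        assert np.array_equal(d1.axial_mm, d2.axial_mm)

    def test_uniform_compression_end_to_end(self, speckle_field, transducer, speckle_frame):
        """1% uniform compression tracked to within 10% over the
        central image region."""
        shifted = speckle_field.copy()
        shifted.positions[:, 1] *= 1 - 0.01
        post = synthesize_rf(shifted, transducer, snr_db=np.inf)
        disp = track_pair(speckle_frame, post, transducer, (14, 0))
        eps_ax, _ = strain_from_displacement(disp)
        centre = eps_ax[6:-6, 100:-100]
        assert centre.mean() == pytest.approx(0.01, rel=0.10)

    def test_phantom_movie_tracking_accuracy(self):
        """Noise-free RF of a creeping phantom (~1% strain): per-frame
        mean absolute strain error below 5e-4 axially and 2e-3
        laterally."""
        from stpe.evaluation import lp_for_tau
        from stpe.phantom_forward import StrainFieldSeries

        spec = PhantomSpec(
            inclusion=MaterialParams(E=2e5, nu=0.4, Lp=lp_for_tau(2e5, 0.4, 5.0)),
            background=MaterialParams(E=1e5, nu=0.3, Lp=lp_for_tau(1e5, 0.3, 5.0)),
            duration_s=10.0,
            dt_s=1.0,
            grid_pixels_per_mm=5.0,
        )
        truth = generate_strain_series(spec)
        pick = [0, 5, 10]  # three creep frames are enough for the check
        truth = StrainFieldSeries(
            times=truth.times[pick],
            axial=truth.axial[pick],
            lateral=truth.lateral[pick],
            pixel_spacing_mm=truth.pixel_spacing_mm,
            inclusion_mask=truth.inclusion_mask,
            meta=truth.meta,
        )
        rf = simulate_rf_series(truth, snr_db=np.inf, seed=3)
        est = track_series(rf, search_range_first=(26, 0))
        # compare on the RF grid away from the borders
        spec_t = rf.spec
        nz, nx = est.axial.shape[1:]
        z = np.arange(nz) * spec_t.sample_pitch_mm
        x = np.arange(nx) * spec_t.line_pitch_mm
        zi = slice(60, nz - 60)
        xi = slice(4, nx - 4)
        for j in (0, len(est.times) - 1):
            t = est.times[j]
            # nearest-pixel lookup of the true strain movie
            from scipy.interpolate import RegularGridInterpolator

            zt = (np.arange(truth.axial.shape[1]) + 0.5) * truth.pixel_spacing_mm[0]
            xt = (np.arange(truth.axial.shape[2]) + 0.5) * truth.pixel_spacing_mm[1]
            interp = RegularGridInterpolator(
                (zt, xt), truth.axial[j], bounds_error=False, fill_value=None
            )
            Z, X = np.meshgrid(z[zi], x[xi], indexing="ij")
            ref = interp(np.column_stack([Z.ravel(), X.ravel()])).reshape(Z.shape)
            err = np.abs(est.axial[j][zi, xi] - ref)
            assert err.mean() < 5e-4
            interp_l = RegularGridInterpolator(
                (zt, xt), truth.lateral[j], bounds_error=False, fill_value=None
            )
            ref_l = interp_l(np.column_stack([Z.ravel(), X.ravel()])).reshape(Z.shape)
            err_l = np.abs(est.lateral[j][zi, xi] - ref_l)
            assert err_l.mean() < 2e-3
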