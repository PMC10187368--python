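"""Wave-optics simulator: propagation, objects, diffuser, detection, statistics."""

from __future__ import annotations

import numpy as np
import pytest

from xstrack.wave_optics import (
    GRAIN_SWEEP_UM,
    OPTICAL_CONSTANTS,
    AliasingError,
    DiffuserSpec,
    ImagingGeometry,
    SampleModel,
    WaveField,
    apply_object,
    autocorrelation_fwhm,
    detect,
    plane_wave,
    propagate,
    simulate_pair,
    speckle_visibility,
    synthesize_diffuser,
    wavelength_from_energy,
)

LAMBDA_30KEV = wavelength_from_energy(30.0)


def _random_field(rng, shape=(64, 64), pitch=1.0, smooth=3.0):
    from scipy import ndimage

    a = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    a = ndimage.gaussian_filter(a.real, smooth) + 1j * ndimage.gaussian_filter(a.imag, smooth)
    return WaveField(a, pitch, LAMBDA_30KEV)


class TestPropagate:
    def test_zero_distance_is_identity(self, rng):
        f = _random_field(rng)
        out = propagate(f, 0.0)
        np.testing.assert_array_equal(out.amplitude, f.amplitude)

    @pytest.mark.parametrize("distance", [1e3, 1e5, 5e5])
    def test_energy_conservation(self, rng, distance):
        # unpadded propagation is a unitary spectral filter
        f = _random_field(rng)
        out = propagate(f, distance, pad_fraction=0.0)
        np.testing.assert_allclose(out.total_intensity(), f.total_intensity(), rtol=1e-10)

    def test_reciprocity(self, rng):
        f = _random_field(rng, smooth=4.0)
        back = propagate(propagate(f, 2e5, pad_fraction=0.0), -2e5, pad_fraction=0.0)
        assert np.max(np.abs(back.amplitude - f.amplitude)) < 1e-8 * np.max(np.abs(f.amplitude))

    def test_aliasing_bound_raises(self, rng):
        f = _random_field(rng, shape=(32, 32))
        with pytest.raises(AliasingError):
            propagate(f, 1e12)

    def test_matches_fresnel_quadrature_oracle(self):
        """30 keV plane wave through a 100 um slit at 1 m versus direct
        quadrature of the Fresnel diffraction integral.  The slit edges are
        apodized over ~1.5 um so the sampled field and the continuous oracle
        describe the same aperture."""
        from scipy.special import erf

        pitch = 1.0
        n = 2048
        rows = 64  # uniform along y; tall enough for the axial sampling bound
        z = 1.0e6  # 1 m in um
        edge = 1.5  # um

        def aperture(xx):
            return 0.5 * (erf((xx + 50.0) / edge) - erf((xx - 50.0) / edge))

        x = (np.arange(n) - n / 2) * pitch
        amp = np.broadcast_to(aperture(x).astype(complex), (rows, n)).copy()
        f = WaveField(amp, pitch, LAMBDA_30KEV)
        out = propagate(f, z)
        profile = np.abs(out.amplitude[rows // 2]) ** 2

        # oracle: direct quadrature of the 1D Fresnel integral
        xs = np.linspace(-62.0, 62.0, 40001)
        dxs = xs[1] - xs[0]
        lamz = LAMBDA_30KEV * z
        sel = np.abs(x) <= 200.0  # compare where the padded simulation is clean
        apod = aperture(xs)
        oracle = np.empty(sel.sum())
        for i, xi in enumerate(x[sel]):
            kernel = apod * np.exp(1j * np.pi * (xi - xs) ** 2 / lamz)
            oracle[i] = np.abs(kernel.sum() * dxs / np.sqrt(lamz)) ** 2
        scale = oracle.max()
        assert np.max(np.abs(profile[sel] - oracle)) / scale < 1e-3


class TestApplyObject:
    def test_zero_thickness_identity(self, rng):
        f = _random_field(rng)
        s = SampleModel(np.zeros(f.grid_shape), delta=1e-7, mu=1e-5)
        out = apply_object(f, s)
        np.testing.assert_array_equal(out.amplitude, f.amplitude)

    def test_uniform_slab_beer_lambert(self, rng):
        f = _random_field(rng)
        mu = 3.62e-5
        t = 500.0
        s = SampleModel(np.full(f.grid_shape, t), delta=2.96e-7, mu=mu)
        out = apply_object(f, s)
        np.testing.assert_allclose(
            np.abs(out.amplitude) ** 2, np.abs(f.amplitude) ** 2 * np.exp(-mu * t), rtol=1e-10
        )

    def test_pmma_phase_shift_matches_independent_delta(self):
        """Phase advance on a PMMA slab cross-checked against delta computed
        from first principles: r_e lambda^2 n_e / (2 pi)."""
        f = plane_wave((8, 8), 1.0, LAMBDA_30KEV)
        t = 100.0
        out = apply_object(f, SampleModel.from_material(np.full((8, 8), t), "PMMA"))
        phase = np.angle(out.amplitude[0, 0] / f.amplitude[0, 0])
        # independent electron-density computation (C5H8O2, 1.19 g/cm^3)
        r_e = 2.8179403e-13  # cm
        n_avog = 6.02214e23
        n_e = 1.19 * n_avog * 54 / 100.12  # electrons / cm^3
        lam_cm = LAMBDA_30KEV * 1e-4
        delta_indep = r_e * lam_cm**2 * n_e / (2 * np.pi)
        expected = -2 * np.pi * delta_indep * t / LAMBDA_30KEV
        expected_wrapped = np.angle(np.exp(1j * expected))
        assert abs(phase - expected_wrapped) < 0.02 * abs(expected_wrapped) + 1e-9

    def test_grid_mismatch_raises(self, rng):
        f = _random_field(rng, shape=(64, 64))
        s = SampleModel(np.zeros((40, 40)), delta=1e-7, mu=0.0)
        with pytest.raises(ValueError):
            apply_object(f, s)


class TestDiffuser:
    def test_determinism(self):
        spec = DiffuserSpec(n_layers=3, seed=7)
        a = synthesize_diffuser(spec, (32, 32), 1.0)
        b = synthesize_diffuser(spec, (32, 32), 1.0)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la[0].thickness_map, lb[0].thickness_map)

    def test_backing_is_uniform_200um(self):
        layers = synthesize_diffuser(DiffuserSpec(n_layers=2, seed=1), (16, 16), 1.0)
        for grain, backing in layers:
            assert np.all(backing.thickness_map == 200.0)
            assert backing.label == "C6H10O5"
            assert grain.label == "Al2O3"

    def test_layer_count_and_nonnegative(self):
        layers = synthesize_diffuser(DiffuserSpec(n_layers=10, seed=2), (16, 16), 1.0)
        assert len(layers) == 10
        assert all(np.all(g.thickness_map >= 0) for g, _ in layers)


class TestDetect:
    def test_flat_field(self, geometry):
        f = plane_wave((64, 64), geometry.detector_pixel_pitch / (geometry.magnification * 4),
                       LAMBDA_30KEV)
        img = detect(f, geometry)
        inner = img.data[2:-2, 2:-2]
        np.testing.assert_allclose(inner, inner.mean(), rtol=1e-10)

    def test_signal_conservation(self, geometry, rng):
        # mean binning + normalized Gaussian PSF preserve the mean intensity
        pitch = geometry.detector_pixel_pitch / (geometry.magnification * 4)
        amp = 1.0 + 0.1 * rng.standard_normal((128, 128))
        f = WaveField(amp.astype(complex), pitch, LAMBDA_30KEV)
        img = detect(f, geometry, apply_source_blur=False)
        incident = np.mean(np.abs(f.amplitude) ** 2) / geometry.magnification**2
        np.testing.assert_allclose(img.data.mean(), incident, rtol=1e-3)

    def test_point_source_gives_sampled_gaussian_psf(self, geometry):
        pitch = geometry.detector_pixel_pitch / geometry.magnification  # oversample 1
        amp = np.zeros((33, 33), dtype=complex)
        amp[16, 16] = 1.0
        f = WaveField(amp, pitch, LAMBDA_30KEV)
        img = detect(f, geometry, apply_source_blur=False)
        sigma = geometry.psf_sigma
        yy, xx = np.mgrid[-16:17, -16:17]
        expected = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        expected /= expected.sum()
        expected *= img.data.sum()
        assert np.max(np.abs(img.data - expected)) < 1e-3 * expected.max()

    def test_non_integer_oversampling_raises(self, geometry):
        f = plane_wave((32, 32), 1.7, LAMBDA_30KEV)
        with pytest.raises(ValueError):
            detect(f, geometry)


class TestSimulatePair:
    def test_no_sample_images_identical(self, geometry):
        ref, sam, gt = simulate_pair(
            geometry, DiffuserSpec(seed=5), detector_shape=(32, 32)
        )
        assert gt is None
        np.testing.assert_array_equal(ref.data, sam.data)

    def test_determinism(self, geometry):
        a, _, _ = simulate_pair(geometry, DiffuserSpec(seed=9), detector_shape=(32, 32))
        b, _, _ = simulate_pair(geometry, DiffuserSpec(seed=9), detector_shape=(32, 32))
        np.testing.assert_array_equal(a.data, b.data)

    def test_default_visibility_at_least_20_percent(self, speckle_128):
        assert speckle_visibility(speckle_128) >= 0.20

    def test_speckle_size_monotone_in_grain_size(self, geometry):
        """Autocorrelation FWHM grows monotonically with the diffuser grain
        size across the sweep range."""
        fwhms = []
        for gf in GRAIN_SWEEP_UM[::2] + (GRAIN_SWEEP_UM[-1],):
            ref, _, _ = simulate_pair(
                geometry, DiffuserSpec(seed=13, grain_fwhm=gf), detector_shape=(96, 96)
            )
            fwhms.append(autocorrelation_fwhm(ref))
        assert all(b > a for a, b in zip(fwhms, fwhms[1:]))
        assert fwhms[0] < 3.5  # fine-grain end near ~2 px
        assert fwhms[-1] > 6.0  # coarse-grain end approaching ~10 px


class TestOpticalConstants:
    @pytest.mark.parametrize("material,rho,electrons,molar_mass", [
        ("PMMA", 1.19, 54, 100.12),
        ("Al2O3", 3.95, 50, 101.96),
        ("C6H10O5", 1.101, 86, 162.14),
    ])
    def test_delta_matches_electron_density_formula(self, material, rho, electrons, molar_mass):
        r_e = 2.8179403e-13
        n_e = rho * 6.02214e23 * electrons / molar_mass
        lam_cm = LAMBDA_30KEV * 1e-4
        delta = r_e * lam_cm**2 * n_e / (2 * np.pi)
        assert OPTICAL_CONSTANTS[material]["delta"] == pytest.approx(delta, rel=0.02)
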