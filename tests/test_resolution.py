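"""Resolution estimators: FWHM, histogram matching, Sparrow, autocov, autoinfo."""

import numpy as np
import pytest

from gsnr import SpeckleSpec, make_two_point_series
from gsnr.beamform import das_transform
from gsnr.metrics import EnvelopeImage
from gsnr.resolution import (
    ResolutionEstimate,
    autocov_length,
    autoinfo_length,
    calibrate_to_das_fwhm,
    fwhm_profile,
    histogram_match,
    matched_psf_fwhm,
    psf_fwhm,
    sparrow_limit,
)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of unit-sigma Gaussian


class TestFwhmProfile:
    def test_gaussian_width(self):
        x = np.arange(-6.0, 6.0, 0.01)
        profile = np.exp(-(x**2) / 2.0)
        assert fwhm_profile(profile, 0.01) == pytest.approx(GAUSS_FWHM, abs=1e-3)

    def test_squared_gaussian_shrinks_by_sqrt2(self):
        x = np.arange(-6.0, 6.0, 0.01)
        profile = np.exp(-(x**2) / 2.0) ** 2
        assert fwhm_profile(profile, 0.01) == pytest.approx(GAUSS_FWHM / np.sqrt(2), abs=1e-3)

    def test_monotone_ramp_rejected(self):
        with pytest.raises(ValueError):
            fwhm_profile(np.arange(10.0), 0.1)

    def test_missing_crossing_rejected(self):
        profile = np.array([0.9, 1.0, 0.9])  # never reaches half maximum
        with pytest.raises(ValueError):
            fwhm_profile(profile, 0.1)


class TestPsfFwhm:
    def test_recovers_configured_widths(self, default_spec, lesion_scene):
        _, _, psf = lesion_scene
        lat, ax = psf_fwhm(psf)
        assert lat == pytest.approx(default_spec.psf_fwhm_lat, abs=psf.dx)
        assert ax == pytest.approx(default_spec.psf_fwhm_ax, abs=psf.dz)

    def test_squared_psf_shrinks_by_sqrt2(self, default_spec, lesion_scene):
        _, _, psf = lesion_scene
        lat, ax = psf_fwhm(das_transform(psf, 2.0))
        assert lat == pytest.approx(default_spec.psf_fwhm_lat / np.sqrt(2), abs=2 * psf.dx)
        assert ax == pytest.approx(default_spec.psf_fwhm_ax / np.sqrt(2), abs=2 * psf.dz)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            psf_fwhm(EnvelopeImage(np.ones((32, 32)), 0.1, 0.1))


class TestHistogramMatch:
    def test_identity_within_quantization(self, speckle_patch):
        mapped = histogram_match(speckle_patch, speckle_patch)
        assert np.allclose(mapped.pixels, speckle_patch.pixels, rtol=1e-6, atol=1e-9)

    def test_undoes_power_transform(self, speckle_patch):
        squared = das_transform(speckle_patch, 2.0)
        restored = histogram_match(squared, speckle_patch)
        # the quantile map recovers the original distribution pointwise
        assert np.allclose(restored.pixels, speckle_patch.pixels, rtol=1e-3, atol=1e-6)

    def test_matched_squared_psf_recovers_das_fwhm(self, lesion_scene, speckle_patch):
        _, _, psf = lesion_scene
        das_lat, das_ax = psf_fwhm(psf)
        squared_psf = das_transform(psf, 2.0)
        squared_speckle = das_transform(speckle_patch, 2.0)
        lat, ax = matched_psf_fwhm(squared_psf, squared_speckle, speckle_patch)
        assert lat == pytest.approx(das_lat, abs=psf.dx)
        assert ax == pytest.approx(das_ax, abs=psf.dz)

    def test_constant_source_rejected(self, speckle_patch):
        flat = EnvelopeImage(np.ones((32, 32)), 0.1, 0.1)
        with pytest.raises(ValueError):
            histogram_match(flat, speckle_patch)


class TestDasCalibration:
    """The calibration arithmetic on the published axial Sparrow row."""

    SPARROW_AXIAL = {"DAS": 0.300, "DAS^2": 0.306, "GCF": 0.301, "MV": 0.302, "F-DMAS": 0.290}
    DAS_FWHM = ResolutionEstimate("fwhm", lateral=0.440, axial=0.385)

    @pytest.fixture(scope="class")
    @classmethod
    def scaled(cls):
        estimates = {
            key: ResolutionEstimate("sparrow", lateral=0.4, axial=ax)
            for key, ax in cls.SPARROW_AXIAL.items()
        }
        return calibrate_to_das_fwhm(estimates, cls.DAS_FWHM)

    def test_das_scaled_equals_das_fwhm_exactly(self, scaled):
        assert scaled["DAS"].axial == pytest.approx(self.DAS_FWHM.axial, rel=1e-12)

    @pytest.mark.parametrize("key, printed", [("MV", 0.388), ("GCF", 0.386), ("DAS^2", 0.393)])
    def test_scaled_cells_round_to_printed_values(self, scaled, key, printed):
        assert round(scaled[key].axial, 3) == printed

    def test_calibration_scalar_recorded(self, scaled):
        assert scaled["MV"].calibration_axial == pytest.approx(0.385 / 0.300, rel=1e-12)
        assert scaled["MV"].scaled

    def test_missing_das_reference_rejected(self):
        ests = {"MV": ResolutionEstimate("sparrow", 0.4, 0.3)}
        with pytest.raises(ValueError):
            calibrate_to_das_fwhm(ests, self.DAS_FWHM)

    def test_mixed_methods_rejected(self):
        ests = {
            "DAS": ResolutionEstimate("sparrow", 0.4, 0.3),
            "MV": ResolutionEstimate("autoinfo", 0.4, 0.3),
        }
        with pytest.raises(ValueError):
            calibrate_to_das_fwhm(ests, self.DAS_FWHM)


@pytest.fixture(scope="module")
def two_point_spec():
    """Gaussian PSF with sigma = 0.2 mm on a fine 6.25 um grid."""
    sigma = 0.2
    return SpeckleSpec(
        field_size=(6.0, 6.0),
        dz=0.025,
        dx=0.025,
        oversample=4,
        lesion_center=(3.0, 3.0),
        lesion_radius=1.0,
        psf_fwhm_lat=sigma * GAUSS_FWHM,
        psf_fwhm_ax=sigma * GAUSS_FWHM,
    )


# separations on the realized grid (multiples of 2 * fine spacing = 0.0125 mm)
SEPARATIONS = np.round(np.arange(0.350, 0.4626, 0.0125), 4)


class TestSparrow:
    def test_noise_free_limit_is_twice_sigma(self, two_point_spec):
        # two coherent Gaussian envelopes develop a midpoint dip at 2*sigma
        series = make_two_point_series(
            two_point_spec, SEPARATIONS, axis="lateral", noise_snr_db=np.inf
        )
        assert sparrow_limit(series) == pytest.approx(0.400, abs=0.0126)

    def test_axial_scan_matches_lateral(self, two_point_spec):
        series = make_two_point_series(
            two_point_spec, SEPARATIONS, axis="axial", noise_snr_db=np.inf
        )
        assert sparrow_limit(series) == pytest.approx(0.400, abs=0.0126)

    def test_noisy_scan_with_quartic_fit(self, two_point_spec):
        limits = []
        for seed in range(6):
            series = make_two_point_series(
                two_point_spec, SEPARATIONS, axis="lateral", noise_snr_db=60.0, seed=seed
            )
            limits.append(sparrow_limit(series, fit_quartic=True))
        # within two scan steps of the noise-free limit for every realization
        assert all(abs(lim - 0.4125) <= 0.025 for lim in limits)

    def test_monotone_transform_invariance(self, two_point_spec):
        series = make_two_point_series(
            two_point_spec, SEPARATIONS, axis="lateral", noise_snr_db=np.inf
        )
        series.stack = [das_transform(img, 2.0) for img in series.stack]
        assert sparrow_limit(series) == pytest.approx(0.400, abs=0.0126)

    def test_unbracketed_scan_rejected(self, two_point_spec):
        resolved = np.round(np.arange(0.500, 0.563, 0.0125), 4)  # all show a dip
        series = make_two_point_series(
            two_point_spec, resolved, axis="lateral", noise_snr_db=np.inf
        )
        with pytest.raises(ValueError, match="outside scan range"):
            sparrow_limit(series)


class TestAutocov:
    def test_recovers_psf_widths(self, default_spec, speckle_patch):
        lat = autocov_length(speckle_patch, "lateral")
        ax = autocov_length(speckle_patch, "axial")
        assert lat == pytest.approx(default_spec.psf_fwhm_lat, rel=0.10)
        assert ax == pytest.approx(default_spec.psf_fwhm_ax, rel=0.10)

    def test_amplitude_scaling_invariance(self, speckle_patch):
        scaled = speckle_patch.with_pixels(speckle_patch.pixels * 7.3)
        assert autocov_length(scaled, "lateral") == pytest.approx(
            autocov_length(speckle_patch, "lateral"), rel=1e-12
        )

    def test_independent_noise_has_subpixel_length(self, rng):
        noise = EnvelopeImage(rng.rayleigh(size=(128, 128)), dz=0.05, dx=0.05)
        assert autocov_length(noise, "lateral") <= 2 * 0.05

    def test_not_invariant_under_squaring(self, speckle_patch):
        # squaring the envelope narrows the measured correlation length:
        # corr(I^2) = (4u + u^2)/5 with u = |rho|^2, whose half-maximum
        # width is 0.929x the intensity-autocovariance width for a Gaussian
        # PSF.  The manipulability (no invariance) is the point.
        base = autocov_length(speckle_patch, "lateral")
        squared = autocov_length(das_transform(speckle_patch, 2.0), "lateral")
        assert squared < base
        assert squared == pytest.approx(0.929 * base, rel=0.05)

    def test_small_patch_rejected(self, rng):
        tiny = EnvelopeImage(rng.rayleigh(size=(8, 8)), dz=0.05, dx=0.05)
        with pytest.raises(ValueError):
            autocov_length(tiny, "lateral")


class TestAutoinfo:
    def test_independent_pixels_drop_immediately(self, rng):
        noise = EnvelopeImage(rng.rayleigh(size=(256, 256)), dz=0.05, dx=0.05)
        assert autoinfo_length(noise, "lateral") == pytest.approx(2 * 0.05, rel=0.5)

    def test_exact_invariance_under_power_transform(self, speckle_patch):
        base = autoinfo_length(speckle_patch, "lateral")
        squared = autoinfo_length(das_transform(speckle_patch, 2.0), "lateral")
        assert squared == base  # rank binning: exactly identical

    def test_scaled_das_value_equals_das_fwhm(self, speckle_patch, lesion_scene):
        _, _, psf = lesion_scene
        das_fwhm = ResolutionEstimate("fwhm", *psf_fwhm(psf))
        raw = {
            "DAS": ResolutionEstimate(
                "autoinfo",
                autoinfo_length(speckle_patch, "lateral"),
                autoinfo_length(speckle_patch, "axial"),
            )
        }
        scaled = calibrate_to_das_fwhm(raw, das_fwhm)
        assert scaled["DAS"].lateral == pytest.approx(das_fwhm.lateral, rel=1e-12)
        assert scaled["DAS"].axial == pytest.approx(das_fwhm.axial, rel=1e-12)

    def test_threshold_domain_checked(self, speckle_patch):
        with pytest.raises(ValueError):
            autoinfo_length(speckle_patch, "lateral", threshold=1.5)
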