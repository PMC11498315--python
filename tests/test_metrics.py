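"""Empirical contrast/gCNR estimators, cell counting and detectability scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsnr import analytic
from gsnr.metrics import (
    DetectabilityResult,
    EnvelopeImage,
    RoiSet,
    cpsi_empirical,
    count_cells,
    cr_empirical,
    gcnr_ecdf,
    gcnr_hist_oracle,
    gsnr,
    resolution_cell_area,
    snr,
)


def split_roi(shape):
    """Top-half lesion / bottom-half background masks of equal size."""
    lesion = np.zeros(shape, dtype=bool)
    background = np.zeros(shape, dtype=bool)
    lesion[: shape[0] // 2] = True
    background[shape[0] // 2 :] = True
    return RoiSet(lesion, background, true_radius=1.0, dz=0.1, dx=0.1)


def rayleigh_image(rng, cr2, shape=(200, 200)):
    """Uncorrelated Rayleigh speckle: lesion scale sqrt(cr2) in the top half."""
    pixels = rng.rayleigh(scale=1.0, size=shape)
    pixels[: shape[0] // 2] *= np.sqrt(cr2)
    return EnvelopeImage(pixels, dz=0.1, dx=0.1)


class TestContainers:
    def test_image_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            EnvelopeImage(np.array([[1.0, -1.0]]), 0.1, 0.1)
        with pytest.raises(ValueError):
            EnvelopeImage(np.array([[np.nan, 1.0]]), 0.1, 0.1)

    def test_roi_requires_disjoint_masks(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            RoiSet(mask, mask, true_radius=1.0)

    def test_roi_requires_count_parity(self):
        lesion = np.zeros((10, 10), dtype=bool)
        background = np.zeros((10, 10), dtype=bool)
        lesion[:5] = True  # 50 px
        background[5:9] = True  # 40 px -> 20% mismatch
        with pytest.raises(ValueError):
            RoiSet(lesion, background, true_radius=1.0)

    def test_lesion_area_uses_pixel_spacing(self):
        roi = split_roi((10, 10))
        assert roi.lesion_area == pytest.approx(50 * 0.01)


class TestCpsiEmpirical:
    def test_identical_regions_give_zero(self):
        img = EnvelopeImage(np.ones((20, 20)), 0.1, 0.1)
        assert cpsi_empirical(img, split_roi((20, 20))) == 0.0

    def test_anechoic_lesion_gives_one(self):
        pixels = np.ones((20, 20))
        pixels[:10] = 0.0
        img = EnvelopeImage(pixels, 0.1, 0.1)
        assert cpsi_empirical(img, split_roi((20, 20))) == 1.0

    def test_signed_value_negative_for_hypoechoic(self, rng):
        img = rayleigh_image(rng, cr2=0.5)
        assert cpsi_empirical(img, split_roi(img.shape), signed=True) < 0

    def test_rayleigh_minus4db_recovers_analytic(self, rng):
        # -4 dB intensity contrast: R = 10^(-0.4), Cpsi = 0.559
        img = rayleigh_image(rng, cr2=10 ** (-0.4), shape=(600, 600))
        value = cpsi_empirical(img, split_roi(img.shape))
        assert value == pytest.approx(0.5592, abs=0.02)

    def test_minimum_region_size_enforced(self):
        img = EnvelopeImage(np.ones((4, 4)), 0.1, 0.1)
        with pytest.raises(ValueError):
            cpsi_empirical(img, split_roi((4, 4)))


class TestCrEmpirical:
    def test_equal_regions(self):
        img = EnvelopeImage(np.ones((20, 20)), 0.1, 0.1)
        ratio, db = cr_empirical(img, split_roi((20, 20)))
        assert ratio == pytest.approx(1.0)
        assert db == pytest.approx(0.0)

    def test_half_amplitude_lesion(self):
        pixels = np.ones((20, 20))
        pixels[:10] = 0.5
        img = EnvelopeImage(pixels, 0.1, 0.1)
        ratio, db = cr_empirical(img, split_roi((20, 20)))
        assert ratio == pytest.approx(0.5)
        assert db == pytest.approx(-6.0206, abs=1e-3)

    def test_rayleigh_scale_ratio(self, rng):
        img = rayleigh_image(rng, cr2=0.5, shape=(500, 500))
        ratio, _ = cr_empirical(img, split_roi(img.shape))
        assert ratio == pytest.approx(np.sqrt(0.5), abs=0.01)

    def test_zero_background_rejected(self):
        pixels = np.zeros((20, 20))
        pixels[:10] = 1.0
        img = EnvelopeImage(pixels, 0.1, 0.1)
        with pytest.raises(ValueError):
            cr_empirical(img, split_roi((20, 20)))


class TestGcnrEcdf:
    def test_identical_samples_give_zero(self, rng):
        x = rng.rayleigh(size=500)
        assert gcnr_ecdf(x, x) == 0.0

    def test_disjoint_supports_give_one(self, rng):
        x = rng.uniform(0.0, 1.0, 300)
        y = rng.uniform(2.0, 3.0, 300)
        assert gcnr_ecdf(x, y) == 1.0

    def test_rayleigh_pair_recovers_analytic(self, rng):
        x = rng.rayleigh(scale=np.sqrt(0.5), size=100_000)
        y = rng.rayleigh(scale=1.0, size=100_000)
        assert gcnr_ecdf(x, y) == pytest.approx(0.25, abs=0.01)

    def test_monotone_transform_invariance_is_exact(self, rng):
        x = rng.rayleigh(scale=0.7, size=3000)
        y = rng.rayleigh(scale=1.0, size=3000)
        base = gcnr_ecdf(x, y)
        assert gcnr_ecdf(x**2, y**2) == base
        assert gcnr_ecdf(np.log(x), np.log(y)) == base
        assert gcnr_ecdf(np.sqrt(x), np.sqrt(y)) == base

    def test_agreement_with_histogram_oracle(self, rng):
        for cr2 in (0.1, 0.5, 0.9):
            x = rng.rayleigh(scale=np.sqrt(cr2), size=10_000)
            y = rng.rayleigh(scale=1.0, size=10_000)
            assert gcnr_ecdf(x, y) == pytest.approx(
                gcnr_hist_oracle(x, y, n_bins=100), abs=0.02
            )

    def test_small_sample_bias_decreases_with_n(self):
        # identical distributions: estimate is pure positive bias
        biases = []
        for n in (100, 1000, 10_000):
            values = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                values.append(gcnr_ecdf(r.rayleigh(size=n), r.rayleigh(size=n)))
            biases.append(np.mean(values))
        assert biases[0] > biases[1] > biases[2]
        assert all(b >= 0 for b in biases)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_always_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=r.integers(2, 50))
        y = r.normal(loc=r.uniform(-2, 2), size=r.integers(2, 50))
        assert 0.0 <= gcnr_ecdf(x, y) <= 1.0

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            gcnr_ecdf([1.0], [1.0, 2.0])


class TestHistOracle:
    def test_trivial_cases(self, rng):
        x = rng.rayleigh(size=1000)
        assert gcnr_hist_oracle(x, x) == pytest.approx(0.0, abs=1e-12)
        assert gcnr_hist_oracle(x, x + 100.0, n_bins=200) == pytest.approx(1.0, abs=0.01)

    def test_bin_count_validated(self):
        with pytest.raises(ValueError):
            gcnr_hist_oracle([1.0, 2.0], [1.0, 2.0], n_bins=1)


class TestCells:
    def test_cell_area_values(self):
        assert resolution_cell_area(2.0, 2.0) == pytest.approx(np.pi)
        assert resolution_cell_area(0.440, 0.385) == pytest.approx(0.133, abs=5e-4)

    @pytest.mark.parametrize("lat, ax", [(0.0, 1.0), (1.0, -1.0)])
    def test_cell_area_rejects_nonpositive(self, lat, ax):
        with pytest.raises(ValueError):
            resolution_cell_area(lat, ax)

    def test_count_cells(self):
        roi = split_roi((40, 40))  # 800 px * 0.01 mm^2 = 8 mm^2
        assert count_cells(roi, roi.lesion_area) == pytest.approx(1.0)
        assert count_cells(roi, 0.133) == pytest.approx(8.0 / 0.133, rel=1e-6)
        with pytest.raises(ValueError):
            count_cells(roi, 0.0)


class TestScores:
    def test_zero_contrast_gives_zero_score(self):
        assert snr(0.0, 50.0).score == 0.0
        assert gsnr(0.0, 50.0, f_mode="exact").score == 0.0

    def test_reference_arithmetic(self):
        res = snr(0.559, 60.5)
        assert res.score == pytest.approx(4.348, abs=5e-3)
        assert res.rose_pass

    def test_compounding_scales_as_sqrt_n(self):
        one = snr(0.5, 40.0, 1)
        four = snr(0.5, 40.0, 4)
        assert four.score == pytest.approx(2.0 * one.score)

    def test_gsnr_equals_snr_for_matched_inputs(self):
        cpsi = 0.559
        gcnr = analytic.gcnr_from_cpsi(cpsi)
        a = snr(cpsi, 60.5)
        b = gsnr(gcnr, 60.5, f_mode="exact")
        assert b.score == pytest.approx(a.score, abs=1e-6)

    def test_gompertz_mode_reference_value(self):
        res = gsnr(0.327, 60.5, f_mode="gompertz")
        assert res.score == pytest.approx(4.35, abs=0.02)

    def test_result_consistency_enforced(self):
        with pytest.raises(ValueError):
            DetectabilityResult(0.5, None, 100.0, 1, score=1.0, rose_pass=False)

    @pytest.mark.parametrize("kwargs", [dict(cpsi=1.5, m=10.0), dict(cpsi=0.5, m=-1.0)])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            snr(kwargs["cpsi"], kwargs["m"])

    def test_gsnr_rejects_unknown_bridge(self):
        with pytest.raises(ValueError):
            gsnr(0.3, 10.0, f_mode="spline")
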