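"""Window cropping and Gaussian peak fitting, checked against closed forms
and a brute-force grid-search oracle."""

import numpy as np
import pytest

from sersquant import (
    PYRENE,
    AcquisitionGrid,
    ResponseModel,
    SpectralWindow,
    Spectrum,
    crop_window,
    estimate_blank_noise,
    fit_gaussian_peak,
    gaussian_area,
    generate_spectrum,
)
from conftest import make_gaussian_spectrum

AREA_CONST = np.sqrt(np.pi / (4.0 * np.log(2.0)))


class TestCropWindow:
    @pytest.mark.parametrize(
        "window,expected_points",
        [
            (SpectralWindow(500, 600), 51),
            (SpectralWindow(350, 405), 28),  # 350, 352, ..., 404
            (SpectralWindow(1190, 1250), 31),
        ],
    )
    def test_point_counts_on_step2_grid(self, grid, window, expected_points):
        sp = Spectrum(grid, np.zeros(len(grid)))
        assert len(crop_window(sp, window).intensities) == expected_points

    def test_full_grid_window_is_identity(self, grid):
        sp = Spectrum(grid, np.arange(len(grid), dtype=float))
        sub = crop_window(sp, SpectralWindow(grid.start, grid.stop))
        assert np.array_equal(sub.intensities, sp.intensities)

    def test_empty_overlap_names_window(self, grid):
        sp = Spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError, match="1900-1950"):
            crop_window(sp, SpectralWindow(1900, 1950))


class TestGaussianFit:
    def test_exact_recovery_on_noiseless_model(self, grid):
        sp = make_gaussian_spectrum(grid, 586.0, 100.0, 20.0)
        fit = fit_gaussian_peak(sp, SpectralWindow(500, 600))
        assert fit.converged
        assert fit.center == pytest.approx(586.0, rel=1e-6)
        assert fit.height == pytest.approx(100.0, rel=1e-6)
        assert fit.fwhm == pytest.approx(20.0, rel=1e-6)

    def test_offset_invariance(self, grid):
        base = make_gaussian_spectrum(grid, 560.0, 80.0, 18.0)
        shifted = Spectrum(grid, base.intensities + 500.0)
        f0 = fit_gaussian_peak(base, SpectralWindow(500, 600))
        f1 = fit_gaussian_peak(shifted, SpectralWindow(500, 600))
        assert f1.height == pytest.approx(f0.height, rel=1e-8)
        assert f1.offset == pytest.approx(f0.offset + 500.0, abs=1e-6)

    def test_area_identity(self, grid):
        sp = make_gaussian_spectrum(grid, 550.0, 42.0, 13.0, offset=5.0)
        fit = fit_gaussian_peak(sp, SpectralWindow(500, 600))
        assert fit.area == pytest.approx(fit.height * fit.fwhm * AREA_CONST, rel=1e-9)

    def test_matches_grid_search_oracle_on_noisy_peak(self, grid):
        # independent oracle: exhaustive search over (center, height, FWHM)
        # at 0.1-unit granularity, offset profiled out by its mean residual
        rng = np.random.default_rng(21)
        sp = make_gaussian_spectrum(grid, 586.0, 100.0, 20.0)
        noisy = Spectrum(grid, sp.intensities + rng.normal(0, 2.0, len(grid)))
        window = SpectralWindow(500, 600)
        sub = crop_window(noisy, window)
        x, y = sub.wavenumbers, sub.intensities

        best = (np.inf, None)
        for c in np.arange(584.0, 588.01, 0.1):
            for h in np.arange(95.0, 105.01, 0.1):
                for w in np.arange(18.0, 22.01, 0.1):
                    s = w / (2 * np.sqrt(2 * np.log(2)))
                    g = h * np.exp(-((x - c) ** 2) / (2 * s**2))
                    b = float(np.mean(y - g))
                    rss = float(np.sum((g + b - y) ** 2))
                    if rss < best[0]:
                        best = (rss, (c, h, w))
        c_o, h_o, w_o = best[1]
        fit = fit_gaussian_peak(noisy, window)
        assert fit.center == pytest.approx(c_o, abs=0.1)
        assert fit.height == pytest.approx(h_o, abs=0.2)
        assert fit.fwhm == pytest.approx(w_o, abs=0.2)

    def test_pyrene_band_recovered_near_586(self, grid):
        sp = generate_spectrum(PYRENE, ResponseModel(), grid, 10.0, seed=4)
        fit = fit_gaussian_peak(sp, SpectralWindow(500, 600))
        assert fit.center == pytest.approx(586.0, abs=2.0)

    def test_flat_window_rejected(self, grid):
        sp = Spectrum(grid, np.full(len(grid), 7.0))
        with pytest.raises(ValueError, match="flat"):
            fit_gaussian_peak(sp, SpectralWindow(500, 600))

    def test_tiny_window_rejected(self):
        grid = AcquisitionGrid(500, 600, 30.0)
        sp = Spectrum(grid, np.arange(len(grid), dtype=float))
        with pytest.raises(ValueError, match="points"):
            fit_gaussian_peak(sp, SpectralWindow(500, 600))


class TestBlankNoise:
    def test_identical_blanks_give_zero(self, grid):
        sp = make_gaussian_spectrum(grid, 550.0, 5.0, 15.0)
        assert estimate_blank_noise([sp, sp, sp], SpectralWindow(500, 600)) == 0.0

    def test_sample_sd_convention(self, grid):
        # three noiseless blanks with known fitted heights: the estimate is
        # the ddof=1 sample sd of the statistic
        heights = [4.0, 7.0, 13.0]
        blanks = [make_gaussian_spectrum(grid, 550.0, h, 15.0) for h in heights]
        est = estimate_blank_noise(blanks, SpectralWindow(500, 600))
        assert est == pytest.approx(np.std(heights, ddof=1), rel=1e-6)

    def test_matches_monte_carlo_oracle(self, grid):
        # blanks = white noise; the estimator should agree with an
        # independent Monte-Carlo rerun of the same statistic's sd
        def make_blanks(seed, n):
            rng = np.random.default_rng(seed)
            return [
                Spectrum(grid, rng.normal(0.0, 3.0, len(grid))) for _ in range(n)
            ]

        window = SpectralWindow(500, 600)
        est = estimate_blank_noise(make_blanks(1, 200), window, statistic="max")
        oracle = estimate_blank_noise(make_blanks(2, 200), window, statistic="max")
        assert est == pytest.approx(oracle, rel=0.25)

    def test_requires_three_blanks(self, grid):
        sp = Spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError, match=">= 3"):
            estimate_blank_noise([sp, sp], SpectralWindow(500, 600))


def test_gaussian_area_constant():
    assert gaussian_area(2.0, 3.0) == pytest.approx(6.0 * AREA_CONST, rel=1e-12)
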