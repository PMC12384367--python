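"""Peak fitting and spectral-window segmentation.

A spectrum is divided into fixed wavenumber windows chosen around the
characteristic bands of the analyte/reference pair (350-405, 410-490,
500-600 and 1190-1250 cm^-1 by default), and each characteristic band is
summarised by a single-Gaussian least-squares fit

    y(x) = height * exp(-(x - center)^2 / (2 sigma^2)) + offset

reported as height, FWHM (= sigma * 2 sqrt(2 ln 2)), area
(= height * FWHM * sqrt(pi / (4 ln 2))) and residual RMS.  The constant
offset absorbs any locally flat background, so the fit is invariant to
adding a constant to the spectrum.  Windows are always expressed in physical
wavenumbers, never array indices, and both endpoints are kept when they fall
on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import AcquisitionGrid, Spectrum

__all__ = [
    "SpectralWindow",
    "DEFAULT_WINDOWS",
    "PeakFit",
    "crop_window",
    "fit_gaussian_peak",
    "estimate_blank_noise",
    "gaussian_area",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_AREA_PER_HEIGHT_FWHM = np.sqrt(np.pi / (4.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralWindow:
    """Closed wavenumber interval [low, high] in cm^-1."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError(f"window low must be < high, got [{self.low}, {self.high}]")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low:g}-{self.high:g}"


#: The four analysis windows bracketing the characteristic bands.
DEFAULT_WINDOWS: tuple[SpectralWindow, ...] = (
    SpectralWindow(350.0, 405.0),
    SpectralWindow(410.0, 490.0),
    SpectralWindow(500.0, 600.0),
    SpectralWindow(1190.0, 1250.0),
)


@dataclass(frozen=True)
class PeakFit:
    """Gaussian band parameters from a single-peak fit."""

    center: float
    height: float
    fwhm: float
    area: float
    offset: float
    residual_rms: float
    converged: bool = True

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM_PER_SIGMA


def gaussian_area(height: float, fwhm: float) -> float:
    """Analytic area of a Gaussian band: height * FWHM * sqrt(pi/(4 ln 2))."""
    return height * fwhm * _AREA_PER_HEIGHT_FWHM


def crop_window(spectrum: Spectrum, window: SpectralWindow) -> Spectrum:
    """Return the sub-spectrum on [low, high]; both endpoints inclusive."""
    x = spectrum.wavenumbers
    tol = 1e-9 * max(1.0, spectrum.grid.step)
    mask = (x >= window.low - tol) & (x <= window.high + tol)
    if not mask.any():
        raise ValueError(
            f"window {window} cm^-1 has no overlap with the grid "
            f"[{spectrum.grid.start}, {spectrum.grid.stop}] cm^-1"
        )
    xs = x[mask]
    grid = AcquisitionGrid(float(xs[0]), float(xs[-1]), spectrum.grid.step)
    return Spectrum(
        grid,
        spectrum.intensities[mask],
        concentration=spectrum.concentration,
        replicate_id=spectrum.replicate_id,
        seed_used=spectrum.seed_used,
    )


def _gauss_offset(x: np.ndarray, height: float, center: float, sigma: float, offset: float):
    return height * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset


def fit_gaussian_peak(
    spectrum: Spectrum,
    window: SpectralWindow,
    init: PeakFit | None = None,
    max_restarts: int = 5,
) -> PeakFit:
    """Least-squares single-Gaussian (plus constant offset) fit in a window.

    Initialisation: center at the window argmax, height at max-minus-min,
    FWHM at a quarter of the window width, unless ``init`` overrides it.  On
    non-convergence the center is jittered across the window for up to
    ``max_restarts`` further attempts; if none converges the best attempt is
    returned flagged ``converged=False`` rather than raising.
    """
    sub = crop_window(spectrum, window)
    x, y = sub.wavenumbers, sub.intensities
    if len(x) < 5:
        raise ValueError(f"window {window} contains only {len(x)} points; need >= 5")
    if np.ptp(y) == 0:
        raise ValueError(f"window {window} is flat; nothing to fit")

    width = window.high - window.low
    if init is not None:
        p0 = [init.height, init.center, init.sigma, init.offset]
    else:
        p0 = [float(np.max(y) - np.min(y)), float(x[np.argmax(y)]), width / 4.0 / _FWHM_PER_SIGMA,
              float(np.min(y))]

    # deterministic jittered restart centers spread over the window
    centers = [p0[1]] + [
        window.low + (i + 0.5) / max_restarts * width for i in range(max_restarts)
    ]
    lower = [0.0, window.low, spectrum.grid.step / 4.0, -np.inf]
    upper = [np.inf, window.high, 2.0 * width, np.inf]

    best: tuple[float, np.ndarray] | None = None
    converged = False
    for c0 in centers:
        trial = [p0[0], float(np.clip(c0, window.low, window.high)),
                 float(np.clip(p0[2], lower[2], upper[2])), p0[3]]
        try:
            popt, _ = curve_fit(
                _gauss_offset, x, y, p0=trial, bounds=(lower, upper), maxfev=5000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_gauss_offset(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
        converged = True
        if rss <= 1e-18 * max(1.0, float(np.sum(y**2))):
            break  # exact recovery; no point restarting
    if best is None:
        # every attempt failed: report the initial guess, flagged
        height, center, sigma, offset = p0
        resid = float(np.sqrt(np.mean((_gauss_offset(x, *p0) - y) ** 2)))
        return PeakFit(center, height, sigma * _FWHM_PER_SIGMA,
                       gaussian_area(height, sigma * _FWHM_PER_SIGMA),
                       offset, resid, converged=False)
    _, (height, center, sigma, offset) = best
    fwhm = sigma * _FWHM_PER_SIGMA
    resid = float(np.sqrt(np.mean((_gauss_offset(x, height, center, sigma, offset) - y) ** 2)))
    return PeakFit(float(center), float(height), float(fwhm),
                   float(gaussian_area(height, fwhm)), float(offset), resid,
                   converged=converged)


def estimate_blank_noise(
    blank_spectra: Sequence[Spectrum],
    window: SpectralWindow,
    statistic: Literal["fit_height", "max"] = "fit_height",
) -> float:
    """Blank-noise term of the SNR: sd of a peak statistic across blanks.

    ``fit_height`` uses the fitted Gaussian height in the window (the same
    statistic used as the calibration signal); ``max`` uses max-minus-median
    intensity.  Needs at least 3 blank spectra.
    """
    if len(blank_spectra) < 3:
        raise ValueError(f"need >= 3 blank spectra, got {len(blank_spectra)}")
    vals = []
    for sp in blank_spectra:
        sub = crop_window(sp, window)
        if statistic == "max":
            vals.append(float(np.max(sub.intensities) - np.median(sub.intensities)))
        elif statistic == "fit_height":
            if np.ptp(sub.intensities) == 0:
                vals.append(0.0)
            else:
                vals.append(fit_gaussian_peak(sp, window).height)
        else:
            raise ValueError(f"unknown blank statistic {statistic!r}")
    return float(np.std(vals, ddof=1))
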