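"""Univariate calibration, limit of detection at SNR = 3, and replicate RSD.

The calibration signal is the fitted 586 cm^-1 peak height.  Because the
calibration series spans four decades of concentration, the default axis
fits intensity against log10(concentration); a plain linear axis is also
available.  The limit of detection follows the SNR = 3 convention: the
concentration whose expected signal rise equals three times the blank-noise
standard deviation, i.e. LOD = T^-1(3 * sigma_blank / slope) with T the
calibration axis transform (identity or log10).

RSD is the replicate-uniformity statistic: 100 * sample sd / mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["CalibrationResult", "fit_calibration", "compute_lod", "rsd"]

AxisTransform = Literal["log10", "linear"]


@dataclass
class CalibrationResult:
    """Ordinary-least-squares calibration line plus (optionally) the LOD."""

    slope: float
    intercept: float
    r_squared: float
    transform: AxisTransform
    blank_noise_sd: float | None = None
    lod: float | None = None

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "transform": self.transform,
            "blank_noise_sd": self.blank_noise_sd,
            "lod_ppm": self.lod,
        }


def _transform(levels: np.ndarray, transform: AxisTransform) -> np.ndarray:
    if transform == "log10":
        if np.any(levels <= 0):
            raise ValueError("log10 axis needs strictly positive concentrations")
        return np.log10(levels)
    if transform == "linear":
        return levels
    raise ValueError(f"unknown axis transform {transform!r}")


def fit_calibration(
    levels: Sequence[float],
    intensities: Sequence[float],
    transform: AxisTransform = "log10",
) -> CalibrationResult:
    """OLS fit of signal intensity on (transformed) concentration.

    Closed-form slope/intercept/R^2; needs at least 3 distinct levels and a
    non-constant signal (otherwise R^2 is undefined).
    """
    levels = np.asarray(levels, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if levels.shape != intensities.shape:
        raise ValueError("levels and intensities must have equal length")
    if len(np.unique(levels)) < 3:
        raise ValueError(f"calibration needs >= 3 distinct levels, got {len(np.unique(levels))}")
    if np.ptp(intensities) == 0:
        raise ValueError("constant intensities: slope 0, R^2 undefined")
    x = _transform(levels, transform)
    # closed-form normal equations
    xm, ym = x.mean(), intensities.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (intensities - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = intensities - (slope * x + intercept)
    ss_tot = float(np.sum((intensities - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationResult(float(slope), float(intercept), float(r2), transform)


def compute_lod(cal: CalibrationResult, blank_noise_sd: float) -> float:
    """Limit of detection at SNR = 3 on the calibration's axis.

    The signal rise 3 * sigma_blank is converted to concentration through the
    calibration slope, then inverted through the axis transform: on a linear
    axis this is the classical 3 sigma / slope; on the log10 axis it is
    10 ** (3 sigma / slope).
    """
    if cal.slope <= 0:
        raise ValueError(f"LOD needs a positive calibration slope, got {cal.slope}")
    if blank_noise_sd < 0:
        raise ValueError(f"blank noise sd must be >= 0, got {blank_noise_sd}")
    if blank_noise_sd == 0:
        warnings.warn("blank noise sd is 0; LOD reported as 0", RuntimeWarning, stacklevel=2)
    x_lod = 3.0 * blank_noise_sd / cal.slope
    if cal.transform == "log10":
        # x_lod is a rise in log10(ppm); 0 noise maps to LOD 0 by convention
        return 0.0 if blank_noise_sd == 0 else float(10.0**x_lod)
    return float(x_lod)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sample sd / mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError(f"RSD needs >= 2 values, got {len(values)}")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD is undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)
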