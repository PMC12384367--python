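import numpy as np
import pytest

from sersquant import (
    PYRENE,
    AcquisitionGrid,
    AnalyteLibrary,
    PeakSpec,
    ResponseModel,
    Spectrum,
    generate_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return AcquisitionGrid(200.0, 1800.0, 2.0)


@pytest.fixture(scope="session")
def clean_response():
    """Noise- and baseline-free response: deterministic Langmuir signal."""
    return ResponseModel(replicate_cv=0.0, noise_sd=0.0, baseline_coeffs=(0.0,))


@pytest.fixture(scope="session")
def single_peak_library():
    return AnalyteLibrary("pyrene-main-band", (PeakSpec(586.0, 1.0, 14.0),))


@pytest.fixture(scope="session")
def default_dataset(grid):
    """One realisation of the default study conditions (seed 7)."""
    return generate_dataset(PYRENE, ResponseModel(), grid, seed=7)


def make_gaussian_spectrum(grid, center, height, fwhm, offset=0.0):
    x = grid.wavenumbers()
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = height * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset
    return Spectrum(grid, y)
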