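"""Synthetic SERS spectrum generator.

Emulates a TLC-SERS acquisition of a trace analyte (pyrene in edible oil is
the canonical use case): Gaussian bands on a smooth baseline, a Langmuir
(saturating-adsorption) signal-vs-concentration response, a per-spectrum
multiplicative lognormal replicate factor, and additive white detector noise.

The statistical structure mirrors what the downstream chemometrics assumes:

* band intensity follows ``A(c) = i_max * k_ads * c / (1 + k_ads * c)`` —
  SERS signal saturates as the finite adsorption sites of the plasmonic
  substrate fill up, so the response is linear only at trace levels;
* replicate-to-replicate scatter is a single lognormal factor shared by all
  bands of one spectrum (substrate-spot enhancement variability), with a
  default coefficient of variation of 9.6 %, the replicate RSD reported for
  the diatomite/Ag substrate this generator emulates;
* a gentle polynomial baseline (oil/substrate background) plus white noise.

All randomness is explicit: each spectrum is produced from one integer seed,
and dataset-level seeds are derived deterministically from a master seed and
the (level, replicate) position, so identical inputs give byte-identical
output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakSpec",
    "AnalyteLibrary",
    "ResponseModel",
    "AcquisitionGrid",
    "Spectrum",
    "PYRENE",
    "R6G",
    "DEFAULT_LEVELS_PPM",
    "generate_spectrum",
    "generate_dataset",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: center (cm^-1), relative amplitude, FWHM (cm^-1)."""

    center: float
    rel_amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"peak FWHM must be > 0, got {self.fwhm}")
        if self.rel_amplitude < 0:
            raise ValueError(
                f"peak rel_amplitude must be >= 0, got {self.rel_amplitude}"
            )

    @property
    def sigma(self) -> float:
        """Gaussian sigma equivalent of the FWHM."""
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AnalyteLibrary:
    """Named set of bands characterising one analyte."""

    name: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("an analyte library needs at least one peak")
        centers = [p.center for p in self.peaks]
        if len(set(centers)) != len(centers):
            raise ValueError(f"duplicate peak centers in library {self.name!r}")


#: Pyrene on the TLC-SERS substrate: the dominant band sits at 586 cm^-1;
#: a weaker ring-breathing band near 1240 cm^-1 gives the 1190-1250 window
#: some analyte signal, as in real pyrene spectra.
PYRENE = AnalyteLibrary("pyrene", (PeakSpec(586.0, 1.0, 14.0), PeakSpec(1240.0, 0.3, 16.0)))

#: Rhodamine 6G reference bands (C-O-C stretch at 308; aromatic C-C at
#: 1194 / 1360 / 1508 cm^-1).
R6G = AnalyteLibrary(
    "rhodamine-6g",
    (
        PeakSpec(308.0, 0.5, 12.0),
        PeakSpec(1194.0, 0.7, 14.0),
        PeakSpec(1360.0, 1.0, 14.0),
        PeakSpec(1508.0, 0.9, 14.0),
    ),
)

#: Default calibration series: 9 log-spaced levels spanning the 0.01-70 ppm
#: range of the emulated acquisition.
DEFAULT_LEVELS_PPM: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 30.0, 70.0)


@dataclass(frozen=True)
class ResponseModel:
    """Signal response and noise settings of the emulated instrument.

    Parameters
    ----------
    i_max : float
        Saturated band intensity (counts) of a unit-amplitude peak.
    k_ads : float
        Langmuir saturation constant (1/ppm).  The default 0.05/ppm puts the
        0.01-70 ppm series across the linear through near-saturated regimes.
    replicate_cv : float
        Coefficient of variation of the per-spectrum lognormal enhancement
        factor (default 0.096 = the substrate's replicate RSD of 9.6 %).
    noise_sd : float
        Additive white-noise standard deviation (counts).
    baseline_coeffs : tuple of float
        Polynomial coefficients (ascending order) of the background, evaluated
        in the normalised coordinate t = (x - start)/(stop - start) in [0, 1].
    """

    i_max: float = 1000.0
    k_ads: float = 0.05
    replicate_cv: float = 0.096
    noise_sd: float = 10.0
    baseline_coeffs: tuple[float, ...] = (20.0, 10.0, -15.0)

    def __post_init__(self) -> None:
        if self.i_max <= 0:
            raise ValueError(f"i_max must be > 0, got {self.i_max}")
        if self.k_ads <= 0:
            raise ValueError(f"k_ads must be > 0, got {self.k_ads}")
        if self.replicate_cv < 0:
            raise ValueError(f"replicate_cv must be >= 0, got {self.replicate_cv}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def amplitude(self, concentration: float | np.ndarray) -> float | np.ndarray:
        """Mean band amplitude at a concentration: Langmuir isotherm."""
        kc = self.k_ads * np.asarray(concentration, dtype=float)
        return self.i_max * kc / (1.0 + kc)


@dataclass(frozen=True)
class AcquisitionGrid:
    """Uniform wavenumber grid (cm^-1), endpoints inclusive."""

    start: float = 200.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError(f"grid start must be < stop, got [{self.start}, {self.stop}]")
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")

    def __len__(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))


#: Spectrometer-like preset matching a 5 cm^-1 instrument resolution.
INSTRUMENT_GRID_5CM = AcquisitionGrid(200.0, 1800.0, 5.0)


@dataclass
class Spectrum:
    """A single acquired (or simulated) spectrum with its metadata.

    ``concentration`` is None for unknowns; ``seed_used`` records the integer
    that reproduces the realisation exactly.
    """

    grid: AcquisitionGrid
    intensities: np.ndarray
    concentration: float | None = None
    replicate_id: int = 0
    seed_used: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError(
                f"intensity vector of length {self.intensities.shape} does not "
                f"match grid of length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum intensities must be finite")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.wavenumbers()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _baseline(response: ResponseModel, grid: AcquisitionGrid) -> np.ndarray:
    t = (grid.wavenumbers() - grid.start) / (grid.stop - grid.start)
    return np.polynomial.polynomial.polyval(t, np.asarray(response.baseline_coeffs, dtype=float))


def generate_spectrum(
    library: AnalyteLibrary,
    response: ResponseModel,
    grid: AcquisitionGrid,
    concentration: float,
    seed: int,
) -> Spectrum:
    """Simulate one spectrum of ``library`` at ``concentration`` ppm.

    The model is ``baseline(x) + eps * A(c) * sum_k a_k g_k(x) + n(x)`` with
    ``A`` the Langmuir response, ``eps`` a lognormal unit-mean factor with
    CV = ``replicate_cv`` shared by all bands, and ``n`` white Gaussian noise.
    The same seed always reproduces the same spectrum.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    x = grid.wavenumbers()
    for p in library.peaks:
        if not (grid.start <= p.center <= grid.stop):
            raise ValueError(
                f"peak center {p.center} cm^-1 of {library.name!r} lies outside "
                f"the grid [{grid.start}, {grid.stop}] cm^-1"
            )

    rng = np.random.default_rng(seed)
    # unit-mean lognormal: E[eps]=1, sd(eps)/E[eps]=replicate_cv
    if response.replicate_cv > 0:
        s2 = np.log1p(response.replicate_cv**2)
        eps = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2))
    else:
        eps = 1.0

    amp = float(response.amplitude(concentration))
    signal = np.zeros_like(x)
    for p in library.peaks:
        signal += p.rel_amplitude * np.exp(-((x - p.center) ** 2) / (2.0 * p.sigma**2))
    y = _baseline(response, grid) + eps * amp * signal
    if response.noise_sd > 0:
        y = y + rng.normal(0.0, response.noise_sd, size=x.shape)
    return Spectrum(grid, y, concentration=concentration, seed_used=int(seed))


def spectrum_seed(master_seed: int, level_index: int, replicate_index: int) -> int:
    """Deterministic per-spectrum seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(level_index), int(replicate_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    library: AnalyteLibrary,
    response: ResponseModel,
    grid: AcquisitionGrid,
    levels: Sequence[float] = DEFAULT_LEVELS_PPM,
    replicates: int = 20,
    seed: int = 0,
) -> list[Spectrum]:
    """Simulate a full calibration series: ``levels x replicates`` spectra.

    Defaults emulate the acquisition the analysis targets: 9 log-spaced
    concentrations spanning 0.01-70 ppm with 20 replicate measurements per
    level.
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if any(c < 0 for c in levels):
        raise ValueError("all concentration levels must be >= 0")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    out: list[Spectrum] = []
    for li, level in enumerate(levels):
        for ri in range(replicates):
            sp = generate_spectrum(
                library, response, grid, float(level), spectrum_seed(seed, li, ri)
            )
            sp.replicate_id = ri
            out.append(sp)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column CSV ``wavenumber_cm1,intensity``."""
    df = pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumbers, "intensity": spectrum.intensities}
    )
    df.to_csv(path, index=False)


def read_spectrum_csv(
    path: str | os.PathLike,
    concentration: float | None = None,
    replicate_id: int = 0,
) -> Spectrum:
    """Read a two-column spectrum CSV written by :func:`write_spectrum_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavenumber_cm1", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    w = df["wavenumber_cm1"].to_numpy(dtype=float)
    if len(w) < 2:
        raise ValueError(f"{path}: spectrum needs at least 2 points")
    steps = np.diff(w)
    step = float(np.median(steps))
    if not np.allclose(steps, step, rtol=0, atol=1e-6 * max(1.0, abs(step))):
        raise ValueError(f"{path}: wavenumber grid is not uniform")
    grid = AcquisitionGrid(float(w[0]), float(w[-1]), step)
    return Spectrum(
        grid,
        df["intensity"].to_numpy(dtype=float),
        concentration=concentration,
        replicate_id=replicate_id,
    )


def write_dataset(
    spectra: Sequence[Spectrum], directory: str | os.PathLike, prefix: str = "spectrum"
) -> str:
    """Write spectra plus a ``path,concentration_ppm,replicate`` manifest.

    Returns the manifest path.  Unknown concentrations are left blank.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, sp in enumerate(spectra):
        fname = f"{prefix}_{i:04d}.csv"
        write_spectrum_csv(sp, os.path.join(directory, fname))
        rows.append(
            {
                "path": fname,
                "concentration_ppm": "" if sp.concentration is None else sp.concentration,
                "replicate": sp.replicate_id,
            }
        )
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows, columns=["path", "concentration_ppm", "replicate"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_dataset(manifest_path: str | os.PathLike) -> list[Spectrum]:
    """Load all spectra listed in a manifest (paths relative to the manifest)."""
    manifest_path = os.fspath(manifest_path)
    base = os.path.dirname(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"path", "concentration_ppm", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{manifest_path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    spectra = []
    for _, row in df.iterrows():
        p = row["path"]
        full = p if os.path.isabs(p) else os.path.join(base, p)
        if not os.path.exists(full):
            raise FileNotFoundError(f"manifest entry not found: {full}")
        conc = row["concentration_ppm"]
        conc = None if pd.isna(conc) else float(conc)
        spectra.append(read_spectrum_csv(full, concentration=conc, replicate_id=int(row["replicate"])))
    return spectra
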