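"""Per-window PCA and variance-contribution region selection.

Each spectral window is mean-centered (never variance-scaled: peak height is
the signal) and decomposed with PCA.  A window's *variance contribution
rate* is the fraction of its total spectral variance captured by the leading
principal component; the window with the highest rate is the one whose
variation is most one-dimensional — in a calibration series that is the
window dominated by the concentration-responsive band — and is selected as
the regression input region.

The rate definition is isolated in :func:`variance_contribution` so an
alternative (e.g. a top-k sum) is a one-line change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .preprocessing import SpectralWindow, crop_window
from .synthetic import Spectrum

__all__ = ["RegionPCA", "fit_region_pca", "select_region", "variance_contribution"]


@dataclass
class RegionPCA:
    """PCA of one spectral window over a set of spectra.

    ``loadings`` is (components x wavenumbers) with orthonormal rows, sign
    fixed so each row's largest-magnitude entry is positive; ``scores`` is
    (samples x components) and reproduces ``(X - mean) @ loadings.T``.
    ``explained_fraction`` is relative to the window's *total* variance, so
    it sums to 1 only when every component is retained.
    """

    window: SpectralWindow
    mean_vector: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray

    @property
    def variance_contribution(self) -> float:
        return variance_contribution(self)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new window data onto the fitted components."""
        return (np.asarray(X, dtype=float) - self.mean_vector) @ self.loadings.T


def variance_contribution(pca: RegionPCA) -> float:
    """Variance-contribution rate: PC1's share of the window's total variance."""
    return float(pca.explained_fraction[0])


def window_matrix(spectra: Sequence[Spectrum], window: SpectralWindow) -> np.ndarray:
    """Stack the cropped window intensities into a (samples x points) matrix."""
    return np.vstack([crop_window(sp, window).intensities for sp in spectra])


def fit_region_pca(
    spectra: Sequence[Spectrum], window: SpectralWindow, n_components: int
) -> RegionPCA:
    """Mean-centered PCA of one window across spectra.

    Deterministic up to component sign, which is fixed by making the
    largest-magnitude loading entry of each component positive.  Components
    beyond the effective rank of the data are dropped with a warning.
    """
    if len(spectra) < 2:
        raise ValueError(f"PCA needs >= 2 spectra, got {len(spectra)}")
    X = window_matrix(spectra, window)
    n_max = min(X.shape)
    if n_components > n_max:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_points)={n_max}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    ev = pca.explained_variance_
    # drop numerically-zero directions beyond the data's rank
    total = float(np.sum(ev)) if ev.size else 0.0
    keep = ev > max(total, 1.0) * 1e-12
    if not np.all(keep):
        warnings.warn(
            f"window {window}: data rank supports only {int(keep.sum())} of "
            f"{n_components} requested components; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        scores, loadings, ev = scores[:, keep], loadings[keep], ev[keep]
        ratio = pca.explained_variance_ratio_[keep]
    else:
        ratio = pca.explained_variance_ratio_

    # sign convention: largest-|entry| of each loading row positive
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]

    return RegionPCA(
        window=window,
        mean_vector=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_fraction=np.asarray(ratio, dtype=float),
    )


def select_region(
    spectra: Sequence[Spectrum],
    windows: Sequence[SpectralWindow],
    n_components: int | None = None,
) -> tuple[SpectralWindow, list[RegionPCA]]:
    """Pick the window with the highest variance-contribution rate.

    Returns the winning window plus every per-window :class:`RegionPCA` for
    reporting.  Ties break toward the lower wavenumber bound, so the result
    is deterministic.
    """
    if len(windows) < 1:
        raise ValueError("select_region needs at least one window")
    results: list[RegionPCA] = []
    for w in windows:
        X = window_matrix(spectra, w)  # raises if the window misses the grid
        k = n_components if n_components is not None else min(5, min(X.shape))
        results.append(fit_region_pca(spectra, w, min(k, min(X.shape))))
    order = sorted(
        range(len(windows)),
        key=lambda i: (-results[i].variance_contribution, windows[i].low),
    )
    return windows[order[0]], results
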