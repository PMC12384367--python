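"""Concentration regression: the PCA-BP network and a PLSR comparator.

The predictive model is a small 1-D convolutional + dense network ("PCA-BP":
principal-component features in, backprop-trained regressor out).  Its fixed
architecture is four valid-padding Conv1D stages (filters, kernel) =
(32, 4), (64, 4), (128, 2), (256, 1), a flatten, dense layers of 400, 200,
100 and 50 ReLU units, and a single sigmoid output.  The sigmoid output is
mapped to concentration through an affine transform of log10(c) (the
*concentration scaler*), because the calibration range spans four decades
and the output is bounded in (0, 1).  Training minimises mean squared error
on the scaled target plus an L2 weight penalty, with full-batch Adam and
early stopping on a held-out validation split.

The network is implemented directly in numpy with analytic backpropagation
— it is small enough (a few hundred thousand parameters on a length-16
input) that no tensor framework is needed — and the analytic gradient is
validated against finite differences in the test suite.

A partial-least-squares regression (PLSR) model fitted on the same window
data and the same scaled target serves as the linear comparator.

Everything is deterministic given a seed: weight initialisation, the
train/validation split, and full-batch gradient descent contain no hidden
randomness, so identical config + seed reproduces identical weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .features import RegionPCA, fit_region_pca, window_matrix
from .preprocessing import SpectralWindow, fit_gaussian_peak
from .synthetic import Spectrum

__all__ = [
    "ConcentrationScaler",
    "NetworkArchitecture",
    "TrainConfig",
    "RegressionReport",
    "PCABPModel",
    "PLSRModel",
    "train_pca_bp",
    "fit_plsr",
    "evaluate",
    "init_params",
    "forward_pass",
    "loss_and_grad",
    "layer_output_shapes",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# concentration scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationScaler:
    """Affine log10 map between ppm and the sigmoid's (0, 1) range.

    ``forward(c_min) = margin`` and ``forward(c_max) = 1 - margin``; the
    margin keeps targets away from the sigmoid asymptotes.
    """

    c_min: float
    c_max: float
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.c_min <= 0 or self.c_max <= self.c_min:
            raise ValueError(
                f"need 0 < c_min < c_max, got c_min={self.c_min}, c_max={self.c_max}"
            )
        if not (0 <= self.margin < 0.5):
            raise ValueError(f"margin must be in [0, 0.5), got {self.margin}")

    def forward(self, c: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(c, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be > 0 for log scaling")
        lo, hi = np.log10(self.c_min), np.log10(self.c_max)
        if np.any(c < self.c_min) or np.any(c > self.c_max):
            warnings.warn(
                "concentration outside the scaler range; clipping", RuntimeWarning,
                stacklevel=2,
            )
            c = np.clip(c, self.c_min, self.c_max)
        f = self.margin + (1.0 - 2.0 * self.margin) * (np.log10(c) - lo) / (hi - lo)
        return float(f) if f.ndim == 0 else f

    def inverse(self, f: float | np.ndarray) -> float | np.ndarray:
        f = np.asarray(f, dtype=float)
        lo, hi = np.log10(self.c_min), np.log10(self.c_max)
        logc = lo + (f - self.margin) * (hi - lo) / (1.0 - 2.0 * self.margin)
        c = 10.0**logc
        return float(c) if c.ndim == 0 else c


# ---------------------------------------------------------------------------
# network definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkArchitecture:
    """Conv/dense stack sizes; fixed defaults are the reference architecture."""

    conv_stages: tuple[tuple[int, int], ...] = ((32, 4), (64, 4), (128, 2), (256, 1))
    dense_widths: tuple[int, ...] = (400, 200, 100, 50)
    l2_lambda: float = 1e-4

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError(f"l2_lambda must be >= 0, got {self.l2_lambda}")


def layer_output_shapes(arch: NetworkArchitecture, input_length: int) -> list:
    """Shapes traversed by the forward pass, ending in the scalar output.

    Valid (no-padding) convolutions; kernels wider than the running sequence
    length are clipped to it, so short feature vectors still pass through.
    """
    shapes: list = []
    L = input_length
    for filters, kernel in arch.conv_stages:
        k = min(kernel, L)
        L = L - k + 1
        shapes.append((filters, L))
    flat = arch.conv_stages[-1][0] * L if arch.conv_stages else L
    shapes.append(flat)
    shapes.extend(arch.dense_widths)
    shapes.append(1)
    return shapes


def init_params(
    arch: NetworkArchitecture, input_length: int, rng: np.random.Generator
) -> list[dict]:
    """He-initialised weights for the conv/dense stack, zero biases."""
    params: list[dict] = []
    cin, L = 1, input_length
    for filters, kernel in arch.conv_stages:
        k = min(kernel, L)
        fan_in = cin * k
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, cin, k))
        params.append({"kind": "conv", "W": W, "b": np.zeros(filters)})
        cin, L = filters, L - k + 1
    width = cin * L
    for w in arch.dense_widths:
        Wd = rng.normal(0.0, np.sqrt(2.0 / width), size=(w, width))
        params.append({"kind": "dense", "W": Wd, "b": np.zeros(w)})
        width = w
    # small output-layer init keeps the initial sigmoid near 0.5 regardless of
    # the hidden activations' scale (a saturated output has ~zero gradient)
    Wo = rng.normal(0.0, 0.01, size=(1, width))
    params.append({"kind": "out", "W": Wo, "b": np.zeros(1)})
    return params


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(params: list[dict], X: np.ndarray) -> tuple[np.ndarray, list]:
    """Forward pass with cache; X is (n_samples, input_length)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected 2-D input (samples x features), got shape {X.shape}")
    h = X[:, None, :]  # (n, channels=1, length)
    cache: list = []
    for layer in params:
        if layer["kind"] == "conv":
            W, b = layer["W"], layer["b"]
            cout, cin, k = W.shape
            n, _, L = h.shape
            if L < k:
                raise ValueError(
                    f"conv kernel {k} wider than sequence length {L}; "
                    f"expected input compatible with the trained architecture"
                )
            Lout = L - k + 1
            # im2col: (n, cin, Lout, k) -> (n*Lout, cin*k), conv as one matmul
            xs = np.lib.stride_tricks.sliding_window_view(h, k, axis=2)
            xcol = np.ascontiguousarray(xs.transpose(0, 2, 1, 3)).reshape(n * Lout, cin * k)
            z = (xcol @ W.reshape(cout, cin * k).T).reshape(n, Lout, cout)
            z = z.transpose(0, 2, 1) + b[None, :, None]
            a = np.maximum(z, 0.0)
            cache.append(("conv", xcol, z, h.shape))
            h = a
        elif layer["kind"] == "dense":
            if h.ndim == 3:
                cache.append(("flatten", h.shape))
                h = h.reshape(h.shape[0], -1)
            z = h @ layer["W"].T + layer["b"]
            a = np.maximum(z, 0.0)
            cache.append(("dense", h, z))
            h = a
        else:  # output
            if h.ndim == 3:
                cache.append(("flatten", h.shape))
                h = h.reshape(h.shape[0], -1)
            z = h @ layer["W"].T + layer["b"]
            p = _sigmoid(z[:, 0])
            cache.append(("out", h, p))
            h = p
    return h, cache


def forward_pass(params: list[dict], X: np.ndarray) -> np.ndarray:
    """Network output in (0, 1) for each row of ``X``.

    Raises on a feature-length mismatch, naming expected vs got.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    expected = _input_length(params)
    if X.shape[1] != expected:
        raise ValueError(f"input length mismatch: expected {expected}, got {X.shape[1]}")
    out, _ = _forward(params, X)
    return out


def _input_length(params: list[dict]) -> int:
    """Recover the expected input length from the parameter shapes."""
    # walk conv stages forward symbolically, then match the first dense fan-in
    convs = [p for p in params if p["kind"] == "conv"]
    first_dense = next(p for p in params if p["kind"] != "conv")
    flat = first_dense["W"].shape[1]
    if not convs:
        return flat
    cout = convs[-1]["W"].shape[0]
    L_out = flat // cout
    L = L_out
    for p in reversed(convs):
        L = L + p["W"].shape[2] - 1
    return L


def loss_and_grad(
    params: list[dict], X: np.ndarray, y: np.ndarray, l2_lambda: float
) -> tuple[float, list[dict]]:
    """MSE-plus-L2 loss on scaled targets and its analytic gradient.

    Loss = mean((p - y)^2) + l2_lambda * sum of squared weights (biases are
    not penalised).  Gradients are returned layer-by-layer in the same
    structure as ``params``.
    """
    y = np.asarray(y, dtype=X.dtype if hasattr(X, "dtype") else float)
    p, cache = _forward(params, X)
    n = len(y)
    resid = p - y
    loss = float(np.mean(resid**2))
    grads: list[dict] = [None] * len(params)  # type: ignore[list-item]

    d = None  # running gradient
    li = len(params) - 1
    for entry in reversed(cache):
        kind = entry[0]
        if kind == "out":
            _, h, pout = entry
            dz = (2.0 / n) * resid * pout * (1.0 - pout)  # (n,)
            grads[li] = {"W": dz[None, :] @ h, "b": np.array([dz.sum()])}
            d = dz[:, None] @ params[li]["W"]  # (n, fan_in)
            li -= 1
        elif kind == "dense":
            _, h, z = entry
            dz = d * (z > 0)
            grads[li] = {"W": dz.T @ h, "b": dz.sum(axis=0)}
            d = dz @ params[li]["W"]
            li -= 1
        elif kind == "flatten":
            _, shape = entry
            d = d.reshape(shape)
        else:  # conv
            _, xcol, z, in_shape = entry
            dz = d * (z > 0)  # (n, cout, Lout)
            W = params[li]["W"]
            cout, cin, k = W.shape
            n, _, L = in_shape
            Lout = dz.shape[2]
            dzcol = np.ascontiguousarray(dz.transpose(0, 2, 1)).reshape(n * Lout, cout)
            grads[li] = {
                "W": (dzcol.T @ xcol).reshape(cout, cin, k),
                "b": dz.sum(axis=(0, 2)),
            }
            # col2im: scatter dxcol back onto the overlapping input positions
            dxcol = (dzcol @ W.reshape(cout, cin * k)).reshape(n, Lout, cin, k)
            dx = np.zeros(in_shape, dtype=dz.dtype)
            for kk in range(k):
                dx[:, :, kk : kk + Lout] += dxcol[:, :, :, kk].transpose(0, 2, 1)
            d = dx
            li -= 1

    if l2_lambda > 0:
        for g, layer in zip(grads, params):
            loss += l2_lambda * float(np.sum(layer["W"] ** 2))
            g["W"] += 2.0 * l2_lambda * layer["W"]
    return loss, grads


# ---------------------------------------------------------------------------
# feature construction shared by both models
# ---------------------------------------------------------------------------

def _peak_param_features(spectra: Sequence[Spectrum], window: SpectralWindow) -> np.ndarray:
    rows = []
    for sp in spectra:
        f = fit_gaussian_peak(sp, window)
        rows.append([f.height, f.center, f.fwhm, f.area])
    return np.asarray(rows, dtype=float)


@dataclass
class _FeatureState:
    """Frozen feature pipeline: window crop -> (optional PCA) -> z-score."""

    mode: str
    window: SpectralWindow
    pca_mean: np.ndarray | None
    pca_loadings: np.ndarray | None
    std_mean: np.ndarray | None = None
    std_scale: np.ndarray | None = None
    train_lo: np.ndarray | None = None  # per-feature training range, for the
    train_hi: np.ndarray | None = None  # out-of-distribution flag
    resid_max: float | None = None  # training max PCA reconstruction residual

    def raw_features(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        if self.mode == "peak_params":
            return _peak_param_features(spectra, self.window)
        X = window_matrix(spectra, self.window)
        if self.mode == "pca_scores":
            return (X - self.pca_mean) @ self.pca_loadings.T
        if self.mode == "raw":
            return X
        raise ValueError(f"unknown feature mode {self.mode!r}")

    def features(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        return (self.raw_features(spectra) - self.std_mean) / self.std_scale

    def _recon_residual(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        """Per-spectrum norm of the window signal the PCA cannot explain."""
        X = window_matrix(spectra, self.window)
        Xc = X - self.pca_mean
        resid = Xc - (Xc @ self.pca_loadings.T) @ self.pca_loadings
        return np.linalg.norm(resid, axis=1)

    def out_of_distribution(
        self, feats: np.ndarray, spectra: Sequence[Spectrum] | None = None
    ) -> np.ndarray:
        """True where an input lies outside the training envelope.

        Two checks: the standardized feature bounding box (widened by a
        quarter of its span per side), and — for PCA features — the window
        reconstruction residual, which catches inputs whose off-component
        structure (e.g. a missing or alien baseline) training never saw.
        """
        span = np.maximum(self.train_hi - self.train_lo, 1e-12)
        lo = self.train_lo - 0.25 * span
        hi = self.train_hi + 0.25 * span
        flags = np.any((feats < lo) | (feats > hi), axis=1)
        if self.mode == "pca_scores" and spectra is not None and self.resid_max:
            # factor 2: with few training spectra the fitted components absorb
            # part of the training noise, so held-out residuals run higher
            flags = flags | (self._recon_residual(spectra) > 2.0 * self.resid_max)
        return flags


def _build_feature_state(
    train_spectra: Sequence[Spectrum],
    window: SpectralWindow,
    mode: str,
    n_scores: int,
) -> _FeatureState:
    if mode == "pca_scores":
        X = window_matrix(train_spectra, window)
        k = min(n_scores, min(X.shape))
        pca = fit_region_pca(train_spectra, window, k)
        state = _FeatureState(mode, window, pca.mean_vector, pca.loadings)
    elif mode in ("raw", "peak_params"):
        state = _FeatureState(mode, window, None, None)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    raw = state.raw_features(train_spectra)
    state.std_mean = raw.mean(axis=0)
    # one common scale (sd of the most variable feature) rather than a
    # per-feature z-score: PCA scores share units, and inflating the
    # noise-only minor components to unit variance would bury the
    # concentration-carrying leading score
    g = max(float(raw.std(axis=0).max()), 1e-12)
    state.std_scale = np.full(raw.shape[1], g)
    feats = (raw - state.std_mean) / state.std_scale
    state.train_lo = feats.min(axis=0)
    state.train_hi = feats.max(axis=0)
    if mode == "pca_scores":
        state.resid_max = float(state._recon_residual(train_spectra).max())
    return state


# ---------------------------------------------------------------------------
# PCA-BP training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters of the PCA-BP fit; every field has a working default."""

    feature_mode: str = "pca_scores"  # pca_scores | raw | peak_params
    n_scores: int = 8
    architecture: NetworkArchitecture = field(default_factory=NetworkArchitecture)
    learning_rate: float = 5e-3
    epochs: int = 300
    patience: int = 300
    margin: float = 0.05
    val_fraction: float = 0.15
    precision: str = "float32"  # training dtype; float64 for exact-recovery work
    seed: int = 0


@dataclass
class PCABPModel:
    """Trained conv+dense regressor with its frozen feature pipeline."""

    architecture: NetworkArchitecture
    params: list[dict]
    scaler: ConcentrationScaler
    feature_state: _FeatureState
    training_log: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def window(self) -> SpectralWindow:
        return self.feature_state.window

    def predict_scaled(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        feats = self.feature_state.features(spectra)
        return forward_pass(self.params, feats)

    def predict_ppm(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        return np.asarray(self.scaler.inverse(self.predict_scaled(spectra)))

    def predict_flagged(self, spectra: Sequence[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus a per-spectrum out-of-distribution flag."""
        feats = self.feature_state.features(spectra)
        pred = np.asarray(self.scaler.inverse(forward_pass(self.params, feats)))
        return pred, self.feature_state.out_of_distribution(feats, spectra)


def _stratified_indices(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices so each distinct y level contributes ~fraction to part 2."""
    part1, part2 = [], []
    for level in np.unique(y):
        idx = np.flatnonzero(y == level)
        idx = idx[rng.permutation(len(idx))]
        n2 = int(round(fraction * len(idx)))
        if len(idx) >= 2:
            n2 = min(max(n2, 1), len(idx) - 1)
        else:
            n2 = 0
        part2.extend(idx[:n2])
        part1.extend(idx[n2:])
    return np.sort(np.asarray(part1, dtype=int)), np.sort(np.asarray(part2, dtype=int))


def train_pca_bp(
    train_spectra: Sequence[Spectrum],
    window: SpectralWindow,
    config: TrainConfig | None = None,
) -> PCABPModel:
    """Fit the PCA-BP network on labelled spectra.

    Full-batch Adam on MSE(scaled targets) + L2; early stopping restores the
    weights of the best validation epoch.  Identical spectra, window, config
    and seed give bitwise-identical weights.
    """
    config = config or TrainConfig()
    y_ppm = np.array([sp.concentration for sp in train_spectra], dtype=float)
    if np.any(np.isnan(y_ppm)):
        raise ValueError("all training spectra need a known concentration")
    levels = np.unique(y_ppm)
    if len(levels) < 2:
        raise ValueError("training needs >= 2 distinct concentration levels")
    if np.any(y_ppm <= 0):
        raise ValueError("log concentration scaling requires strictly positive levels")

    scaler = ConcentrationScaler(float(levels.min()), float(levels.max()), config.margin)
    state = _build_feature_state(train_spectra, window, config.feature_mode, config.n_scores)
    X = state.features(train_spectra)
    y = np.asarray(scaler.forward(y_ppm))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    tr_idx, va_idx = _stratified_indices(y_ppm, config.val_fraction, rng)
    if len(va_idx) == 0:
        tr_idx = np.arange(len(y))
        va_idx = tr_idx
    dtype = {"float32": np.float32, "float64": np.float64}[config.precision]
    Xtr, ytr = X[tr_idx].astype(dtype), y[tr_idx].astype(dtype)
    Xva, yva = X[va_idx].astype(dtype), y[va_idx].astype(dtype)

    arch = config.architecture
    params = init_params(arch, X.shape[1], rng)
    for layer in params:
        layer["W"] = layer["W"].astype(dtype)
        layer["b"] = layer["b"].astype(dtype)

    # Adam state
    m = [{"W": np.zeros_like(l["W"]), "b": np.zeros_like(l["b"])} for l in params]
    v = [{"W": np.zeros_like(l["W"]), "b": np.zeros_like(l["b"])} for l in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    # early stopping tracks validation error on the concentration (ppm) scale:
    # the scaled-space loss saturates long before the saturating high-ppm end
    # of the curve is learned, so it is a poor stopping signal
    yva_ppm = y_ppm[va_idx]

    def val_loss() -> float:
        p, _ = _forward(params, Xva)
        c = np.asarray(scaler.inverse(np.clip(p, 1e-9, 1.0 - 1e-9)))
        return float(np.mean((c - yva_ppm) ** 2))

    best_loss = np.inf
    best_params = [{k: l[k].copy() for k in ("W", "b")} | {"kind": l["kind"]} for l in params]
    best_epoch = 0
    log: list[tuple[int, float, float]] = []
    for epoch in range(1, config.epochs + 1):
        loss, grads = loss_and_grad(params, Xtr, ytr, arch.l2_lambda)
        # global-norm gradient clipping guards against rare unstable steps
        gnorm = np.sqrt(sum(float(np.sum(g[k] ** 2)) for g in grads for k in ("W", "b")))
        if gnorm > 5.0:
            scale = 5.0 / gnorm
            for g in grads:
                g["W"] *= scale
                g["b"] *= scale
        bc1 = 1 - beta1**epoch
        bc2 = 1 - beta2**epoch
        # cosine decay to 1% of the base rate over the epoch budget lets Adam
        # settle into the fine-scale minimum instead of bouncing around it
        lr_t = lr * (0.01 + 0.495 * (1.0 + np.cos(np.pi * epoch / config.epochs)))
        step = lr_t * np.sqrt(bc2) / bc1  # fold both bias corrections into one scalar
        for layer, g, mi, vi in zip(params, grads, m, v):
            for key in ("W", "b"):
                mi[key] *= beta1
                mi[key] += (1 - beta1) * g[key]
                vi[key] *= beta2
                vi[key] += (1 - beta2) * g[key] ** 2
                layer[key] -= step * mi[key] / (np.sqrt(vi[key]) + eps * np.sqrt(bc2))
        vl = val_loss()
        log.append((epoch, loss, vl))
        if vl < best_loss - 1e-12:
            best_loss = vl
            best_epoch = epoch
            best_params = [
                {k: l[k].copy() for k in ("W", "b")} | {"kind": l["kind"]} for l in params
            ]
        elif epoch - best_epoch >= config.patience:
            break

    return PCABPModel(arch, best_params, scaler, state, log)


# ---------------------------------------------------------------------------
# PLSR comparator
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Linear PLS calibration on window intensities and scaled targets."""

    window: SpectralWindow
    scaler: ConcentrationScaler
    x_mean: np.ndarray
    coef: np.ndarray  # (n_features,)
    intercept: float
    n_components: int

    def predict_scaled(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        X = window_matrix(spectra, self.window)
        raw = (X - self.x_mean) @ self.coef + self.intercept
        return np.clip(raw, 0.0, 1.0)

    def predict_ppm(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        return np.asarray(self.scaler.inverse(self.predict_scaled(spectra)))


def fit_plsr(
    train_spectra: Sequence[Spectrum],
    window: SpectralWindow,
    n_components: int = 10,
    margin: float = 0.05,
) -> PLSRModel:
    """Standard (NIPALS) PLS regression on the window data and scaled targets.

    Deterministic; scaled predictions are clipped to [0, 1] before inverse
    concentration scaling so extrapolations stay finite.
    """
    y_ppm = np.array([sp.concentration for sp in train_spectra], dtype=float)
    levels = np.unique(y_ppm)
    if len(levels) < 2:
        raise ValueError("PLSR needs >= 2 distinct concentration levels")
    X = window_matrix(train_spectra, window)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    scaler = ConcentrationScaler(float(levels.min()), float(levels.max()), margin)
    y = np.asarray(scaler.forward(y_ppm))
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = np.asarray(pls.coef_, dtype=float).ravel()
    x_mean = np.asarray(pls._x_mean, dtype=float)
    intercept = float(np.asarray(pls.intercept_).ravel()[0])
    return PLSRModel(window, scaler, x_mean, coef, intercept, n_components)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    """Predictions vs truth on the ppm scale with summary statistics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    r_squared: float
    rmse: float
    fit_line_slope: float
    fit_line_intercept: float

    def to_dict(self) -> dict:
        return {
            "y_true_ppm": self.y_true.tolist(),
            "y_pred_ppm": self.y_pred.tolist(),
            "r_squared": self.r_squared,
            "rmse_ppm": self.rmse,
            "fit_line_slope": self.fit_line_slope,
            "fit_line_intercept": self.fit_line_intercept,
        }


def evaluate(model, test_spectra: Sequence[Spectrum]) -> RegressionReport:
    """Score a fitted model on labelled test spectra (ppm scale).

    R^2 = 1 - SS_res/SS_tot on unscaled ppm; RMSE in ppm; plus the
    least-squares line of predictions against truth.
    """
    if len(test_spectra) == 0:
        raise ValueError("test set is empty")
    y_true = np.array([sp.concentration for sp in test_spectra], dtype=float)
    if np.any(np.isnan(y_true)):
        raise ValueError("all test spectra need a known concentration")
    if np.ptp(y_true) == 0:
        raise ValueError("R^2 is undefined for a constant y_true")
    y_pred = np.asarray(model.predict_ppm(test_spectra), dtype=float)
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    slope, intercept = np.polyfit(y_true, y_pred, 1)
    return RegressionReport(y_true, y_pred, r2, rmse, float(slope), float(intercept))


# ---------------------------------------------------------------------------
# JSON model persistence (the networks are small; no binary format needed)
# ---------------------------------------------------------------------------

def _window_dict(w: SpectralWindow) -> dict:
    return {"low": w.low, "high": w.high}


def _state_to_dict(s: _FeatureState) -> dict:
    return {
        "mode": s.mode,
        "window": _window_dict(s.window),
        "pca_mean": None if s.pca_mean is None else s.pca_mean.tolist(),
        "pca_loadings": None if s.pca_loadings is None else s.pca_loadings.tolist(),
        "std_mean": s.std_mean.tolist(),
        "std_scale": s.std_scale.tolist(),
        "train_lo": s.train_lo.tolist(),
        "train_hi": s.train_hi.tolist(),
        "resid_max": s.resid_max,
    }


def _state_from_dict(d: dict) -> _FeatureState:
    arr = lambda v: None if v is None else np.asarray(v, dtype=float)
    return _FeatureState(
        d["mode"],
        SpectralWindow(d["window"]["low"], d["window"]["high"]),
        arr(d["pca_mean"]),
        arr(d["pca_loadings"]),
        arr(d["std_mean"]),
        arr(d["std_scale"]),
        arr(d["train_lo"]),
        arr(d["train_hi"]),
        d.get("resid_max"),
    )


def save_model(model: PCABPModel | PLSRModel, path: str) -> None:
    """Serialise a fitted model (weights, scaler, feature pipeline) to JSON."""
    if isinstance(model, PCABPModel):
        doc = {
            "kind": "pca_bp",
            "architecture": {
                "conv_stages": [list(s) for s in model.architecture.conv_stages],
                "dense_widths": list(model.architecture.dense_widths),
                "l2_lambda": model.architecture.l2_lambda,
            },
            "params": [
                {"kind": l["kind"], "W": l["W"].tolist(), "b": l["b"].tolist()}
                for l in model.params
            ],
            "scaler": asdict(model.scaler),
            "feature_state": _state_to_dict(model.feature_state),
        }
    elif isinstance(model, PLSRModel):
        doc = {
            "kind": "plsr",
            "window": _window_dict(model.window),
            "scaler": asdict(model.scaler),
            "x_mean": model.x_mean.tolist(),
            "coef": model.coef.tolist(),
            "intercept": model.intercept,
            "n_components": model.n_components,
        }
    else:
        raise TypeError(f"cannot serialise model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> PCABPModel | PLSRModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    scaler = ConcentrationScaler(**doc["scaler"])
    if doc["kind"] == "pca_bp":
        arch = NetworkArchitecture(
            conv_stages=tuple(tuple(s) for s in doc["architecture"]["conv_stages"]),
            dense_widths=tuple(doc["architecture"]["dense_widths"]),
            l2_lambda=doc["architecture"]["l2_lambda"],
        )
        params = [
            {"kind": l["kind"], "W": np.asarray(l["W"]), "b": np.asarray(l["b"])}
            for l in doc["params"]
        ]
        return PCABPModel(arch, params, scaler, _state_from_dict(doc["feature_state"]))
    if doc["kind"] == "plsr":
        return PLSRModel(
            SpectralWindow(doc["window"]["low"], doc["window"]["high"]),
            scaler,
            np.asarray(doc["x_mean"]),
            np.asarray(doc["coef"]),
            doc["intercept"],
            doc["n_components"],
        )
    raise ValueError(f"unknown model kind {doc['kind']!r} in {path}")
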