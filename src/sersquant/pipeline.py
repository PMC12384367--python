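"""End-to-end orchestration: simulate, quantify, predict.

``run_quantify`` executes the full analysis chain on a labelled spectrum
set: window segmentation -> per-region PCA and variance-contribution region
selection -> PCA-BP training and PLSR comparison on a stratified train/test
split -> univariate calibration of the fitted peak height with an SNR = 3
limit of detection -> one JSON report bundle carrying enough provenance
(config, hash, seed, versions) to re-execute it exactly.

All randomness flows from the single master seed in the config; stage seeds
are derived from it deterministically, so a rerun reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationResult, compute_lod, fit_calibration, rsd
from .features import select_region
from .models import (
    PCABPModel,
    TrainConfig,
    evaluate,
    fit_plsr,
    load_model,
    save_model,
    train_pca_bp,
)
from .preprocessing import (
    DEFAULT_WINDOWS,
    SpectralWindow,
    estimate_blank_noise,
    fit_gaussian_peak,
)
from .synthetic import (
    DEFAULT_LEVELS_PPM,
    PYRENE,
    R6G,
    AcquisitionGrid,
    AnalyteLibrary,
    ResponseModel,
    Spectrum,
    generate_dataset,
    generate_spectrum,
    read_dataset,
    read_spectrum_csv,
    spectrum_seed,
    write_dataset,
)

__all__ = [
    "GeneratorConfig",
    "ModelSection",
    "CalibrationSection",
    "PipelineConfig",
    "run_simulate",
    "run_quantify",
    "run_predict",
]

logger = logging.getLogger("sersquant")

_ANALYTES: dict[str, AnalyteLibrary] = {"pyrene": PYRENE, "r6g": R6G}


def _from_dict(cls, d: dict, context: str):
    """Build a dataclass from a dict, rejecting unknown keys by name."""
    if not isinstance(d, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"{context}: unknown config key(s) {sorted(unknown)}")
    return cls(**d)


@dataclass
class GeneratorConfig:
    """Synthetic-acquisition settings (see :mod:`sersquant.synthetic`)."""

    analyte: str = "pyrene"
    i_max: float = 1000.0
    k_ads: float = 0.05
    replicate_cv: float = 0.096
    noise_sd: float = 10.0
    baseline_coeffs: list[float] = field(default_factory=lambda: [20.0, 10.0, -15.0])
    grid_start: float = 200.0
    grid_stop: float = 1800.0
    grid_step: float = 2.0
    levels: list[float] = field(default_factory=lambda: list(DEFAULT_LEVELS_PPM))
    replicates: int = 20

    def library(self) -> AnalyteLibrary:
        if self.analyte not in _ANALYTES:
            raise ValueError(
                f"unknown analyte {self.analyte!r}; available: {sorted(_ANALYTES)}"
            )
        return _ANALYTES[self.analyte]

    def response(self) -> ResponseModel:
        return ResponseModel(
            i_max=self.i_max,
            k_ads=self.k_ads,
            replicate_cv=self.replicate_cv,
            noise_sd=self.noise_sd,
            baseline_coeffs=tuple(self.baseline_coeffs),
        )

    def grid(self) -> AcquisitionGrid:
        return AcquisitionGrid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class ModelSection:
    """PCA-BP hyperparameters exposed in the config file."""

    n_scores: int = 8
    learning_rate: float = 5e-3
    epochs: int = 300
    patience: int = 300
    l2_lambda: float = 1e-4
    margin: float = 0.05
    val_fraction: float = 0.15


@dataclass
class CalibrationSection:
    transform: str = "log10"  # log10 | linear
    blank_replicates: int = 20
    # max-minus-median is the stable blank statistic: an unconstrained
    # Gaussian fit on a signal-free window is ill-posed and its height
    # scatters far above the actual noise level
    blank_statistic: str = "max"  # max | fit_height


@dataclass
class PipelineConfig:
    """Validated configuration of the whole pipeline."""

    seed: int = 0
    outdir: str = "results"
    feature_mode: str = "pca_scores"  # pca_scores | raw | peak_params
    test_fraction: float = 0.3
    plsr_components: int = 10
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelSection = field(default_factory=ModelSection)
    calibration: CalibrationSection = field(default_factory=CalibrationSection)
    windows: list[list[float]] = field(
        default_factory=lambda: [[w.low, w.high] for w in DEFAULT_WINDOWS]
    )

    def __post_init__(self) -> None:
        if self.feature_mode not in ("pca_scores", "raw", "peak_params"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if not (0 < self.test_fraction < 1):
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        for w in self.windows:
            if len(w) != 2:
                raise ValueError(f"window entries must be [low, high], got {w}")
        self.generator.library()  # validates analyte name

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sub = {}
        for key, sub_cls in (
            ("generator", GeneratorConfig),
            ("model", ModelSection),
            ("calibration", CalibrationSection),
        ):
            if key in d:
                sub[key] = _from_dict(sub_cls, d.pop(key), key)
        cfg = _from_dict(cls, d, "pipeline")
        for key, val in sub.items():
            setattr(cfg, key, val)
        cfg.__post_init__()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def spectral_windows(self) -> list[SpectralWindow]:
        return [SpectralWindow(float(lo), float(hi)) for lo, hi in self.windows]

    def train_config(self) -> TrainConfig:
        m = self.model
        from .models import NetworkArchitecture

        return TrainConfig(
            feature_mode=self.feature_mode,
            n_scores=m.n_scores,
            architecture=NetworkArchitecture(l2_lambda=m.l2_lambda),
            learning_rate=m.learning_rate,
            epochs=m.epochs,
            patience=m.patience,
            margin=m.margin,
            val_fraction=m.val_fraction,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, outdir: str | None = None) -> str:
    """Generate the configured dataset and write spectra + manifest CSVs."""
    outdir = outdir or config.outdir
    gen = config.generator
    logger.info(
        "simulating %d levels x %d replicates of %s (seed %d)",
        len(gen.levels), gen.replicates, gen.analyte, config.seed,
    )
    spectra = generate_dataset(
        gen.library(), gen.response(), gen.grid(),
        levels=gen.levels, replicates=gen.replicates, seed=config.seed,
    )
    manifest = write_dataset(spectra, outdir)
    logger.info("wrote %d spectra and %s", len(spectra), manifest)
    return manifest


def _stratified_split(
    spectra: Sequence[Spectrum], test_fraction: float, seed: int
) -> tuple[list[Spectrum], list[Spectrum]]:
    y = np.array([sp.concentration for sp in spectra], dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    train, test = [], []
    for level in np.unique(y):
        idx = np.flatnonzero(y == level)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        if len(idx) >= 2:
            n_test = min(max(n_test, 1), len(idx) - 1)
        else:
            n_test = 0
        test.extend(spectra[i] for i in idx[:n_test])
        train.extend(spectra[i] for i in idx[n_test:])
    return train, test


def _generate_blanks(config: PipelineConfig) -> list[Spectrum]:
    gen = config.generator
    return [
        generate_spectrum(
            gen.library(), gen.response(), gen.grid(), 0.0,
            spectrum_seed(config.seed, 10_000, i),
        )
        for i in range(config.calibration.blank_replicates)
    ]


def run_quantify(
    config: PipelineConfig,
    manifest: str | None = None,
    outdir: str | None = None,
) -> dict:
    """Execute the full quantitation workflow and return the report bundle.

    If no manifest is given the configured synthetic dataset is generated in
    memory.  Writes ``report.json``, both model files and the training log
    to ``outdir`` (pass ``outdir=None`` with ``config.outdir`` unset paths
    handled by the caller).
    """
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)

    if manifest is not None:
        spectra = read_dataset(manifest)
        missing = [sp for sp in spectra if sp.concentration is None]
        if missing:
            raise ValueError(
                f"{len(missing)} manifest entries have no concentration; "
                "quantify needs labelled spectra"
            )
    else:
        gen = config.generator
        spectra = generate_dataset(
            gen.library(), gen.response(), gen.grid(),
            levels=gen.levels, replicates=gen.replicates, seed=config.seed,
        )

    labelled = [sp for sp in spectra if sp.concentration and sp.concentration > 0]
    blanks = [sp for sp in spectra if sp.concentration == 0]

    # --- stage 1: segmentation + region selection --------------------------
    windows = config.spectral_windows()
    try:
        train, test = _stratified_split(labelled, config.test_fraction, config.seed)
        selected, region_pcas = select_region(train, windows)
        logger.info("selected window %s", selected)

        # --- stage 2: regression models ------------------------------------
        model = train_pca_bp(train, selected, config.train_config())
        pcabp_report = evaluate(model, test)
        plsr = fit_plsr(
            train, selected,
            n_components=min(config.plsr_components, len(train)),
            margin=config.model.margin,
        )
        plsr_report = evaluate(plsr, test)
        logger.info(
            "test R^2: PCA-BP %.4f, PLSR %.4f",
            pcabp_report.r_squared, plsr_report.r_squared,
        )

        # --- stage 3: univariate calibration + LOD -------------------------
        levels = sorted({sp.concentration for sp in labelled})
        mean_heights, level_stats = [], []
        for level in levels:
            heights = [
                fit_gaussian_peak(sp, selected).height
                for sp in labelled
                if sp.concentration == level
            ]
            mean_heights.append(float(np.mean(heights)))
            level_stats.append(
                {
                    "level_ppm": level,
                    "mean_height": float(np.mean(heights)),
                    "sd_height": float(np.std(heights, ddof=1)) if len(heights) > 1 else 0.0,
                    "n": len(heights),
                    "rsd_percent": rsd(heights) if len(heights) > 1 else None,
                }
            )
        cal = fit_calibration(levels, mean_heights, config.calibration.transform)
        if len(blanks) < 3:
            blanks = _generate_blanks(config)
        blank_sd = estimate_blank_noise(
            blanks, selected, statistic=config.calibration.blank_statistic
        )
        lod = compute_lod(cal, blank_sd)
        cal = CalibrationResult(
            cal.slope, cal.intercept, cal.r_squared, cal.transform, blank_sd, lod
        )
        # replicate uniformity at the mid calibration level
        mid = levels[len(levels) // 2]
        mid_rsd = next(s["rsd_percent"] for s in level_stats if s["level_ppm"] == mid)
    except Exception as err:
        raise RuntimeError(f"quantify pipeline failed: {err}") from err

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    report = {
        "regions": {
            "windows": [str(w) for w in windows],
            "variance_contribution": {
                str(r.window): r.variance_contribution for r in region_pcas
            },
            "selected_window": str(selected),
        },
        "pca_bp": pcabp_report.to_dict(),
        "plsr": plsr_report.to_dict(),
        "calibration": cal.to_dict(),
        "replicate_rsd_percent_at_mid_level": mid_rsd,
        "calibration_table": level_stats,
        "provenance": {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "versions": _versions(),
            "n_train": len(train),
            "n_test": len(test),
        },
    }

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    save_model(model, os.path.join(outdir, "model_pca_bp.json"))
    save_model(plsr, os.path.join(outdir, "model_plsr.json"))
    pd.DataFrame(
        model.training_log, columns=["epoch", "train_loss", "val_loss"]
    ).to_csv(os.path.join(outdir, "training_log.csv"), index=False)
    pd.DataFrame(level_stats).to_csv(
        os.path.join(outdir, "calibration_table.csv"), index=False
    )
    return report


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "sersquant": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }


def run_predict(
    model_path: str,
    spectrum_paths: Sequence[str],
    out_csv: str | None = None,
) -> pd.DataFrame:
    """Predict concentration for each spectrum file with a saved model.

    Returns (and optionally writes) one row per spectrum:
    ``path, predicted_ppm, flagged`` where ``flagged`` marks inputs outside
    the model's training feature envelope (out-of-distribution).
    """
    if not os.path.exists(model_path):
        raise FileNotFoundError(f"model file not found: {model_path}")
    model = load_model(model_path)
    spectra = []
    for p in spectrum_paths:
        if not os.path.exists(p):
            raise FileNotFoundError(f"spectrum file not found: {p}")
        spectra.append(read_spectrum_csv(p))
    _check_grid(model, spectra)
    if isinstance(model, PCABPModel):
        pred, flagged = model.predict_flagged(spectra)
    else:
        pred = model.predict_ppm(spectra)
        flagged = np.zeros(len(spectra), dtype=bool)
    df = pd.DataFrame(
        {"path": list(spectrum_paths), "predicted_ppm": pred, "flagged": flagged}
    )
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df


def _check_grid(model, spectra: Sequence[Spectrum]) -> None:
    from .preprocessing import crop_window

    if isinstance(model, PCABPModel):
        window = model.window
        state = model.feature_state
        expected = (
            state.pca_loadings.shape[1]
            if state.pca_loadings is not None
            else len(state.std_mean)
        )
        if state.mode == "peak_params":
            expected = None
    else:
        window = model.window
        expected = len(model.x_mean)
    for sp in spectra:
        sub = crop_window(sp, window)  # raises if the window misses the grid
        if expected is not None and len(sub.intensities) != expected:
            raise ValueError(
                f"grid mismatch: model expects {expected} points in window "
                f"{window} but spectrum grid [{sp.grid.start}, {sp.grid.stop}] "
                f"step {sp.grid.step} provides {len(sub.intensities)}"
            )
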