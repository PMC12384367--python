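# sersquant

Quantitative chemometrics for surface-enhanced Raman spectroscopy (SERS) of
trace contaminants, built around the canonical task of quantifying the
polycyclic aromatic hydrocarbon pyrene in edible oil after thin-layer
chromatography separation (TLC-SERS).  Spectra in, predicted concentration
out.

The pipeline:

1. **Synthetic acquisition** — labelled SERS spectra with a Gaussian band
   model (pyrene's main band at 586 cm⁻¹), a saturating Langmuir response
   `A(c) = I_max·K·c/(1+K·c)`, a per-spectrum lognormal replicate factor
   (CV 9.6 %), polynomial baseline and white noise.  Defaults emulate a
   0.01–70 ppm series, 9 log-spaced levels × 20 replicates.
2. **Peak fitting** — least-squares Gaussian `h·exp(−(x−μ)²/2σ²) + b` per
   characteristic band; height, FWHM = 2√(2 ln 2)·σ, area =
   h·FWHM·√(π/(4 ln 2)).
3. **Region selection** — the spectrum is split into four windows
   (350–405, 410–490, 500–600, 1190–1250 cm⁻¹); each is mean-centered and
   decomposed by PCA, and the window whose first principal component
   explains the largest fraction of its variance (the *variance
   contribution rate*) is selected.
4. **Regression** — a small 1-D conv + dense network ("PCA-BP": conv
   stages (32,4), (64,4), (128,2), (256,1); dense 400–200–100–50; sigmoid
   output with an invertible log₁₀ concentration scaling) trained with
   full-batch Adam on MSE + L2, against a PLSR (partial least squares)
   linear comparator on the same window.  Test-set R² is reported on the
   ppm axis.
5. **Calibration + LOD** — univariate line of the 586 cm⁻¹ peak height vs
   log₁₀(c), blank noise from zero-concentration spectra, limit of
   detection at SNR = 3, and the replicate RSD (100·sd/mean).

Who it is for: method developers who need a reproducible, fully seeded
desk-scale testbed for SERS quantitation workflows — every stage is a plain
Python function with a typed result object, and the network is implemented
in numpy with analytic backprop (no tensor framework).

## Worked example

```bash
sersquant quantify --seed 7 --out demo
sersquant report demo/report.json
```

prints

```
variance contribution by window:
     1190-1250 cm^-1: 0.9302
       350-405 cm^-1: 0.0754
       410-490 cm^-1: 0.0549
       500-600 cm^-1: 0.9879 <- selected
PCA-BP test R^2: 0.9348 (RMSE 5.65 ppm)
PLSR   test R^2: 0.1344 (RMSE 20.6 ppm)
calibration R^2: 0.7099 (log10 axis), LOD 1.23 ppm, replicate RSD 14.86 %
```

Reading it: the 500–600 cm⁻¹ window containing the concentration-responsive
586 cm⁻¹ pyrene band is almost perfectly one-dimensional (rate 0.988) and
is selected as the regression input; the analyte-free windows sit below
0.08.  The nonlinear network explains 93 % of the held-out concentration
variance where the linear PLSR — defeated by the Langmuir curvature —
manages 13 %.  The univariate calibration of peak height vs log₁₀(c)
flattens at the low end (heights there sit under the noise floor), and the
SNR = 3 limit of detection of this synthetic instrument is about 1.2 ppm.
Test-set R² for the network lands between roughly 0.89 and 0.96 depending
on the master seed; the ppm-axis ceiling under the 9.6 % multiplicative
replicate noise is about 0.95 (see `docs/methods.md`).

The same stages are available as library calls
(`generate_dataset`, `fit_gaussian_peak`, `select_region`, `train_pca_bp`,
`fit_plsr`, `evaluate`, `fit_calibration`, `compute_lod`) and as the other
CLI subcommands `simulate` (write a spectra + manifest dataset) and
`predict` (apply a saved model JSON to spectrum CSVs, with an
out-of-distribution flag).

## Layout

```
src/sersquant/
  synthetic.py      # spectrum generator, CSV/manifest I/O
  preprocessing.py  # windows, Gaussian peak fits, blank noise
  features.py       # per-window PCA, variance-contribution selection
  models.py         # scaler, conv+dense network, PLSR, evaluation
  calibration.py    # calibration line, LOD (SNR=3), RSD
  pipeline.py       # config, orchestration, report bundle
  cli.py            # sersquant simulate | quantify | predict | report
docs/methods.md     # model, assumptions, parameter rationale, limitations
```
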