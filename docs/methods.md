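# Methods

`sersquant` implements a quantitation pipeline for trace analytes measured by
surface-enhanced Raman spectroscopy (SERS) after thin-layer-chromatography
separation, with pyrene in edible oil as the canonical system.  The package
has two halves: a synthetic-acquisition model that generates labelled
spectra with the statistical structure such measurements exhibit, and the
analysis chain that turns spectra into predicted concentrations.

## Synthetic acquisition model

A spectrum on a uniform wavenumber grid (default 200–1800 cm⁻¹, 2 cm⁻¹
step; a 5 cm⁻¹ instrument preset is available) is

    y(x) = b(x) + ε · A(c) · Σₖ aₖ gₖ(x) + η(x)

* **Bands** gₖ are unit-height Gaussians.  The pyrene library puts its
  dominant band at 586 cm⁻¹ (FWHM 14 cm⁻¹, relative amplitude 1.0) and a
  weaker ring band at 1240 cm⁻¹ (FWHM 16 cm⁻¹, amplitude 0.3); a rhodamine
  6G library (308, 1194, 1360, 1508 cm⁻¹) is included for mixture work.
* **Response** A(c) = I_max·K·c/(1+K·c) is a Langmuir adsorption isotherm:
  SERS intensity saturates as analyte covers the finite plasmonic sites.
  Defaults I_max = 1000 counts and K = 0.05 ppm⁻¹ place the default
  calibration series (9 log-spaced levels, 0.01–70 ppm, 20 replicates each)
  across the linear through near-saturated regimes.  This saturation is the
  nonlinearity that motivates a nonlinear regressor over a straight
  calibration line.
* **Replicate scatter** ε is one lognormal factor per spectrum, unit mean,
  coefficient of variation 0.096 — the 9.6 % replicate RSD typical of a
  good TLC-SERS substrate.  It is shared by all bands of a spectrum
  (spot-to-spot enhancement variability), which is why averaging over grid
  points cannot remove it.
* **Background** b(x) is a gentle quadratic (coefficients in a normalised
  0–1 abscissa) and η is white Gaussian noise, default sd = 1 % of I_max.

Whether real replicate scatter is multiplicative or additive is not
observable from summary statistics alone; the generator makes it
multiplicative (plus the additive floor) as a deliberate modelling choice,
and both knobs are configurable.  Each spectrum's seed derives
deterministically from (master seed, level index, replicate index), so
datasets are byte-reproducible.

What the generator does *not* emulate: baseline drift between spectra,
cosmic-ray spikes, wavenumber miscalibration, band-shape asymmetry, and
matrix interference bands from the oil.  Passing tests therefore demonstrate
the correctness and statistical behaviour of the analysis chain under the
stated noise model, not instrument-grade robustness.

## Peak fitting

Characteristic bands are summarised by a least-squares single-Gaussian fit
with a constant offset, `h·exp(−(x−μ)²/2σ²) + b`, inside a fixed window.
Width is reported as FWHM = 2√(2 ln 2)·σ and area as h·FWHM·√(π/(4 ln 2)).
The offset absorbs locally flat background, making the fit invariant to
constant shifts; no smoothing or baseline-correction pre-processing is
applied before fitting.  Initialisation is the window argmax (center),
max−min (height) and a quarter window width (FWHM); on non-convergence the
center is jittered deterministically across the window for up to 5
restarts, and a still-unconverged fit is returned flagged rather than
raised, so batch jobs survive pathological spectra.  Flat windows and
windows with fewer than 5 points are errors.

## Region selection

The spectrum is segmented into four windows bracketing the characteristic
bands: 350–405, 410–490, 500–600 and 1190–1250 cm⁻¹ (endpoints inclusive,
physical wavenumbers).  Each window is mean-centered — never
variance-scaled, because absolute peak height carries the concentration
signal — and decomposed by PCA.  The *variance-contribution rate* of a
window is defined here as the fraction of its total variance captured by
the first principal component.  In a calibration series the window
dominated by a concentration-responsive band varies essentially along one
direction (the band shape), so its rate approaches 1, while analyte-free
windows split their variance across many noise directions.  The window with
the highest rate is selected (ties break to the lower wavenumber bound).
On default synthetic data the 500–600 cm⁻¹ window containing the 586 cm⁻¹
pyrene band wins with a rate around 0.99, against roughly 0.93 for the
weaker 1240 cm⁻¹ window and < 0.1 for the analyte-free windows.  The rate
definition is isolated in one function so a top-k variant is a one-line
change.

## Concentration regression

**Target scaling.**  Concentrations spanning four decades are mapped
through an affine transform of log₁₀(c) onto [margin, 1−margin] (default
margin 0.05), matching the bounded sigmoid output; the transform is exactly
invertible.

**PCA-BP network.**  The regressor input is the window's top PCA scores
(default 8; modes for raw window intensities and Gaussian-fit peak
parameters exist, and for inputs shorter than the stack's receptive field
the kernels clip to the running sequence length).  Eight scores retain
essentially all of the selected window's variance — beyond the leading
components the window is white noise — while keeping the flattened conv
output at 256 rather than 2304 units, which makes training several times
faster at equal accuracy.  Features are centered and divided by one common
scale (the sd of the most variable score): PCA scores share units, and
per-score z-scoring would inflate the noise-only minor components to the
same magnitude as the concentration-carrying leading score.  The
architecture is fixed: Conv1D stages (filters, kernel) = (32, 4), (64, 4),
(128, 2), (256, 1) with valid padding and ReLU, flatten, dense layers
400–200–100–50 with ReLU, and one sigmoid output.  Training minimises MSE
on the scaled target plus an L2 weight penalty (default λ = 10⁻⁴, biases
unpenalised) by full-batch Adam (lr 5·10⁻³, cosine-decayed to 1 % over the
epoch budget, default 300 epochs, global gradient-norm clip at 5).  The output layer is initialised near zero so the sigmoid starts at
0.5 regardless of hidden-activation scale — with a saturated sigmoid the
gradient vanishes and training never recovers.  An 85/15 stratified
validation split drives early stopping; the stopping metric is validation
MSE on the *ppm* scale, because the scaled-space loss saturates long before
the high-concentration end of the curve is learned.  The best-epoch weights
are restored.  The network is implemented directly in numpy with analytic
backpropagation (it is small enough that a tensor framework would add
nothing); the gradient is validated against central finite differences in
the tests.  All randomness (init, splits) derives from one seed, and
training is full-batch, so identical config + seed reproduces identical
weights bit for bit.

**PLSR comparator.**  Partial least squares regression (NIPALS, via
scikit-learn, `scale=False`) fits the same window intensities against the
same scaled target, default 10 components; scaled predictions are clipped
to [0, 1] before inverse transformation so linear extrapolation cannot
produce unbounded concentrations.  Because PLSR is linear in the
intensities while log-concentration is strongly curved in the Langmuir
signal, it underfits both ends of the series — this is the point of the
comparison.

**Evaluation.**  R² = 1 − SS_res/SS_tot and RMSE are computed on the
unscaled ppm axis, together with the least-squares line of predictions
against truth.  A constant truth vector is an error (R² undefined).

### What the headline R² can and cannot reach

Under the default noise model the concentration information in one spectrum
is carried by the 586 cm⁻¹ band height h = A(c)·ε with CV(ε) = 0.096.  Near
70 ppm the Langmuir curve is nearly flat (d ln A/dc = 1/(c(1+Kc)) ≈
0.003 ppm⁻¹), so a 9.6 % amplitude uncertainty corresponds to a ~30 ppm
single-spectrum uncertainty.  A Monte-Carlo Bayes-optimal posterior-mean
estimator over the default levels caps the ppm-axis test R² near 0.95; the
trained network typically reaches 0.89–0.96 depending on the seed (8-seed
median 0.93 at defaults), and PLSR −0.5 to 0.35.  Reported R² values from
real-instrument studies of this design (≈ 0.995) are not reproducible from
these synthetic conditions — the model comparison (PCA-BP ≫ PLSR), not the
absolute R², is the reproducible finding.  Relative (per-level) accuracy is
likewise bounded: the ideal estimator exploits the discreteness of the 9
calibration levels and snaps to them, while the smooth sigmoid-output
regression under the scaled-MSE objective keeps a median absolute relative
error of roughly 0.2–0.6 across levels ≥ 0.1 ppm; at 0.1 ppm and below the
band amplitude (≤ 5 counts) sits under the additive noise floor and no
estimator resolves neighbouring levels.

## Univariate calibration and LOD

The calibration signal is the mean fitted 586 cm⁻¹ peak height per level.
Because the series spans four decades the default axis regresses intensity
on log₁₀(c) (a linear axis is available).  Blank noise is the sample sd of
a peak statistic over ≥ 3 (default 20) zero-concentration spectra; the
pipeline default statistic is max-minus-median window intensity, because an
unconstrained Gaussian fit on a signal-free window is ill-posed and its
fitted height scatters far above the real noise level (the fitted-height
statistic remains available in the config).
The limit of detection follows the SNR = 3 convention, LOD =
T⁻¹(3·σ_blank/slope) with T the axis transform: the classical 3σ/b on the
linear axis, 10^(3σ/a) on the log axis (with a in counts per decade, the
reference point of the log-axis form is the 1 ppm intercept; zero blank
noise reports LOD = 0 with a warning).  How a given instrument's SNR = 3
line was constructed is generally not recoverable from a published plot, so
the definition here is declared rather than inferred.  The replicate-
uniformity statistic is RSD = 100·sd/mean over replicate peak heights.

## Pipeline and determinism

`run_quantify` chains: stratified 70/30 level-wise split → region selection
on the training spectra → PCA-BP training and PLSR fit → evaluation on the
held-out spectra → calibration + LOD (+ per-level RSD table).  The JSON
report embeds the full config, its SHA-256 hash, the master seed and
library versions; rerunning the same config reproduces the report
byte-for-byte.  Stage seeds all derive from the single master seed.
Problem sizes used throughout the tests and the acceptance script — 180
spectra per dataset, 5 seeds for model medians, 50 seeds for
region-selection rates — are the package's default desk-scale study
conditions.

## Known limitations

* Single-Gaussian fits only; overlapping bands in one window would bias
  height and width (multi-peak deconvolution is out of scope).
* The variance-contribution rule assumes the analyte band dominates its
  window's variance; a strongly drifting baseline would need detrending
  first.
* The network's accuracy at the saturated end is information-limited by
  the multiplicative replicate noise (see above); no architecture change
  can recover what the signal does not contain.
* `peak_params` feature mode compresses a window to 4 numbers and is
  correspondingly less accurate; it exists to mirror the peak-parameter
  workflow, not as the recommended input.
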