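# Methods

This note documents the models, the estimators, the numerical choices,
and what the synthetic data do and do not emulate.

## Kinetic model and units

A growing microtubule plus end gains dimers at rate
v(c) = k_a·c − k_d (dimers/s), with c the free tubulin concentration in
µM. Nothing in the package clamps negative velocities: below the
critical concentration C_c = k_d/k_a the same law describes net
disassembly, which is what the seed-depolymerization analysis relies on.

Image-derived velocities are in µm/min; rate constants are in dimers/s.
Conversion uses `GeometryConstants`: 13 protofilaments × 8 nm dimer
repeat → 1625 dimers per µm. Published work rarely states the conversion
it used, so the geometry is configurable; all bundled values assume
13 × 8 nm. The bundled off-rates are derived as k_d = k_a·C_c from
published (k_a, C_c) pairs, since off-rates are rarely printed directly.

## The stochastic generator

`sample_trajectory` alternates growth intervals (exponential waiting
times with hazard f_cat, constant — no age dependence, matching the
single-frequency summaries the analysis produces) with shrinkage at
v_shrink back to the seed, then regrowth. Rescue is available
(`f_rescue`) but defaults to 0; in this assay regime rescues are not
observed. Each interval's realized slope carries multiplicative Gaussian
jitter (default CV 10%), representing filament-to-filament variability;
imaging noise is added separately at render time so the two sources can
be switched independently in tests.

Templated nucleation lags are exponential with rate
λ(c) = −ln(1 − p(c))/60 s, where p(c) = c^s/(C^s + c^s) is the 1-minute
success probability. Only the 1-minute integral of the hazard is
constrained by the assay read-out, so a constant hazard is the minimal
choice. When p(c) → 1 the rate is capped (default ε = 10⁻⁶) and a
warning is issued. Spontaneous nucleation counts per field are Poisson
with mean spont_slope·max(0, c − spont_Cc): exactly zero below the
critical concentration, linear above.

GMPCPP seed depolymerization is a deterministic constant-speed
shrinkage, optionally with per-frame localization noise.

### Bundled condition table

`data/default_conditions.csv` holds one row per condition. Kinetic
constants (k_a, k_d), Hill parameters (C, s), spontaneous critical
concentrations and the control seed-shrinkage speed are the fitted
values for tubulin alone and for CKAP2 at 0.125, 0.2, 0.5 and 1 µM.
Three kinds of entries are the package's own choices because no fitted
values exist:

* catastrophe rates (0.3 min⁻¹ control, falling to 0.01–0.05 min⁻¹ with
  CKAP2) — representative of in vitro dynamics at these tubulin levels
  and of the strong catastrophe suppression by CKAP2;
* shrinkage speed 10 µm/min — an order of magnitude above growth, as
  observed generally;
* spontaneous-nucleation slopes (2 MT field⁻¹ µM⁻¹ control,
  30 MT field⁻¹ µM⁻¹ at 0.2 µM CKAP2) — chosen to give tens of
  microtubules per field at the top of each assayed concentration
  range;
* the 0.2 µM CKAP2 row's kinetic and Hill entries are plausible
  interpolations between the 0.125 and 0.5 µM conditions; only its
  spontaneous-nucleation law is used quantitatively.

## Imaging model

Per frame, polymer is a line density of `photons_per_um` expected
photons per µm; the expected pixel signal is the geometric overlap of
the polymer with the pixel, blurred with an isotropic Gaussian PSF
(σ = 130 nm ≈ λ/2NA for 637 nm / 1.46 NA; the default photon budget of
1000 photons/µm/frame over a 20-photon background gives tip SNR ≈ 5).
Shot noise is Poisson on signal + background; read noise is Gaussian.
Kymograph rows are frames, columns are position with the origin at the
seed minus end; pixel k covers [k·px, (k+1)·px). Two channels mirror
the assay's labelling: a static seed channel and a dynamic lattice
channel. The renderer generates drift-free data — drift correction is a
preprocessing step for real data and out of scope.

## Tip tracking

Per row the candidate tip is the farthest pixel above background mean +
k·SD (k = 3; background statistics are median/MAD of the trailing 10% of
columns, which lie beyond the longest excursion by construction). The
sub-pixel position is the descending crossing of a level fixed per
kymograph at background + half the resolved-filament amplitude (the 75th
percentile of above-threshold pixels, iterated three times so PSF-tail
pixels do not drag it down). For a PSF-blurred filament end the
half-amplitude crossing sits at the true edge *independent of length*,
which is what keeps velocity estimates unbiased; a simple crossing of
the detection threshold sits 2–3 pixels beyond the tip by an amount that
grows as a short filament brightens, and that length-dependent offset
was measurable as a several-percent slope bias at slow growth before the
half-amplitude rule was adopted.

Rows whose signal never reaches `min_peak_fraction` of the resolved
amplitude carry a sub-resolution stub (length below roughly 2–4 PSF σ,
~0.25–0.45 µm) whose tip cannot be localized; they are reported missing.
Velocity-oriented analyses use a strict floor (0.9) so slopes are fit on
fully resolved positions only; lag-oriented analyses keep the permissive
default (0.5) so nucleation is timed as early as possible. The seed
channel, when present, provides the seed plus-end position to sub-pixel
accuracy (median over rows of its own half-amplitude edge), replacing
the pixel-quantized stored seed extent.

## Phase segmentation

Change-point detection minimizes per-segment OLS residuals plus a
BIC-style penalty (3·penalty_factor·σ̂²·log n per segment,
penalty_factor = 3), with σ̂ estimated robustly from second differences
(floor 10⁻⁶ µm). The dynamic program is exact, O(n²) via prefix sums,
with a minimum segment length of 5 frames; the strictly positive
penalty makes fewer segments preferred at equal fit.

Missing-frame policy: runs of up to 10 missing frames are bridged by
linear interpolation for the segmentation only; longer blind stretches
split the trace. If the position dropped by more than 0.15 µm (≥3× the
tracking noise) across a blind stretch, the gap is reported as a shrink
segment — the filament demonstrably depolymerized while unresolved —
which is what lets catastrophes be counted even when the shrink itself
was too fast or too short to image. Every reported slope is refit on
observed frames only, excluding one frame at internal breakpoints
(breakpoints are localized to ±1 frame). Adjacent same-phase segments
are merged only when they abut in time and their slopes agree within
25%; a genuine growth-rate change survives as two segments.

Phase labels: growth above +0.05 µm/min, shrink below −1 µm/min
(shrinkage is ~10× faster than growth), pause between. The pause band
and shrink threshold are configurable; the underlying assay has no
operational definition of a pause.

A catastrophe is a growth segment immediately followed by a shrink
segment. Growth censored by the end of the recording contributes growth
time but no event, so frequency = events / total growth time matches
the assay's estimator. Filament-level (event count, growth time) pairs
are retained so the bootstrap confidence interval resamples filaments,
the exchangeable unit (percentile CI, default 10⁴ resamples, seeded).

## Estimators

* `fit_growth_kinetics` — OLS on per-concentration *mean* velocities
  (the assay fits the mean curve; per-event weighting is available but
  off by default). C_c = k_d/k_a uses the delta method with the full
  (k_a, k_d) covariance. The kinetics drivers only accept growth
  segments lasting ≥ 60 s, the automated analogue of measuring slopes
  on clearly resolved kymograph excursions.
* `fit_nucleation_hill` — nonlinear least squares with endpoints fixed
  at 0 and 1; free parameters C and s. Initial values: C at the
  concentration whose fraction is nearest 0.5, s = 3; bounds C > 0,
  0.5 < s < 20. Data that do not span the transition (no fraction below
  and above 0.5) are refused rather than extrapolated.
* `nucleation_ecdf` — Kaplan–Meier product-limit cumulative incidence;
  equals the empirical CDF when nothing is censored.
* `fit_spontaneous_nucleation` — OLS of mean count vs concentration
  restricted to concentrations with mean count above a zero floor
  (default 0.5 counts/field), excluding the below-critical plateau;
  critical concentration = −intercept/slope with delta-method SE.
* `fold_change` — ratio of on-rate constants with first-order error
  propagation (verified against Monte Carlo in the tests).

## What the synthetic data do not emulate

Real kymographs contain stage drift, photobleaching, fluorophore
blinking, neighbouring filaments crossing the scan line, and non-Poisson
camera artefacts; the renderer has none of these. Catastrophe hazard in
real data can be age-dependent; the generator's is constant by
construction. Passing the recovery suite therefore demonstrates that the
analysis chain is unbiased and correctly calibrated *under the stated
model*, not that it is robust to every pathology of real microscopy
data.

## Problem sizes

The recovery suite and the acceptance script use 80 growth events per
tubulin concentration (3 concentrations for the control law, 5 for the
500 nM CKAP2 law, each filament imaged for 10 min at 2 s intervals),
150 seeds × 8 concentrations for templated nucleation, 14–20 fields per
concentration for spontaneous counts, and a single 600-frame / 1-min
interval depolymerization kymograph — comparable to the replicate sizes
of the underlying assays. With these sizes the recovered k_a, C_c,
Hill C/s and critical concentrations sit within a few percent of the
generating values across seeds; sampling spread dominates, with no
detectable residual bias.

## Known limitations

* Tip localization assumes one filament per kymograph line and a
  monotone intensity edge; overlapping filaments would confuse the
  farthest-crossing rule.
* Catastrophes that strike while the filament is still below the
  resolution floor (~0.3 µm) are undetectable in images; at the bundled
  conditions this affects a few percent of events and is visible in the
  render-loop catastrophe test as a small deficit.
* The spontaneous-field counter splits crossing filaments by skeleton
  endpoint counting (⌈endpoints/2⌉), which undercounts bundles thicker
  than two and is only exercised on synthetic geometries.
* `fit_growth_kinetics` accepts two concentrations (the algebra is
  defined) but standard errors then collapse to zero; three or more
  concentrations are required for meaningful uncertainties.
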