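# mtdynamics

Simulation and quantitative analysis of in vitro microtubule dynamics
experiments, built around the measurement chain of a TIRF reconstitution
assay: stabilized (GMPCPP) seeds template the growth of dynamic
microtubules, a camera records kymographs and fields of view, and the
analysis extracts growth kinetics, nucleation statistics, catastrophe
frequencies and depolymerization rates. The package is aimed at people
developing or validating such analyses — every stage of the chain is
available both as a stochastic generator (so ground truth is known) and
as an estimator (so recovery can be checked).

## The models

**Elongation.** The net dimer addition rate at a growing plus end is
linear in free tubulin concentration *c*:

v(c) = k_a·c − k_d  [dimers/s]

with apparent on-rate constant *k_a* (dimers µM⁻¹ s⁻¹) and off-rate
*k_d* (dimers/s). The critical concentration is C_c = k_d/k_a; velocities
convert to µm/min through the lattice geometry (13 protofilaments × 8 nm
dimers = 1625 dimers/µm). A linear regression of mean growth velocity
against concentration returns k_a (slope), k_d (−intercept) and C_c
(x-intercept, with a delta-method standard error).

**Dynamic instability.** Growth is interrupted by catastrophes at a
constant hazard f_cat (min⁻¹, exponential waiting times), followed by
rapid shrinkage back to the seed. Catastrophe frequency is estimated as
events per total growth time, with a bootstrap-over-filaments confidence
interval.

**Templated nucleation.** The probability that a seed nucleates a
microtubule within 1 minute follows an endpoint-constrained Hill law
p(c) = c^s/(C^s + c^s) with half-max concentration *C* and steepness
*s*. Lags are simulated as exponential with the rate chosen so the
60 s success probability equals the Hill law; censored lags are handled
with a Kaplan–Meier cumulative incidence.

**Spontaneous nucleation.** Per-field counts are Poisson with mean
linear in concentration above a critical concentration; the fitted
x-intercept of mean count vs concentration estimates that critical
concentration.

**Imaging.** Kymographs and fields are rendered with a 107 nm pixel,
Gaussian PSF (σ 130 nm), Poisson shot noise and Gaussian read noise.
Tip tracking localizes the filament end per frame by a half-amplitude
threshold crossing; a penalized change-point segmentation decomposes the
trace into growth/shrink/pause phases.

The bundled parameter table (`mtdynamics.load_default_params()`) holds
per-condition laws for purified tubulin alone and in the presence of the
mitotic spindle protein CKAP2, whose headline effects — a ~54-fold
increase in k_a, a 100-fold drop in the critical concentrations for
elongation and nucleation, and suppression of catastrophe and seed
depolymerization — are the quantities the recovery suite exercises.

## Worked example

Simulate 40 filaments at 5, 10 and 14 µM tubulin under the control law,
render each as a kymograph, track and segment the tips, and fit the
kinetic law — then do the templated-nucleation assay:

```python
from mtdynamics import load_default_params
from mtdynamics.pipeline import measure_growth_kinetics, measure_nucleation

params = load_default_params()
fit, _ = measure_growth_kinetics(params["control"], [5, 10, 14], 40,
                                 seed=7, label="control")
print(f"k_a = {fit.k_a:.2f} ± {fit.k_a_se:.2f} dimers/µM/s")
print(f"k_d = {fit.k_d:.2f} ± {fit.k_d_se:.2f} dimers/s")
print(f"C_c = {fit.C_c:.2f} ± {fit.C_c_se:.2f} µM")

hill, _ = measure_nucleation(params["control"],
                             [2, 4, 6, 8, 10, 12, 16, 20], 150,
                             seed=7, label="control")
print(f"C = {hill.C:.2f} ± {hill.C_se:.2f} µM, s = {hill.s:.2f} ± {hill.s_se:.2f}")
```

prints

```
k_a = 2.56 ± 0.02 dimers/µM/s
k_d = 7.31 ± 0.23 dimers/s
C_c = 2.85 ± 0.07 µM
C = 7.34 ± 0.22 µM, s = 3.09 ± 0.27
```

The fitted k_a and C_c recover the generating law (k_a = 2.6,
C_c = 2.89 µM) through the full imaging loop; the Hill fit recovers the
generating half-max (C = 6.85 µM, s = 3.37) from 150 seeds per
concentration within sampling error.

The same experiments run from the shell:

```bash
mtdyn --seed 7 all            # bundled default study design
mtdyn --config my_run.yaml all
```

`mtdyn all` writes fit tables (CSV), nucleation event tables, figures
and a plain-text report to the output directory; `simulate`, `render`,
`analyze`, `fit` and `report` expose the individual stages.

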