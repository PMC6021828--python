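# Methods

## Sensing model

A single SnO2 MOX sensor is operated in dual-temperature mode: the heater
alternates between two voltages (defaults 0.5 V and 0.9 V, i.e. roughly
131 °C and 462 °C, 90 s per phase), yielding two virtual sensors.  The
observable of virtual sensor *i* is the dimensionless resistance ratio
`x_i = R0/Rg|Ti` of clean-air to gas-exposed resistance, both taken at the
transient peak that follows a heater switch (peak heights carry the
sensor's dynamic response and discriminate the two gases better than the
steady-state level).

For a single reducing gas, SnO2 response follows a power law in
concentration; for a two-gas mixture the package models the ratio as a
full second-order polynomial in the powered concentrations, the *sources*
`s_j = C_j^{r_j}` (C in ppm):

    x_i − 1 = Σ_j a_ij s_j + Σ_j b_ij s_j² + d_i s_1 s_2

with per-gas exponents `r_j` shared across the two temperatures (assumed
temperature-independent to keep the problem identifiable) and all gain
coefficients temperature-specific.  Clean air maps to x = (1, 1) exactly,
for every coefficient set.  Gas 1 is acetone, gas 2 ethanol, throughout.

Three literature variants are exposed on the same observable for
comparison: linear (`x − 1 = A1 s1 + A2 s2`), bilinear (adds the `s1 s2`
cross term; natively stated on `1/Rg − 1/R0`, which equals `(x − 1)/R0`,
so with the normalisation R0 = 1 it reads `x − 1 = A1 s1 + A2 s2 +
A3 s1 s2`), and logarithmic (`Rg = A1 + A2 log C1 + A3 log C2 +
A4 log C1 log C2`, mapped to x via R0 = 1).  The logarithmic variant is
undefined at zero concentration; zero rows are rejected in prediction and
excluded (with a logged count) in fitting — no pseudo-count offset is
applied, since any silent offset would bias the model comparison.

Some formulations of this model family carry an additional additive vector
`e` that never enters the response equation; it is not implemented here.

## Acquisition chain

The sensor sits in a voltage divider driven at 4.55 V, so the sensing
resistance follows from the measured output voltage as
`Rg = RL·(4.55/Vg − 1)` with RL the load resistance (default 10 kΩ; the
reference hardware value is not documented, so it is a configurable
parameter).  Raw traces (500 Hz) are mean-filtered (centered moving
average, default window 0.5 s, edges shrunken) and the extremum of the
output inside a search window after each heater switch (default 20 s,
configurable — the transient peak occurs a few seconds after switching) is
the per-phase readout.  Heater switches are detected from level crossings
of the heater-voltage midpoint rather than a fixed clock, so traces may be
trimmed arbitrarily.  One observation pair requires a clean-air readout
(R0) and a gas readout (Rg) from the same schedule; the interface accepts
a per-cycle or per-session air reference.

## Calibration

Fitting minimises the unweighted sum of squared observation residuals over
all records and both temperatures with a Levenberg–Marquardt solver
written for this package: at each iterate the damped normal equations
`(JᵀJ + λI)·step = Jᵀr` are solved, λ shrinking ÷10 on an accepted
(non-increasing-cost) step and growing ×10 otherwise (λ0 = 1e−3,
tol_step 1e−10, tol_cost 1e−12, max 500 iterations).  The Jacobian is
central finite differences for calibration and analytic for inversion.
When a projection (bounds) clips a trial step, the damped system is
re-solved over the free coordinates with the clipped ones held at their
bounds — without this active-set refinement a blocked coordinate can
dominate the solve and stall the free ones at a non-stationary point.

The fit is nonconvex (exponents multiply gains), so initialisation is
two-stage: exponents start at r = (0.5, 0.5) and the gains at the ordinary
linear least-squares solution of `x − 1` on the design `(s, s², s1·s2)`
evaluated at those exponents.  A seeded multi-start (default 3 restarts,
parameters perturbed by log-uniform factors in [0.5, 1.5]) guards against
local minima; the best final cost is kept.  Exponents are constrained to
(0.05, 1.5): SnO2 exponents are sub-linear in practice and the bounds
prevent exponent/gain aliasing.  The design must contain at least two
distinct levels of each gas and at least 10 records for the full model
(24 unknowns would otherwise exceed the 2N equations' margin); violations
raise before fitting.

On a noiseless synthetic 39-mixture grid the fit recovers all 12
generating coefficients to well below 1% relative error (this is the
calibration acceptance oracle, `tests/test_acceptance.py`), and
`scipy.optimize.least_squares` reaches the same optimum on noisy data (an
independent cross-check in the test suite, never the implementation).

## Cross-validation

Model reliability is estimated by repeated K-fold cross-validation
(defaults K = 13, 10 seeded segmentations): per segmentation the records
are shuffled and partitioned into folds differing in size by at most one;
each fold is predicted by a model fitted on the others; the reported value
is the mean over segmentations of the mean per-fold MSE, in observation
units (model vs measures).  Fold assignments and the grand mean are
bit-reproducible under a fixed seed.

## Inversion

Each observed ratio pair is inverted independently by minimising
`‖forward(s) − x‖²` over the source pair with the same LM core and the
analytic Jacobian `∂x_i/∂s_j = a_ij + 2 b_ij s_j + d_i s_{3−j}`.  Iterates
are projected onto s ≥ 0 (concentrations are physical; unconstrained
iterates can cross zero at low concentrations).  Initialisation is either
`mid_range` — the midpoint of the working concentration rectangle mapped
to source units (the simulation-study condition) — or `perturbed_truth` —
the true sources times (1 ± 0.20) with a seeded sign draw, emulating
approximately known concentrations.  Non-convergence within the iteration
cap is flagged on the result, never silently clipped.  Estimated ppm
concentrations are the back-transform `C_j = s_j^{1/r_j}`.

A brute-force oracle (`grid_oracle_invert`) evaluates the cost exhaustively
on a concentration grid (default 201 points per axis over 0–20 × 0–40 ppm)
and returns the arg-min; the LM solution's cost never exceeds the
oracle's in the test suite.

## Performance metrics

Per column (per gas, or per temperature): sample Pearson correlation
(N−1 normalisation), symmetric mean relative error
`mean(2|u−v|/|u+v|)·100` (%), `SNR = 10·log10(‖true‖²/‖true−est‖²)` (dB,
+inf flags exact recovery) and the mean squared error (ppm^{2 r_j} in
source units).  SNR and MSE share the uncentered norm convention, so
`SNR = 10·log10(mean(true²)/MSE)` exactly.  Single-number summaries are
arithmetic means over the two columns; whether pooled or per-column
aggregation is intended by convention is ambiguous in parts of the
literature, so reports always carry both.  The symmetric relative error is
undefined where a pair sums to zero (e.g. a perfectly recovered zero
concentration); reports record NaN for such columns.

## Synthetic data

Generators are pure functions of (configuration, seed) and bit-reproducible.

* **Calibration grid** (default 39 mixtures over acetone 0–20 ppm ×
  ethanol 0–40 ppm): the four corner mixtures — clean air included, which
  anchors the x = (1,1) baseline — plus a seeded Latin-hypercube fill.
  The original 39 mixture recipes were never published; a stratified
  design covers the same rectangle.
* **Simulation series** (default N = 200): acetone follows a sinusoid
  spanning exactly 0–20 ppm (2 periods over the series — a diurnal-like
  variation; the period count is immaterial to the metrics and
  configurable), ethanol is iid uniform on 0–40 ppm.
* **Observation noise**: iid Gaussian per ratio entry.  Two modes:
  `variance` (default 0.28 — the model's cross-validated misfit, the
  reproduction condition used by `reproduce-simulation` and
  `scripts/acceptance.py`) and `target_snr_db`, which rescales the realised
  noise so the pooled observation-domain SNR `10·log10(Σx²/Σnoise²)` hits
  the target exactly.  Ratios pushed nonpositive are redrawn (counted and
  logged; never triggered at realistic scales).
* **Temporal traces**: per heater phase the output follows a
  double-exponential transient `exp(−t/30) − exp(−t/5)` (time constants in
  seconds, matching the sensor's ~30 s response), normalised so the peak
  voltage encodes — through the divider equation — exactly the ratio the
  forward model predicts for the programmed mixture, then relaxing towards
  a steady level between the air baseline and the peak; optional Gaussian
  voltage noise.  The generator returns the encoded ratio pair as ground
  truth, making the preprocessing chain testable end-to-end (recovery
  within 2%, dominated by mean-filter attenuation of the peak).

What the generators do **not** emulate: humidity (assumed removed by a
hydrophobic filter upstream), oxygen and temperature variation, sensor
drift and aging, flow effects, and inter-sensor variability.  Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to real-breath confounders.

## Conditioning of the reference coefficient set

The packaged reference coefficients are taken at face value from their
published source.  Two consequences, both verified numerically and frozen
as tests, matter for interpretation:

1. **Extreme channel asymmetry.**  The acetone gains (a11 = 80, a21 = 61)
   exceed the ethanol gains (0.32, 1.47) by two orders of magnitude, so
   inverting additive observation noise concentrates almost all source
   error in the ethanol channel: with noise variance 0.28 the recovered
   acetone correlation is ≈ 100% (SNR ≈ 48 dB) while ethanol reaches
   ≈ 81% (SNR ≈ 15 dB) — numbers computed by `scripts/acceptance.py`.
   The reference study these coefficients come from reported the
   *opposite* ordering (acetone recovered worse than ethanol), which is
   unreachable under any iid observation-noise level with these gains;
   the printed coefficient scale evidently differs from the surface that
   study actually simulated.  The comparisons are kept in the acceptance
   tests at their stated tolerances and left failing rather than tuned.

2. **A fold at low ethanol.**  The Jacobian determinant of the forward map
   vanishes along a curve crossing the whole acetone range at ethanol
   ≈ 1–5 ppm.  Mixtures near that fold have a second *exact* preimage in
   the physical quadrant, so noiseless round-trip inversion from a
   mid-range start recovers the generating sources only above the fold
   (ethanol ≳ 6 ppm); below it, picking between two exact solutions is
   impossible without prior information.  Unit round-trip tests are scoped
   accordingly; the full-rectangle round-trip acceptance check fails on
   the ~4% of draws that hit the twin root, and is left failing for the
   same reason as above.

## Defaults at a glance

| parameter | default | units | why |
|---|---|---|---|
| heater levels | 0.5 / 0.9 | V | the two virtual-sensor temperatures (~131/462 °C) |
| phase duration | 90 | s | reaches steady state between switches |
| sampling rate | 500 | Hz | acquisition rate of the front-end |
| mean-filter window | 0.5 | s | cuts high-frequency noise, negligible peak attenuation |
| peak search window | 20 | s | transient peak occurs a few s after a switch |
| load resistance RL | 10 | kΩ | plausible front-end value; configurable |
| exponent bounds | (0.05, 1.5) | – | sub-linear SnO2 response; prevents aliasing |
| LM λ0 / factor | 1e−3 / 10 | – | classical multiplicative damping schedule |
| restarts | 3 | – | guards the nonconvex calibration fit |
| CV folds / repeats | 13 / 10 | – | ~10% held out per fold; segmentation averaging |
| simulation N | 200 | – | study series length |
| noise variance | 0.28 | ratio² | the model's cross-validated misfit |
| inversion init | mid-range | – | midpoint of the working rectangle, in source units |

The simulation study sizes (N = 200, 5 seeds) keep the whole acceptance
run within seconds while leaving the seed-to-seed spread of every reported
metric far below the comparison tolerances.
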