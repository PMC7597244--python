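# Methods

## Models

Both tissue models are five-element one-ports over three resistors and two
constant phase elements (CPEs).  A CPE has impedance `1/(s^α C_α)`; on the
real-frequency axis the package uses the phasor substitution
`s^α → ω^α (cos(απ/2) + j sin(απ/2))`, which gives the exact magnitude
`1/(C_α ω^α)` and constant phase −90α°.  The two topologies are

- Cole (double dispersion): `Z = R_ss + (Z_s ∥ R_s) + (Z_d ∥ R_d)`;
- recurrent ladder (n = 2):  `Z = R_ss + Z_s ∥ (R_s + (Z_d ∥ R_d))`,

with `x ∥ y = xy/(x+y)` evaluated in complex arithmetic.  Both satisfy
`Z → R_ss + R_s + R_d` as ω → 0 and `Z → R_ss` as ω → ∞.  With both orders
fixed at 0.5, each family spans degree-2/degree-2 rational functions of
√s, so the two topologies can represent exactly the same responses with
different element values.  This is the central observation the package
encodes: the recurrent re-fit of a Cole-generated spectrum converges to a
residual on the order of floating-point noise, and topology choice cannot
be decided from fit quality on such data.

Reference spectra are regenerated from packaged mean Cole parameters for
two age groups of human teeth dentin measured in saline, on a grid of 1400
log-spaced frequencies from 10 mHz to 10 MHz (log-uniform in cyclic
frequency, endpoints inclusive).  Degrees are used in every public
interface; radians only internally.

## CNLS fitting

The objective is `Σ_i w_i [(ΔRe Z_i)² + (ΔIm Z_i)²]`.  Defaults:

- **weighting** `modulus` (`w_i = 1/|Z_i|²`): the dentin spectra span six
  orders of magnitude in |Z|, and modulus weighting makes every decade
  count; `unit` weighting is available for comparison.  Under modulus
  weighting the objective is invariant to a uniform impedance rescale of
  data and model; under unit weighting it scales by c².
- **optimizer** Powell's direction-set method (derivative-free), run from
  `restarts = 5` starting points: the asymptotic initializer first, then
  log-space Gaussian jitters of it (SD 0.3, seeded).  The best restart is
  returned; everything is deterministic under the seed.
- **parameterization**: resistances and pseudo-capacitances in natural
  log (positivity by construction); free CPE orders, when enabled
  (`free_equal`, `free_independent`), through a logit map onto (0, 1).
  Default is both orders fixed at 0.5, matching the packaged fits.
- **tolerances**: Powell `ftol 1e-14`, `xtol 1e-12`, up to 20 000
  iterations — tight because the noiseless re-fits are expected to reach
  residuals near machine precision.

The asymptotic initializer reads `R_ss` from the top of the band and the
DC sum from the bottom, with two refinements that matter at α = 0.5
because the dispersions converge only as √ω:

- high end: linear fit of `Re Z` against `ω^(−α)` over the top decade;
  the intercept strips the residual CPE contribution (the raw 10 MHz
  readout is still ~8 % above `R_ss` for the young group);
- low end: an algebraic (Kåsa) circle fit to the lowest-frequency seventh
  of the Nyquist arc, intersected with the real axis.  At 10 mHz the
  old-group dispersion is far from complete (`Re Z` is only 24 % of the
  DC sum), so plateau readouts are useless there; the circle intercept
  recovers the DC sum to better than 0.1 % for both groups.

The remaining resistance is split 1:9 between `R_s` and `R_d` and the
pseudo-capacitances are seeded from the mid-band |Z|; the split is
arbitrary but irrelevant, since the fits converge from jittered starts
anyway.  Flat, purely resistive spectra degenerate gracefully (series
resistances floored at a small ε).  Note the Cole topology has an exact
stage-swap symmetry — `(R_s, C_s) ↔ (R_d, C_d)` — so recovered labels may
be exchanged; comparisons in the tests account for this.

## Goodness-of-fit panel

MAE, RMSE, NSE, WIA and LCE follow their standard definitions (see
README).  R² is the squared Pearson correlation of reference and test
values, *not* `1 − SSres/SStot` — the latter is already NSE, and the panel
reports both as distinct statistics.  Error statistics (max, mean, median,
sample SD with ddof = 1) are taken over per-point absolute relative errors
of a chosen component: Re(Z), −Im(Z) or |Z|.  Points with an exactly zero
reference component are excluded and counted in the log.  All statistics
are computed on whatever grid the spectra share; the packaged regression
values use the 1400-point reconstruction grid.

CPE characterization reads the effective order per frequency from the
phase (`α_i = −θ_i/90`), the effective pseudo-capacitance from the
magnitude using the mean order (`C_i = 1/(|Z_i| ω_i^ᾱ)`), and reports
means, SDs and coefficients of variation `CoV = 100·SD/mean`, plus
magnitude errors against the ideal CPE and phase errors against −90α°.

## Valsa synthesis

A CPE is emulated by a shunt `R_p/C_p` in parallel with m series-RC
branches (admittance `1/R_p + jωC_p + Σ jωC_k/(1 + jωR_kC_k)`).  Synthesis
is memetic:

1. **Analytic seed** from the spectral representation of `s^(−α)`: branch
   time constants log-spaced across the band, `C_k ∝ τ_k^(1−α)`,
   `R_k = τ_k/C_k`; `R_p` three times the CPE impedance level at the low
   band edge, `C_p` 0.35 of the CPE capacitance level at the high edge.
   For 13 branches over 9 decades this seed alone is inside ~1.5° ripple.
2. **Genetic algorithm** on the log of all 2m + 2 values: fitness is the
   maximum absolute phase deviation from −90α° on a 100-point log grid;
   binary tournament selection, uniform crossover (rate 0.5), per-gene
   Gaussian log-space mutation (rate 0.15, SD 0.03), (µ+λ) elitist
   survival; population 60, 500 generations by default, all seeded.
3. **Local polish**: Levenberg–Marquardt least squares on the phase
   residuals from the best individual (a plain GA plateaus above the 1°
   target at practical budgets; the polish closes the gap and typically
   lands near 0.3°).
4. **Magnitude rescale**: phase is invariant under `R → κR, C → C/κ`, so κ
   is chosen to centre the log-magnitude error band around zero.  The
   residual few-percent |Z| error at the band edges is the integrated
   effect of the tiny order bias and cannot be removed by rescaling.

If the ripple tolerance is unreachable (e.g., one branch across three
decades, where exhaustive local search bottoms out near 18.5°), the best
candidate is returned with `converged = False`.

E-series snapping uses the union of the E24 and E96 significand sets with
a nearest-in-log rule; only that combination is consistent with all the
packaged component values (E24-only or E96-only each mispredict some).
Snapping the packaged networks is a no-op (every value is a series
member), and snapping a synthesized network costs at most about a factor
two in phase ripple.

## Robustness analyses

- **Temperature**: linear tempcos, defaults 200 ppm/°C (R) and 30 ppm/°C
  (C), envelope over four corners — both temperature extremes (−40, +125
  vs nominal 27 °C) with both drift signs applied uniformly per component
  class.  Per-frequency worst-case |Z| and phase deviations are returned;
  the packaged circuits stay under 2 % / 0.5°, consistent with a uniform
  ~±2 % resistor drift at the extremes.
- **Monte-Carlo**: every R and C perturbed independently per iteration by
  a Gaussian with σ = tolerance/3 (±x % read as a 3σ bound, the common
  SPICE convention; `sigma_rule` is configurable), 200 iterations at a
  query frequency (1 Hz by default), seeded.
- **Thermal noise**: via Nyquist's theorem on the port, density
  `√(4kT·Re Z(jω))` in nV/√Hz for B = 1 Hz — equivalent to per-resistor
  superposition for a passive network, since lossless capacitors are
  noiseless.  Default temperature 300.15 K (27 °C).

## Synthetic noise model

`add_measurement_noise` perturbs spectra in polar form — multiplicative
Gaussian magnitude noise (CV) and additive Gaussian phase noise (degrees),
independent per point — matching how EIS analyzer accuracy is specified.
It emulates instrument noise only: no electrode polarization, stray
capacitance, drift or frequency correlation.  Tests passing on such data
show estimator correctness under ideal i.i.d. polar noise, not robustness
to the structured artefacts of a physical saline cell.

## I/O

CSV spectra (`frequency_hz,re_z_ohm,im_z_ohm`, strictly ascending, 15
significant digits) round-trip to 1e−12 relative.  Netlists are generic
SPICE3 R/C cards with one `.subckt` per CPE network and deterministic
formatting; `evaluate_netlist` re-parses and solves them by modified nodal
analysis and is used in the tests as an independent check of the
closed-form impedance code.

## Problem sizes and determinism

Everything runs on the study-scale inputs: 1400-point spectra, 13-branch
networks, 200 Monte-Carlo iterations.  The test suite trims only where
statistically equivalent (250-point grids for fit-recovery properties,
reduced GA generations with the seeded pipeline).  Every stochastic
component — fit restarts, GA, Monte-Carlo, noise — takes an explicit
integer seed and is bit-reproducible under it.

## Known limitations

- Only n = 2 recurrent bifurcations are validated; deeper ladders and
  fractional-order inductors are out of scope, as are time-domain
  fractional operators (everything lives in the Laplace/frequency
  domain).
- No uncertainty quantification on fitted parameters.
- The GA will not reproduce any particular published component list —
  stochastic search admits many near-equivalent networks; only the
  evaluated performance of a network is meaningful.
- Component perturbations are uncorrelated; real part batches correlate,
  and real capacitors have ESR and dielectric absorption that the ideal
  R/C model ignores.
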