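# Methods

`aqpkit` implements the quantitative chain behind functional
characterization of insect aquaporins: a forward biophysical model of
*Xenopus* oocyte swelling, estimation of water (Pf) and solute (Ps)
permeability coefficients from area time courses, comparative-Ct
relative expression for tissue/lifestage profiling and RNAi knockdown
time courses, and blood-meal excretion / urea / fecundity phenotype
statistics. Every stage can be driven by the built-in seeded
generators, so the whole pipeline is testable without laboratory data.

## Oocyte swelling model

The oocyte is a single well-mixed compartment of osmotically active
volume `V` behind a membrane of fixed area `S`. Water flux follows the
osmotic gradient:

    dV/dt = Pf · S · Vw · (osm_in(t) − osm_out)

with the internal impermeant-osmolyte amount conserved, so
`osm_in(t) = osm_in0 · V0 / V(t)`. In a solute challenge a permeant
solute additionally crosses the membrane,

    ds/dt = Ps · S · (sol_out − s/V)

and `s/V` contributes to the internal osmolarity; `osm_out` is the
*total* bath osmolarity including the test solute.

Assumptions, deliberately matching the idealizations under which the
initial-slope formulas are exact:

* constant surface area `S` during swelling — a real oocyte unfolds
  microvilli as it swells, so at large `V/V0` the model under-counts
  area and the fixed-`S` inversion formula progressively
  underestimates the true Pf;
* the whole volume is osmotically active (no solid fraction), which
  keeps the equilibrium closed-form: `V/V0 → osm_in0/osm_out`
  (2.857 for the standard 200 → 70 mOsm challenge);
* no membrane tension or unstirred layers.

The system is integrated with `scipy.integrate.solve_ivp` (RK45,
relative tolerance 1e-10); the swelling relaxation is first-order and
monotone with no overshoot, which the tests assert, and internal
amounts are conserved to better than 1e-6 relative. Osmolarities and
concentrations enter the API in mOsm/mM and are converted to
amount/cm³ (×1e-6) in exactly one module (`aqpkit.units`).

Hg²⁺ inhibition is modeled phenomenologically as a multiplicative
reduction of Pf (default factor 0.2, i.e. 80% block) with
2-mercaptoethanol reversal restoring the factor toward 1 (default
0.9). Binding kinetics are out of scope.

### Solute-assay conventions

Two conventions deserve explicit notice:

1. The Ps inversion formula implemented here,
   `Ps = V0·slope / (S·Vw·|Δsol|)`, includes the molar volume of
   water `Vw`. A sizeable part of the oocyte literature defines Ps
   without `Vw` (and a quasi-steady physical inversion of the coupled
   model would instead read `Ps = c_out·V0·slope / (S·Δsol)`). The two
   differ by a constant factor, so cross-study comparisons must check
   which convention was used.
2. In the coupled model, volume change *lags* solute entry: at `t = 0`
   in an isosmotic bath the volume slope is exactly zero and ramps up
   as internal solute accumulates (relaxation time
   `V0/(Pf·S·Vw·c_out)`, ≈ 280 s at Pf = 2×10⁻² cm/s). An
   initial-slope Ps from a short window therefore reflects the
   water-limited transient, not the pure solute permeability; Ps
   values from this assay are comparative (construct vs control), not
   absolute. This is why the package's solute tests validate the
   forward model against an independent integrator rather than
   asserting a Ps round trip.

Both estimators use the *magnitude* of the gradient so influx-driven
swelling yields positive coefficients (the literal `sol_in − sol_out`
ordering would make Ps negative for influx).

## Permeability estimation

`V/V0 = (At/A0)^{3/2}` converts each oocyte's cross-sectional areas to
relative volume using its own first frame as `A0` (never a cohort
average); the initial slope is an ordinary least-squares fit of `V/V0`
on `t` restricted to `t ≤ window`, with free intercept, reported with
its standard error and R². Defaults:

* geometry `V0 = 9×10⁻⁴ cm³`, `S = 0.045 cm²`, `Vw = 18 cm³/mol` —
  the standard oocyte constants (note `S` is exactly the surface of
  the sphere holding `V0`, which is also how the generator maps
  volumes back to areas: `A = A0·(V/V0)^{2/3}`, `A0 = πr²`);
* fit window 20 s of the 60-s record. The window trades noise
  (longer is better) against internal-dilution bias: as the oocyte
  swells the gradient shrinks, so the OLS slope underestimates the
  `t = 0` slope by ≈ 3.5% at 20 s, and the bias grows monotonically
  with the window (the package exposes this as a testable property);
* post-equilibration internal osmolarity 200 mOsm, overridable;
* fits with R² < 0.8 are flagged `low_quality` but never dropped —
  exclusion is the analyst's decision, and every flag is logged.

Fits are per oocyte, then group statistics are computed across oocyte
coefficients (rather than fitting pooled trajectories); this matches
designs that report n ≥ 5 individual oocytes per group. Group
comparison follows the assay convention: two groups → two-sided Welch
t-test (the unequal-variance form, since equality is rarely
defensible for permeability data); three or more → one-way ANOVA with
Tukey-HSD-adjusted pairwise p-values (scipy implementations; the
statsmodels Tukey is used as an independent cross-check in the test
suite).

## Relative expression (comparative Ct)

Replicate Cts are averaged per (group, gene) before differencing
(Livak & Schmittgen's formulation): `ΔCt = Ct_target − Ct_ref`,
`ΔΔCt = ΔCt_group − ΔCt_calibrator`, `RQ = 2^(−ΔΔCt)`, so the
calibrator's RQ is exactly 1 by construction. Replicate SDs combine
as `sqrt(sd_t² + sd_r²)` and propagate to the fold range
`2^{−(ΔΔCt ± SD)}`. The occasionally printed form "−2^ΔΔCt" is a typo
for `2^(−ΔΔCt)` and is implemented as the latter.

Primer sets are admitted through a dilution-series efficiency gate:
`E = 10^{−1/slope} − 1` from the OLS slope of Ct vs log10 relative
template (so a perfect doubling gives slope −3.3219 and E = 1), gate
0.9 ≤ E ≤ 1.1. Failing genes are *excluded with a warning*, not
efficiency-corrected (no Pfaffl-type model, single reference gene
only — both are explicit non-goals). Slopes ≥ 0, or E > 1.5, are
rejected outright as malformed input.

`knockdown_timecourse` quantifies a dsRNA treatment against its
matched-day control (per-day calibrator), carrying every non-target
gene along so off-target effects can be checked as RQ ≈ 1; days
missing a group are skipped with a warning.

## Phenotype endpoints

* **% excreted** at hour *n*: `100·(W_t0 − W_tn)/(W_t0 − W_{t−1})`,
  reported as a positive magnitude (the weight-difference form is
  negative as written). Weight gains after t0 and non-monotone
  reversals are flagged, never truncated: balance jitter is data.
* **Engorgement**: `100·(W_t0 − W_{t−1})/W_{t−1}`.
* **Urea**: OLS standard curve (linear, per the colorimetric kit's
  read-out; the standard levels are caller-supplied), in-reaction
  nmol `(A − intercept)/slope`, scaled by well/sample volume
  (100 µL / 20 µL = 5×) to per-bug nmol. Absorbances below the
  intercept floor at 0 with a warning; above the top standard they
  are returned flagged as extrapolated.
* **Fecundity**: per-bug total eggs until oviposition ceased; the
  daily series is retained but not modeled further (no survival/life
  table analysis).

All two-group endpoints use the two-sided Welch t-test with the
difference of means and its 95% CI (confidence level fixed; sidedness
chosen two-sided as the conservative default).

## Synthetic generators

All generators take explicit integer seeds (`numpy.random.default_rng`;
no global state) and are bit-reproducible. Defaults encode the study
conditions; where the assays' noise magnitudes are unreported the
defaults below are one-time choices of realistic values, overridable
per call (and via the CLI's YAML config):

* **Swelling cohorts** — per-oocyte Pf (and Ps) drawn lognormal
  (positive, right-skewed) around the cohort truth, default CV 10%;
  trajectory from the forward model; areas via the sphere relation
  with multiplicative lognormal noise, default CV 2% (a plausible
  segmentation error for microscope area extraction); 60-s records
  sampled at 1 s (a typical frame-analysis interval for
  digital-camera swelling assays); 5 oocytes per cohort.
* **Ct tables** — target Ct = 25 − log2(fold) + N(0, 0.15²) cycles;
  reference gene at Ct 20 in every group; 3 replicates per group.
* **Bug cohorts** — unfed weight lognormal around 4.0 mg (CV 15%);
  engorgement N(318, 72²) % of unfed weight; excretion follows
  `plateau·(1 − e^{−kt})` with plateau 0.5 of the meal, half-time
  8 h, per-bug lognormal rate variability (CV 20%), and 0.05 mg
  balance noise; the treatment group's rate is scaled by the effect
  multiplier. Excreta urea is proportional to 24-h mass excreted
  (5 nmol/mg) and reported as a well absorbance on the default
  standard curve. Egg totals are negative binomial (mean 12,
  dispersion k = 8 — counts are over-dispersed) spread over a
  decaying daily profile; a knockdown that doubles fecundity is
  expressed through an egg multiplier.
* **Urea plates** — absorbance = slope·nmol + intercept + read noise
  (defaults 0.02/nmol, 0.05, 0.005).

With all noise switched off each generator is an exact round-trip
oracle for its estimator, and the tests use them that way.

What the generators do *not* emulate: image formation (areas are the
starting point, not micrographs), oocyte-batch effects and injection
variability, qPCR plate effects or multi-reference normalization,
redundant in-vivo channels that blunt knockdown phenotypes, and any
correlation between a bug's excretion rate and its meal size. Passing
tests therefore demonstrate correctness of the computations and
calibration of the statistics under these stated conditions, not
robustness to every failure mode of real data.

## Statistical calibration and a known estimator limitation

Monte-Carlo checks included in the acceptance suite (problem sizes
chosen to keep the full run in a few seconds): under the null
(identical excretion law in both groups, n = 10/group, 1000
replicates) the Welch test rejects at the nominal 5%; at a halved
excretion rate it detects the reduction in essentially 100% of 200
replicates.

A genuine limitation, derivable in closed form and confirmed by
simulation: single-oocyte Pf from a 20-s OLS window is *noisy*.
Multiplicative area noise of CV ε produces ≈ 1.5·ε relative noise on
each `V/V0` point; the OLS slope standard deviation is
`σ/√Σ(t−t̄)²`, which at ε = 2%, 1-s sampling and a 20-s window is
≈ 46% of the true 2.34×10⁻³ s⁻¹ slope — the swelling signal over 20 s
(≈ 4.7% volume change) is comparable to the per-point noise (≈ 3%).
Combined with the ≈ −3.5% window bias and the √5 sampling error of a
5-oocyte cohort mean, the probability that a cohort-mean Pf lands
within 10% of the population truth is ≈ 30–35% at these settings (the
acceptance suite measures it rather than hiding it). Practical
remedies are faster sampling, longer windows with a dilution-corrected
model, or larger cohorts; none is silently applied.

## Numerical choices

* RK45 with rtol 1e-10 / atol `V0`·1e-13; integrator failures raise,
  never truncate.
* OLS fits are closed-form (no iterative optimizer); degenerate
  zero-residual fits report R² = 1; slope standard errors are NaN for
  2-point fits (no residual degrees of freedom).
* Degenerate group comparisons (identical data) return statistic 0,
  p = 1 instead of a 0/0 NaN.
* `equilibrium_relative_volume(0, osm_out)` returns the mathematical
  limit 0 and is documented as a model floor; `osm_out = 0` raises
  (unbounded swelling).
* Ties/tolerances: window membership uses `t ≤ window·(1+1e-12)`;
  the urea top-standard extrapolation flag has a 1e-9 absorbance
  guard so the top standard itself is in range.
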