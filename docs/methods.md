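# Methods

## Model structure and assumptions

The growth model tracks two state variables per unit ground area:
non-structural dry mass (mobilizable carbohydrates) and structural dry mass.
Photosynthate enters the non-structural pool scaled by the CO₂→CH₂O
molecular-weight ratio c_α = 0.68; conversion to structure proceeds at the
specific rate r_gr with a (1−c_β)/c_β conversion loss (c_β = 0.8);
maintenance respiration drains the pool in proportion to structural mass.
The canopy is treated as horizontally uniform with no leaf-area dynamics:
light interception is a Beer-law function of structural mass alone (c_K =
0.9, c_lar = 0.075 m² g⁻¹), so morphological acclimation to spectrum —
a real and sometimes dominant effect — is deliberately outside the model.
Canopy temperature equals the air set point (no energy balance), and
photoperiod is realized as piecewise-constant irradiance with I = 0 in the
dark.

Temperature sensitivity enters through Q10 laws: growth 1.6 (anchored at
20 °C), respiration 2.0 (anchored at 25 °C), and the CO₂ compensation point
2.0 with Γ(20 °C) = 40 ppm. Carboxylation conductance is an empirical
parabola in temperature whose roots sit at 5 and 40 °C; evaluating outside
that open interval raises rather than returning a non-positive conductance.
CO₂ concentrations quoted as mL L⁻¹ in the source literature (402, 410,
350, 1000, Γ = 40) are treated as ppm (µmol mol⁻¹), and the CO₂ density
coefficient c_ω = 1.83×10⁻³ is read as g m⁻³ per ppm so the units of the
photosynthesis equation close.

All spectral quantities live on 400–750 nm: PAR plus far-red. Waveband
edges are half-open [lo, hi) with far-red closed at 750 nm, so a shared
boundary is never counted twice. Integration is trapezoidal on the supplied
grid (instrument exports are typically ~1 nm steps; irregular grids are
accepted), with linear interpolation at band edges. Photon flux converts to
irradiance via the molar photon energy N_A h c/λ with CODATA 2018
constants.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| c_ε | 1.7×10⁻⁵ | g J⁻¹ | quantum use efficiency; the spectrum-dependent coefficient |
| c_gr_max | 5×10⁻⁶ | s⁻¹ | saturation growth rate at 20 °C; caps exponential growth at ~0.43 day⁻¹ |
| c_τ | 0.15 / 0.14 | – | root mass fraction, soil / hydroponic |
| g_bnd, g_stm | 0.007, 0.005 | m s⁻¹ | boundary-layer and stomatal conductances |
| plant_density | 1 | m⁻² | per-area ↔ per-plant conversion only |
| I_ref | 32.8 | W m⁻² | RI normalization reference (pure-red 180 µmol m⁻² s⁻¹ treatment) |

`plant_density` defaults to 1, i.e. per-plant grams are compared directly
with model g m⁻². The source experiments never state the conversion they
used; surfacing it as an explicit parameter makes the assumption visible
instead of baking it in.

## Calibration

Harvest dry mass is strictly increasing in c_ε whenever the schedule
carries light and CO₂ above compensation, which the calibrator verifies
empirically on its bracket (default [10⁻⁷, 10⁻⁴] g J⁻¹, auto-expanded up to
[10⁻⁸, 10⁻³]). Brent's method then solves for the efficiency; convergence
is judged on the mass residual (relative 10⁻⁸) because mass is the
observable, with root-finder tolerances set near machine precision since
the mass responds to the efficiency with an elasticity of ~10 in the
exponential growth phase. ODE integration is adaptive Runge–Kutta (RK45,
rtol 10⁻⁸, atol 10⁻¹²), restarted at every schedule-segment boundary so no
step crosses a forcing discontinuity; negative non-structural mass warns
but is not clamped.

## Regression and identifiability

Features are the waveband fraction ratios, optionally raised to powers 2–4
and/or multiplied pairwise (22 candidate terms; the studied families have
4, 8, 12, 14 and 16 coefficients). No standardization is applied so fitted
weights are directly comparable to the packaged coefficient set. Metrics:
R², MAPE (guard 10⁻¹²), and Gaussian-likelihood AIC/BIC with the intercept
counted. The conventional definitions (AIC = 2(k+1) − 2LL,
BIC = ln(n)(k+1) − 2LL) are the default; an `as_printed` mode swaps the two
penalty terms for compatibility with published tables that interchange
them. Model selection ranks by test R² with BIC as tiebreaker. Ridge is
closed-form with an unpenalized intercept; lasso delegates to scikit-learn's
coordinate descent (tol 10⁻¹⁰).

Because the four fractions sum to one, the intercept column equals the sum
of the first-order features, and when squares and interactions are both
present F_i = F_i² + Σ_j F_iF_j adds four more exact dependencies. On
exactly-closed compositions the coefficient vector is therefore identified
only up to this closure gauge (`structural_rank` reports the identifiable
count: 16 of 17 for the quartic family). The fitter solves minimum-norm
least squares, which leaves predictions unaffected; a training set must
reach the structural rank, which is also why 16 training rows suffice for
the 16-term family. Fractions obtained by integrating real spectra close
only to rounding level, which restores full rank; the coefficient-recovery
tests mimic this with a closure jitter below the 10⁻⁶ tolerance that the
feature builder enforces on the sum. Replicated treatments with identical
labels produce exactly duplicate feature rows; the minimum-norm solve
handles the resulting rank drop silently, as a practitioner's OLS call
would.

The packaged published model is the RI-normalized 16-coefficient quartic
over irradiance fractions, with the training-domain fraction ranges stored
alongside; predictions outside that domain succeed but warn.

## Packaged fixtures and their assumptions

The LED treatment table (20 rows) and greenhouse validation table (3
periods × 7 harvest ages) ship as checksummed CSVs. One source prints the
irradiance of treatment 11 as "37.3>"; it is stored as 37.3. The white
(WW/EQW) treatments' labels carry no band decomposition, so the three white
rows calibrate but contribute no regression features; summary statistics
that depend on their measured spectra are not reproducible from labels.

Environment recipes render the narrative experiment descriptions into
schedules. Fields the descriptions do not state are flagged `assumed` in
the recipe file:

* **Initial state** — 0.05 g m⁻² total at transplant, 90 % structural
  (configurable); transplant mass is unstated in all sources.
* **Harvest days** for the two 2020 indoor studies are unstated. They are
  anchored so that calibrating a reference treatment reproduces the
  published mean efficiency (1.30×10⁻⁵ g J⁻¹ for the pure-red treatment of
  the first study) — day 15 and day 11 — since the calibrated efficiencies
  are meaningful only jointly with the schedule that produced them. Under
  these anchors the 20 calibrated efficiencies of the indoor treatments
  span 0.7–1.6×10⁻⁵ g J⁻¹, consistent with the published spread.
* **CO₂ for the 2019 study** reuses the 410 ppm of the sibling study.
* **Greenhouse light** is a smooth solar-like spectrum (photon-weighted
  5800 K blackbody over 400–750 nm) scaled to each period's daily light
  integral over a 10 h window; real measured solar spectra are not
  packaged, and atmospheric absorption features are not represented.

The synthetic LED generator places one Gaussian peak per waveband
(defaults: centres 449/526/664/733 nm, FWHM 25 nm — typical narrow-band
horticultural LEDs), truncated at band edges and rescaled so the requested
band photon fluxes round-trip through the integrator to well within 0.1 %.
It emulates the band structure of real fixtures but not their asymmetric
tails or the broad phosphor continuum of white LEDs — so tests passing on
synthetic spectra demonstrate the integration/feature pipeline, not
fidelity to any particular lamp.

## Problem sizes

The test suite and the end-to-end workflow run at the scale of the study
itself: 20 calibrations over 10–15-day schedules (a few seconds in total),
polynomial fits on ≤40 samples, and property checks on 1000 synthetic
spectra. The solver-fidelity check compares one simulated day against a
fixed-step RK4 at dt = 1 s.

## Known limitations

* Spectrum affects the model only through c_ε; morphology (leaf area,
  pigmentation), fresh mass and quality traits are out of scope.
* Calibrated efficiencies inherit every recipe assumption; the tiny values
  for the day-10-harvest study reflect plants that barely exceed the
  assumed transplant mass, not LED physiology.
* The greenhouse cross-validation tracks the low-DLI period to ~10 % at
  final harvest but overshoots the high-DLI period badly — expected, since
  the RI normalization extrapolates linearly in total irradiance far beyond
  the 30–42 W m⁻² training range and no light-saturation or acclimation
  mechanism is modelled.
* Extrapolating the quartic polynomial outside the training fraction domain
  (e.g. a pure-blue spectrum) produces values with no physiological
  warrant; the out-of-domain warning is the guard rail.
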