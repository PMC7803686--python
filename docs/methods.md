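# Methods

## Physical model

The fruit is treated as a homogeneous sphere that keeps its spherical shape
while shrinking. Heat moves inside by conduction and water by Fickian
diffusion with an effective diffusivity; phase change happens only at the
surface; the initial temperature and moisture are uniform; the surface heat
and mass transfer coefficients are constant over the surface and over time.
There is no internal heat source: acoustic energy enters only through the
surface energy balance as a flux `Q_US = P_US / 4πr(t)²`, spread over the
current surface, so the flux grows as the fruit shrinks.

The governing equations and boundary conditions are stated in the README.
Two sign conventions deserve a note, because renderings of surface balances
differ between sources: here the evaporation flux
`j_m = h_m (C_s − C_air) ≥ 0` during drying *cools* the surface through
`−h_fg·j_m`, and the acoustic flux `+Q_US` *heats* it. These signs are what
produce the observed behaviour — sonicated runs approach air temperature
faster, and the early surface–centre temperature difference is largest under
contact sonication.

Material property correlations: specific heat and thermal conductivity are
moisture-dependent (`C_p = (0.837 + 1.256 W)·10³` J/kg/K,
`λ = (0.149 + 0.493 W)/(1 + W)` W/m/K), the latent heat follows a
critical-point power law, and the saturation vapour pressure a standard
polynomial-logarithmic correlation valid on 273–473 K. The surface water
activity is the analytic inverse of the GAB isotherm — a quadratic in
`K·a_w` whose physical branch is continuous with `a_w → 0` — clamped at
0.9999: a fresh fruit's moisture lies far above the hygroscopic range, where
free water at `a_w ≈ 1` is the correct physical reading and the clamp keeps
the isotherm's pole out of the arithmetic.

Shrinkage is quasi-static. The radius follows the volume-average moisture
through the linear law `r/r0 = (1 − s) + s·(W̄/W0)` with a mode-specific
slope `s` (0.6068 plain air drying, 0.4365 airborne, 0.3656 contact —
sonication mitigates structural collapse). Both densities are recomputed
from the current radius: `ρ_s = M0·f_dm / (4/3 πr³)` and
`ρ_b = (1 + W) ρ_s`.

## Numerics

* **Coordinate.** Normalized radius ξ = x/r(t). The grid-velocity advection
  term that an exact moving-boundary transform would add is neglected,
  consistent with the quasi-static treatment of shrinkage: the radius acts
  through the diffusion path length and the densities only.
* **Space.** Conservative finite volumes on a uniform ξ grid, 121 nodes
  including both endpoints (the convention when "pieces" do not say whether
  endpoints count). Interface diffusivities/conductivities are arithmetic
  means. The discrete water inventory then balances the surface evaporation
  flux *identically*, so the mass-balance diagnostic (an extra integrated
  state accumulating the boundary flux) checks the scheme's conservative
  property rather than a quadrature.
* **Time.** LSODA with a banded Jacobian (the state interleaves `[T_i, W_i]`,
  bandwidth 3) at rtol 1e-6, atol 1e-8. The early surface transient is stiff:
  the surface moisture falls from W0 ≈ 6.25 to its local-equilibrium value
  within the first second of hot-air exposure (the "drying front").
* **Splitting.** The radius is frozen inside each output window and updated
  from W̄ between windows — every 0.5 s for the first minute, every 10 s
  after. Updating inside the integrator would couple every W node into every
  equation through r(W̄) and destroy the banded structure; at these output
  cadences the splitting error is far below the grid error (halving the node
  spacing moves the simulated drying time by ~2·10⁻⁵ relative).
* **Robustness.** Error-controlled trial steps may probe unphysical states;
  property evaluations clip temperature to [250, 640] K and moisture to
  W ≥ 0. A converged solution never sits in the clipped region.
* **Post-processing.** `average_moisture` uses the composite trapezoid rule;
  the stored `w_avg` uses the finite-volume cell weights (exactly
  conservative). `time_to_moisture` interpolates linearly between bracketing
  outputs.

## Estimators

* **GAB fit** — trust-region least squares started from a fixed 27-point grid
  (`W_m ∈ {0.05, 0.1, 0.2}`, `C ∈ {1, 10, 50}`, `K ∈ {0.5, 0.7, 0.9}`); the
  lowest final residual wins, ties resolved by grid order, which makes the
  fit deterministic. K is bounded below 1/max(a_w).
* **Slope method** — fits ln MR vs t only over points with t > 0 and
  MR < 0.6, where the one-term truncation of the exact series dominates
  (the threshold is configurable). The equilibrium moisture defaults to the
  mean of the last three samples but should be supplied explicitly when the
  isotherm is known; a retained nonpositive moisture ratio is an error, not
  a silently dropped point. On data from the full 50-term series the
  one-term fit carries an O(1%) truncation bias — hence the 10% tolerance
  used when validating against that oracle.
* **Arrhenius** — ordinary least squares of ln D_e on 1/T; duplicate
  temperatures are rejected as rank-deficient.
* **Lumped capacitance** — one-parameter nonlinear fit of the exponential
  response; for the 25-mm copper sphere (ρ = 8960 kg/m³, C_p = 390 J/kg/K)
  the Biot number is ≪ 0.1 at these h values, so the assumption of a
  negligible internal gradient holds. The fitting window/duration is
  configurable because no standard protocol fixes it.
* **Chilton–Colburn** — `h_m = h·Le^{2/3}/(ρ_air C_p,air)` with
  Le = α_air/D_air = 2.5/2.18. The textbook analogy is often written with
  Le^{2/3} in the denominator; only the form used here maps each measured h
  onto its reported h_m (10.61 → 0.01130, 24.54 → 0.02613, 26.61 → 0.02833
  m/s) with the stated air properties, so that is the form the measured
  pairs define. The discrepancy is a factor Le^{4/3} ≈ 1.2.
* **Calorimetry** — OLS slope of the initial temperature rise over the first
  60 s or first 10 samples, whichever spans more points (the window is a
  declared convention), times the sphere's heat capacity.

## Synthetic data: what it emulates and what it does not

The generators draw from the exact statistical model each estimator assumes:
one-term (or full-model) drying kinetics with multiplicative noise, floored
at equilibrium; exponential sphere cooling and linear calorimetric heating
with additive noise; GAB-shaped sorption points on a seven-point
water-activity grid standing in for the usual saturated-salt series. Default
noise magnitudes — 2% (kinetics), 0.2 K (cooling), 0.05 K (calorimetry), 3%
(sorption) — are plausibility choices; no measured noise levels exist for
these experiments. Passing closed-loop tests therefore demonstrates that the
estimators invert their own generating models correctly and degrade
gracefully under realistic noise; it does not certify them against
instrument drift, sample-to-sample variability, or model misspecification in
real fruit.

## Default study conditions

Hot air at 65 °C and 10% RH (a typical dryer inlet; the RH was not
reported), 2 m/s implicit in the measured transfer coefficients. Fresh fruit:
M0 = 3.5 g, dry-mass fraction 0.138 (so W0 = 6.25 kg/kg DM), r0 = 12.5 mm
(the radius of the copper analogue), T0 = 298.15 K. Per-mode measured
inputs: the Arrhenius diffusivity laws (printed per minute, converted to
m²/s; the contact row's doubled minus sign is read as a single minus),
transfer coefficients (h, h_m), acoustic powers 0 / 0.245 / 0.299 W and the
shrinkage slopes above. The GAB defaults (W_m = 0.10, C = 10, K = 0.85) are
*synthetic* values typical of a dried berry at this temperature — the
source isotherm fit exists only as a figure — so simulated drying times can
only be compared with the measured 150/205/390 min on ordering and scale
(they land within a factor of ~1.7 with these defaults), not point-by-point.

## Problem sizes used in the tests and the acceptance script

Three full-fruit simulations to the 1.0 kg/kg DM endpoint (≈ 5·10³–2·10⁴ s
of simulated drying, 121 nodes), one solver-vs-series benchmark on an
80-point logarithmic output grid, one grid-refinement run at 241 nodes, and
200 seeded replicates per noisy-recovery check. Small-sphere kinetics use 61
samples truncated where the moisture ratio reaches ≈ 0.02 — comfortably
above the equilibrium noise floor, as a balance protocol would stop.

## Known limitations

One-dimensional spherical geometry only; no airflow modelling, internal
pressure-driven flow, case hardening or glass transition; the acoustic field
is a single scalar surface flux; h and h_m measured at 65 °C are reused
unchanged at other temperatures; the quality/energy comparisons are
arithmetic on measured inputs, not predictions. Reported quality narratives
elsewhere occasionally disagree with their own tables (e.g. an anthocyanin
difference of 225.2 µg/g DM where the tabulated means give 1313.3); the
comparison module always computes from the table.
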