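# Methods

## Scope and shape of the model

`pollensim` simulates the emission, atmospheric transport and removal of
airborne allergenic pollen (oak and ragweed) on a regular Cartesian grid
with fixed-height layers and hourly time steps. It is a desk-scale system:
the physics is the pollen-relevant subset of a chemical-transport model —
inert coarse-mode aerosol, no chemistry, no aerosol microphysics — built so
that every operator is individually verifiable against a closed form and
every run closes its mass budget exactly. A Cartesian grid with fixed layer
tops replaces a projected, terrain-following domain deliberately: none of
the pollen dynamics studied here depend on the coordinate choice, and the
simplification removes a pressure solver and map-projection machinery from
the verification surface. Indices are 0-based, intervals half-open, and all
timestamps UTC.

## Emission

The unit-area hourly flux is

    F_e = q_p L_d L_h (K_e·LAI + C_r·K_r·(1+LAI)) / (1 + v_d(1+LAI)/u★),

scaled per cell by `F_g = F_e S_g P_c` and injected into layer 1
(0–60 m). Units are made explicit by convention: `L_d` is the fraction of
the annual release per day and `L_h` the fraction of the daily release per
hour, so `F_e` carries grains m⁻² h⁻¹ when `q_p` is grains m⁻² yr⁻¹.

**Meteorology adjustment factors.** `K_e` and `K_r` are clamped linear
responses around reference conditions,

    K = clamp(1 + α_T(T−T_ref) + α_w(W−w_ref) − α_RH(RH−RH_ref), K_min, K_max),

non-decreasing in temperature and wind speed and non-increasing in relative
humidity — the empirically established directions for pollen release. The
defaults (T_ref 15 °C, w_ref 3 m s⁻¹, RH_ref 60 %, α_T 0.05 °C⁻¹,
α_w 0.05 s m⁻¹, α_RH 0.01 %⁻¹, clamp [0, 2]; the resuspension factor K_r
uses a stronger wind sensitivity, α_w 0.15) are modest sensitivities chosen
so that K varies over roughly [0.5, 1.5] across ordinary spring weather.
The functional form is pluggable: any alternative parameterization with the
same monotone directions can be substituted behind `met_adjust_factor`.

**Friction velocity.** Neutral logarithmic profile
`u★ = κ W10 / ln(10/z0)` with κ = 0.4 and a calm-air floor of 0.01 m s⁻¹ so
the emission denominator stays finite. Default roughness length 0.5 m.

**Deposition velocity.** `v_d` is taken equal to the Stokes terminal
settling velocity `v_s = ρ_p g d_p² / 18μ` — for 20–30 μm grains
gravitational settling dominates the deposition pathway, so no surface
resistance network is carried. Grain density defaults to 1000 kg m⁻³
(configurable); the particle Reynolds number is checked (< 1) and the
formula refuses diameters above 100 μm. The coarse-mode geometric standard
deviation (default 2.2) is carried as metadata only; transport uses the
fixed mean diameter per taxon (monodisperse equivalent), since only mean
diameters are constrained.

**Taxon defaults.** Oak: d_p 28 μm, clinical threshold 13 grains m⁻³,
season window March 1 – April 30, diurnal release peak 11:00. Ragweed:
d_p 18 μm, threshold 30 grains m⁻³, window August 1 – September 30, peak
14:00. Verification levels 10/50/100 grains m⁻³ for both. Annual production
q_p is a per-taxon scalar (oak 1×10⁸, ragweed 4×10⁸ grains m⁻² yr⁻¹ of
covered area), set once so that simulated seasonal-mean and peak-hourly
concentrations over dense vegetation fall in the observed ranges for these
taxa (seasonal means up to a few thousand grains m⁻³, hourly peaks an order
of magnitude higher); an optional per-cell multiplier map allows spatial
variation.

## Phenology

Onset is the first day on which cumulative growing degree days
`GDD_t = Σ max(T_daily − T_base, 0)` crosses a threshold. Daily release is
Gaussian in time, centred `peak_offset` days after onset with standard
deviation `season_spread`, normalized to unit sum over the season window in
the absence of rain, then multiplied by `max(0, 1 − p_s·P_daily)`. The
suppressed mass is *removed*, not redistributed: pollen washed out before
release is lost to the air. The diurnal profile is a wrapped Gaussian over
hour-of-day summing to exactly 1.

Defaults (oak): T_base 5 °C, GDD threshold 100 °C·day, spread 7 days, peak
offset 10 days, diurnal width 3 h, suppression 0.05 per mm of daily rain.
Ragweed uses a warmer base (10 °C), larger threshold (450 °C·day) and a
broader season (spread 10 d, offset 15 d). These are stand-in values for a
fitted phenology model; the interface (`PhenologyParams`,
`daily_release_curve`) accepts any replacement. The one property the model
guarantees — and tests — is mechanism-level: uniformly warmer temperature
series never delay onset, which is what propagates a warming scenario into
earlier simulated seasons.

## Transport

Operator splitting in the fixed order EMIS → HADV → ZADV → HDIF →
VDIF+DDEP → CLDS, one output step per hour, each operator sub-stepping
internally to meet its own stability constraint. Emissions come first so a
single step on a pollen-free domain isolates each subsequent operator for
testing.

* **Horizontal advection**: dimension-split, flux-form, first-order upwind
  with face velocities averaged from cell centres; automatic sub-stepping
  keeps the Courant number ≤ 1 (at exactly 1 the scheme translates a profile
  exactly — used as an oracle). Lateral boundaries exchange mass with a
  prescribed constant boundary concentration (zero by default); inflow and
  outflow are tallied in grains. First-order upwind is chosen over
  higher-order schemes because positivity and exact conservation matter more
  here than phase accuracy; the attendant numerical diffusion is accepted
  and documented.
* **Vertical advection**: upwind on the effective velocity `w − v_s` with a
  rigid lid at the model top; any settling flux through the bottom face is
  routed to the dry-deposition accumulator.
* **Horizontal diffusion**: explicit, conservative second-order flux form,
  zero-flux lateral boundaries, sub-stepped to `K dt (1/dx²+1/dy²) ≤ 0.25`.
* **Vertical diffusion + dry deposition**: backward-Euler tridiagonal solve
  per column (vectorized Thomas algorithm) with the deposition flux
  `v_d·C₁` taken implicitly at the bottom face; the single-layer limit
  reduces to `C/(1 + v_d dt/h)` exactly.
* **Wet scavenging**: `C ← C·exp(−Λ dt)` with `Λ = a·P^b`,
  a = 8.4×10⁻⁵ s⁻¹ (mm h⁻¹)⁻ᵇ, b = 0.79 — one lumped coefficient standing
  for both in-cloud and below-cloud removal, applied column-wide, since no
  cloud water is tracked.

**Where settling acts.** The composed step applies gravitational settling
through the dry-deposition velocity inside the vertical-diffusion operator
(the standard placement for deposition as a bottom-flux boundary condition)
and passes `v_s = 0` to vertical advection, so settling is never counted
twice. The alternative placement (settling inside vertical advection) is
available via `TransportConfig(settling_in="zadv")`; both configurations
conserve mass exactly, and in either one the deposition-attributed share of
the concentration change is booked under the DDEP process, not under the
transporting operator.

**Budgets.** Every operator's per-cell concentration change is recorded;
their sum equals the hourly total change by construction (closure is
asserted at 10⁻⁸ relative, measured at ~10⁻¹⁵). The global budget — emitted
+ boundary inflow = airborne + dry deposition + wet deposition + boundary
outflow — closes to round-off because all accounting reuses the operators'
own flux arithmetic.

**Boundary-condition experiment.** `bc_sensitivity_experiment` runs the
same configuration with boundary values 0 and V and reports the maximum
absolute concentration difference. Because every operator is linear and
monotone (discrete maximum principle), the difference field is bounded by V
everywhere; the 30-day default experiment with V = 10 grains m⁻³ measures a
maximum difference just under 10, attained at inflow-boundary cells.

## Season metrics, evaluation, scenario deltas

* **Season start/length**: start is the first day at which the cumulative
  daily sum reaches 2.5 % of the seasonal total, end at 97.5 %; length is
  end − start + 1. This cumulative-percentage convention is scale-invariant
  and robust to trace concentrations; it is a package convention (several
  operationalizations exist in aerobiology) and both quantiles are
  arguments.
* **Exceedance hours** use strict `>` at the clinical threshold;
  **verification exceedances** use `≥` at the 10/50/100 levels. Fixed and
  documented rather than configurable ambiguity.
* **Hit rate** is the probability of detection TP/(TP+FN); **false rate**
  is the false-alarm ratio FP/(TP+FP), the reading under which a high false
  rate means overprediction. Undefined ratios (no observed or no predicted
  exceedances) are flagged NaN, never zero-filled.
* **Pairing**: model daily means (complete 24-hour days only) are compared
  exclusively on days with non-missing observations; seasonal counts for the
  fractional bias are sums over those paired days.
* **Scenario deltas**: per-cell percentage changes for mean/max/exceedance
  (cells with zero or undefined historic value excluded), day changes for
  start and length (negative start = earlier); per-region unweighted mean
  and sample (ddof = 1) standard deviation; regions with no included cells
  are flagged NaN.

## Synthetic data

The generator emulates the *structure* the model assumes, not any real
geography: temperature = seasonal ramp + diurnal sinusoid + smooth spatial
gradient + hourly AR(1) noise; winds AR(1) around a mean vector;
precipitation as random hourly events with exponential intensity and a
smooth spatial footprint; RH anticorrelated with the temperature anomaly;
vegetation as Gaussian patches with a guaranteed ≥ 20 % exactly-zero
coverage so transport into unvegetated areas is always exercised; regions
as a near-equal rectangular tiling; observations as daily means of the
simulated truth with median-1 lognormal noise and an intermittent weekly
sampling schedule (default 3 days per week). The perturbed scenario reuses
the baseline's random draws and adds a uniform +2 °C, a precipitation scale
of 1.1 and an optional wind scale, so scenario differences are purely the
prescribed climate signal.

What passing tests on synthetic data do **not** show: skill against real
pollen counts. Real drivers have correlated synoptic variability, real
vegetation has species-specific spatial structure, and real observations
have sampler-dependent biases — none of which the generator reproduces. The
synthetic experiments establish that the machinery is correct (budgets
close, oracles recovered, monotonicities propagate end-to-end), not that
the default parameters are calibrated to any particular region or year.

## Problem sizes and numerical tolerances

The default demonstration configuration is a 20×15×4-cell grid (36 km
spacing; layer tops 60/150/400/1000 m) over 720 hourly steps — large enough
that every process acts and small enough that the full test suite runs in
seconds. Budget closures are asserted at 10⁻⁸ relative (measured at
round-off); the settling column test compares against its exponential limit
at 10⁻³ after fine sub-stepping; the evaluation self-consistency oracle is
asserted at 10⁻⁹. Splitting error is monitored (half-step comparison within
10 % for an hourly step), not asserted exactly, as expected for first-order
operator splitting.

## Known limitations

* First-order upwind advection is numerically diffusive; sharp plumes
  spread faster than physically warranted.
* One lumped scavenging coefficient; no cloud-water or precipitation-type
  dependence beyond the P^b rate.
* Monodisperse settling at the taxon mean diameter; the stated size
  distribution is not propagated into a settling spectrum.
* The phenology is a minimal GDD + Gaussian stand-in; it preserves the
  temperature/precipitation dependencies but is not a fitted species model.
* No species-distribution change, CO₂ fertilization or land-use change:
  identical vegetation is used for both scenarios by design, isolating the
  meteorological pathway (K_e, K_r, L_d, u★, v_d) of climate response.
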