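# Methods

## Scope and intent

`igplake` is a deliberately reduced, desk-scale analogue of a coupled
1-D hydrodynamic–ecological–fish model of a warm monomictic lake.  It
keeps exactly the machinery the intraguild-predation (IGP) analysis
needs — a stratified column, an IGP triangle with self-limitation, an
individual-based fish population with bioenergetics, a predation-flux
ledger, and a scenario engine — and replaces everything else (full
hydrodynamics, multi-element biogeochemistry, five phytoplankton groups,
bacteria, oxygen) with minimal closures.  Its outputs are therefore
*patterns* (dominance ratios, monotone shifts, compensation, sensitivity
signs), not calibrated magnitudes.

## Physical stage

* **Grid.** Fixed Eulerian layers (default ten 4 m layers over 40 m)
  with a frustum hypsography: plan area shrinks linearly with depth and
  is scaled so the column integrates to the configured lake volume
  (default 4×10⁹ m³ under 1.66×10⁸ m² — Kinneret-like; the real
  hypsography is not built in).
* **Temperature.** A two-value profile: layers above the seasonal
  mixed-layer depth take the (sinusoid + AR(1) noise, clipped) surface
  temperature; deeper layers take a constant hypolimnion temperature
  (default 15 °C).  Stratification runs mid-March to mid-December with
  a 15 m summer mixed layer; outside it the column is holomictic.
* **Mixing.** Conservative pairwise volume exchange between adjacent
  layers: fast (5 day⁻¹) inside the mixed layer, slow (0.02 day⁻¹)
  across the thermocline.  The per-step exchanged volume is capped at
  half the smaller layer volume so the explicit update can never
  overdraw a layer at any admissible step size.
* **Light.** Surface PAR decays exponentially (extinction 0.3 m⁻¹ by
  default) to the layer midpoint; no self-shading.
* **Forcing determinism.** All noise is AR(1) with a stationary start,
  drawn from `numpy.random.default_rng(seed)`; identical (config, seed)
  gives byte-identical series.  Wet-winter flood events are additive,
  local to one hydrological year (ramp up from 1 December, drawdown
  complete by 30 November).

## Plankton stage

Pools per layer: nanoplankton A, detritus D, phosphate N, and
zooplankton Z1 (predatory), Z2 (herbivorous), Z3 (micro), in
mgC L⁻¹; N in mgP L⁻¹ with a fixed Redfield-mass P:C of 0.0244 in all
organic material, which makes phosphorus conservation automatic.

Process closure (all temperature factors are Q10-style,
θ^((T−T_ref)/10), θ = 2, T_ref = 20 °C):

* A grows by a Liebig minimum of Monod nutrient and light terms
  (μ_max 1.5 day⁻¹, K_N 0.005 mgP L⁻¹, I_k 40 W m⁻²), respires
  (0.05 day⁻¹) and dies to detritus (0.02 day⁻¹).
* Z2 grazes only on A; Z3 on A and D with fixed diet weights (0.8/0.2);
  Z1 grazes on Z3, Z2 and itself with the literature preferences
  0.5/0.35/0.15 and g_max 3.03 gC m⁻³(gZ m⁻³)⁻¹day⁻¹.  All grazing is
  one preference-weighted Michaelis–Menten response; each prey gets its
  weighted share, so the partition sums exactly to the total.
* Assimilated fractions (0.7) build grazer biomass; egestion goes to D;
  basal respiration (0.014 day⁻¹, temperature-scaled) releases P
  back to N; non-predation mortality (0.008 day⁻¹) goes to D; detritus
  remineralises at 0.05 day⁻¹, with a configurable buried fraction
  (default 0.5) leaving the system — the nutrient sink that balances
  the external load at steady state.

**Numerics.** Hourly fixed-step classic Runge–Kutta on the reaction
terms, then a proportional flux limiter on the combined step amounts
(if a pool's gross outgoing amount exceeds the pool, all its outgoing
channels scale down together, with a 1−10⁻¹² headroom against rounding),
then the mixing exchange.  Positivity is enforced only through the
limiter — never by clamping — and every pool change equals the signed
sum of the recorded flux channels to better than 10⁻¹² relative.  A
fine-tolerance adaptive integration (`scipy.solve_ivp`, rtol 10⁻¹¹) of
the same right-hand side is the correctness reference; on the standard
1-layer 30-day instance the fixed-step trajectory agrees to ≲5×10⁻⁵
relative.  Fixed-step second-order-free forward-Euler was rejected: at
realistic rates its 30-day global error (~r²·T·dt/2 ≈ 1 %) cannot meet
the 10⁻³ fidelity bound at a 1 h step.

## Fish stage

A population of super-individuals (arrays of count, wet weight W,
ratcheted length from W = αL³ with α = 0.0085, layer).  Daily order of
operations: redistribute → consume → grow → starve → die/harvest, after
the 24 plankton substeps (operator splitting: fish see the end-of-day
plankton state).

* **Habitat choice.** Each super-individual samples a layer with
  probability ∝ (vulnerability-weighted prey density) × Gaussian
  temperature suitability (optimum 24 °C, σ 8 °C); layers further than
  15 °C from the optimum are uninhabitable.  Draws come from the
  population's own seeded generator.
* **Consumption.** Effective prey E_w = 0.4·Z1 + 0.5·Z2 + 0.02·Z3
  (literature vulnerabilities), half-saturation 0.10 mgC L⁻¹, maximum
  ration 0.007·W^0.725·θ(T) gC day⁻¹.  Layer demand above the standing
  prey is scaled back proportionally across the super-individuals in
  the layer (logged as limiter events).
* **Bioenergetics.** Specific growth g = c − (r+e+u+s+g_r) with
  egestion 0.15, excretion 0.08, SDA 0.12 and activity respiration 0.20
  of consumption, basal respiration 0.012 g_ww g⁻¹ day⁻¹
  (temperature-scaled), and an annual spawning pulse (8 % of adult
  weight on day 120).  The per-fish carbon channels sum exactly to
  intake.  Egestion + spawned material feed detritus in the fish's
  layer; excretion + respiration release nutrient and respired carbon;
  fish that fall below 20 % of their length-expected weight die to
  detritus.
* **Mortality and harvest.** Counts thin deterministically at
  exp(−(m_nat + f)·dt), m_nat = 0.0023 day⁻¹, with the fishing rate
  f = −ln(1 − annual/100)/365 selected by the 12 cm commercial-length
  threshold (28 % yr⁻¹ commercial, 0 non-commercial at base).  Natural
  deaths return to detritus; harvest leaves the system into a ledger.
  Deterministic thinning removes demographic noise at desk scale; a
  Bernoulli mode was not needed.
* **Recruitment.** Once a year (30 April) recruits = 0.8 per adult
  (≥ 7 cm) × a water-level multiplier: 1 up to a 1 m December–April
  rise, then +5 per additional metre — a 4.5 m flood winter yields an
  ~18× pulse and an 8–10-fold population within the lag year, matching
  the "atypical year" phenomenology.  Recruits enter as 0.5 g
  super-individuals.  Making baseline recruitment proportional to the
  spawning stock (rather than constant) keeps the multiplied-fish
  scenarios persistently elevated, which is what the abundance
  experiments require.

## Coupling and bookkeeping

Hourly plankton, daily fish, fixed order; runs are bit-reproducible per
(config, seed), with the forcing and the fish population on independent
streams derived from one seed.  The six IGP fluxes are accumulated daily
per layer and reported as volume-weighted rates (μgC L⁻¹ day⁻¹) and
lake-wide wet-weight totals (ton day⁻¹, carbon:wet-weight 0.05 gC/g_ww —
a single uncalibrated conversion used on both sides of every ratio, so
ratios and percents are insensitive to it).  Carbon closes exactly:
organic pools + fish + cumulative respired + buried + harvested −
cumulative fixed − recruited is constant (≈10⁻¹⁵ relative per simulated
year in the closed configuration).  Respired carbon is a cumulative
sink; there is no DIC pool.

## Scenario engine

* **Multipliers** ×1/×2/×8 scale only the count each super-individual
  represents (100,000 → 800,000); initial weights, seed and forcing are
  shared, so differences are attributable to fish abundance.
* **Sensitivity** perturbs g_max, P_zk1, V_11, V_12 by ±50 % one at a
  time; perturbing the self-predation preference re-balances the
  micro-zooplankton preference so the diet weights still sum to 1 (the
  herbivore preference is never touched).  The response metric is the
  volume-weighted mean herbivore concentration over the run excluding a
  one-year spin-up — the spin-up guard is needed because the synthetic
  run starts from idealised uniform initial conditions.
* **Biomanipulation** reruns the ×8 scenario with exploitation raised
  to 50/50 % yr⁻¹ from 28/0.

## Calibration of the synthetic base state

The literature supplies g_max, the diet preferences, the
vulnerabilities, the exploitation rates and the commercial length; every
other rate constant is uncalibrated.  Those defaults were chosen so the
seven-year base run sits in the reported qualitative regime: annual
Z1→Z2 predation a few-fold larger than fish predation at ×1 (here ≈16×),
the ratio falling below 1 at ×8, fish predation monotone in abundance,
near-constant total predation on herbivores across scenarios, the full
±50 % sensitivity sign pattern, and fish shifting to sub-commercial
sizes under ×8 crowding.  Two structural conditions proved necessary and
are worth recording: (i) zooplankton turnover must be slow (half-
saturation well above ambient weighted prey, so the functional response
is nearly linear, and small respiration/mortality rates), otherwise the
predatory-zooplankton standing stock and its fluxes run an order of
magnitude hot; and (ii) the micro-zooplankton must remain trophically
marginal — if Z3 can bloom on detritus it becomes a predation refuge
that decouples Z1 from Z2 and destroys the triangle.  Absolute flux
magnitudes (thousand ton yr⁻¹) are *not* matched to the calibrated
Kinneret run and should not be read as such.

## What the synthetic data do and do not show

The generator emulates seasonality, stratification, stochastic weather,
flood winters and nutrient loading — enough to exercise every model
mechanism and the qualitative IGP regime.  It does not reproduce
observed Kinneret time series, the real hypsography and heat budget,
multi-nutrient limitation, or the phenological detail of the plankton
succession (e.g. the observed December predation peak; the synthetic
climatology peaks in late spring instead).  Passing tests therefore
demonstrate internal correctness (conservation, closure, determinism,
integrator fidelity) and the robustness of the IGP patterns to this
family of forcings — not predictive skill for any real lake.

## Degenerate inputs and edge behaviour

Zero prey gives zero flux (no 0/0); a 0/0 dominance ratio is missing, a
finite/0 ratio is +∞; an empty month in a climatology is missing; zero
fish decouple the stages exactly; a wholly uninhabitable column leaves
fish in place with a warning; preferences that leave [0,1] after a
sensitivity perturbation are a configuration error, as are exploitation
rates outside [0,100] and unknown configuration keys.

## Known limitations

One fish cohort structure (no explicit age classes), no littoral
habitat, a single nutrient, one phytoplankton group, no oxygen or DIC,
no sediment diagenesis beyond a buried fraction, and monthly-scale
phenology that is only qualitatively lake-like.  Problem sizes (10
layers, 1000–1400 super-individuals, ~2,500 simulated days per run)
were chosen so a full scenario suite runs in minutes on one CPU.
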