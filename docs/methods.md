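# Model description and methods

`soyflood` simulates a soybean crop on a layered soil profile at a daily
time step. This note documents the model equations and assumptions, the
parameters that matter and their defaults, what the synthetic study
environments emulate, the numerical conventions, and the design choices
made where the design was genuinely open.

## Daily loop

For each day from sowing: read weather → apply flood forcing if a
treatment window is active → water balance → water-table/predictor
diagnostics → phenology → root growth → drought stress → waterlogging
photosynthesis stress with recovery accounting → N uptake and fixation →
growth → grain fill → trace append. The season ends at physiological
maturity or when the weather series is exhausted (flagged truncated).
Transpiration is computed from the morning soil state and withdrawn inside
the water-balance step; stresses are evaluated from the post-balance state.

## Soil water

Each layer holds `ll15 < dul < sat` (volumetric): the lower limit of plant
extraction, the drained upper limit (field capacity) and saturation. The
balance is a tipping bucket: rain plus any surface pond infiltrates
top-down, each layer fills to `dul` and passes water above `dul` downward
at most at its saturated conductivity `ks` (mm/d); water that cannot drain
backs up, saturating layers from the restrictive horizon upward — that is
how a claypan perches a water table. Excess arriving at the surface ponds
up to the profile's `pond_capacity` (flat, graded fields hold standing
water); only the overflow runs off. Evaporation comes off the pond first,
then layer 1 down to `ll15`. The **water table** is the top of the deepest
contiguous saturated block (perched tables over unsaturated subsoil count;
standing surface water means depth 0); "saturated" uses a volumetric
tolerance of 1e-4. Depths are mm below the surface, layers indexed
top-down, intervals half-open [top, bottom).

The daily balance closes exactly: rain + forced flood water + irrigation =
Δ(storage incl. pond) + runoff + drainage + evaporation + transpiration
(machine precision; the test suite asserts < 1e-3 mm per season).

Water supply to the crop sums `kl · thickness · (sw − ll15)` over root-zone
layers, **excluding saturated layers** — roots in anoxic layers take up
neither water nor N. `kl` defaults decay from 0.10 at the surface to 0.02
at depth. When the water table stands at the surface the crop is not
water-limited (transpiration is met from free water and logged as flood
irrigation in the ledger): under flooding the binding constraint is oxygen,
not water.

Forced flooding (treatment windows) saturates the whole profile and tops it
back up after the daily drainage step — emulating "excess rainfall
maintained until the water table reaches the surface". When a window ends
the flood water is released: pond and profile return to field capacity,
logged as runoff. This mirrors the surface drainage of the levee-flooded
trial fields; without it the slow claypan recession would dominate the
treatment response and a 2-day flood would approach a 14-day flood in
effect.

## Mineral nitrogen

A single mineral-N pool per layer. A constant mineralisation input (kg N
ha⁻¹ d⁻¹, default 1.0–1.2 by fixture) feeds the top layer and is left
insensitive to excess moisture (mineralisation is the least
moisture-sensitive soil N process). Saturated layers lose nitrate at a
first-order rate (default 0.015 d⁻¹) to denitrification and leaching.
Plants access 10% per day of the mineral N in non-saturated root-zone
layers.

## The excess-water stress functions

All stress functions are piecewise-linear 0–1 multipliers over x/y pairs,
linearly interpolated and clamped at the ends. The three oxygen-deficit
functions share the anchors x = 0 at field capacity (no stress) and x = 1
at saturation (full stress):

| function | predictor | default pairs | notes |
|---|---|---|---|
| photosynthesis | fraction of roots below the water table | (0,1) (0.8,1) (1,0.75) | response minor until ~80% submergence; the 25% full-submergence reduction sits inside the 16–33% range reported for 48-h floods at V4 |
| development | same | (0,1) (0.8,1) (1,0.65) | calibrated so a 14-day V4 flood delays maturity by 3–8 days |
| N fixation | water-filled pore-space excess, (sw−dul)/(sat−dul), thickness-weighted over the top 0.45 m | (0,1) (0.5,1) (1,0) | minor until x = 0.5; fixation **stops** on saturated soil — the x=1 anchor is pinned at 0 and never perturbed |

The nodule-zone depth (0.45 m) is user-configurable. Drought stress is the
classic supply/demand ratio capped at 1; the daily growth multiplier is the
minimum of drought, waterlogging-photosynthesis and N stress (stresses do
not multiply — the binding one governs).

**Stage severity.** A factor S multiplies the stress depth (1−y), ramping
linearly from 1.0 before the sensitive stage (default R1, user-definable)
to 1.2 at pod-fill onset (R3) and holding to maturity. At full submergence
this takes the photosynthesis reduction from 25% (vegetative) to 30%
(reproductive), inside the 22–32% range reported for R2-stage floods.

**Post-flood recovery.** Waterlogging stress incurred at or after the
sensitive stage accumulates as *exposure*, measured in full-stress-
equivalent days (each day contributes its stress depth relative to the
function's maximum depth at saturation). The multiplier is then capped at
`1 − p·min(1, exposure/D)` for the rest of the season, with persistence
p = 0.65 and saturation scale D = 17 days. Stress before the sensitive
stage accrues nothing — the plant recovers fully from vegetative floods —
while repeated or long reproductive floods leave cumulative damage (lost
leaf tissue, dead nodules) that can exceed the acute stress level. An
instantaneous-minimum carry was rejected during development: because the
fixation multiplier hits 0 in any full flood, it made 2-day and 14-day
reproductive floods equally damaging, contrary to the duration-study
pattern the model exists to reproduce.

**Sensitivity perturbations.** The sensitivity driver shifts one function's
interior/terminal y values by ±1 and ±2 SD (shipped default 0.05 per
parameter, user-overridable), clamped to [0,1], with the fixation y(1)=0
anchor held fixed, and reports percent changes of yield, biomass, N fixed,
N uptake and maximum root depth averaged over flood treatments and years.

## Crop physiology

- **Phenology**: thermal time from the daily mean temperature, linear above
  a base (8 °C) and capped at an optimum (30 °C). Stage code runs 0 sowing,
  1 emergence, 3 R1, 4 R3, 5 R5, 6 maturity, with phase durations per
  maturity-group preset (MG 3–5.5). Waterlogging scales the daily thermal
  increment (stall). An optional pre-flowering catch-up parameter
  (photoperiod anchoring of R1) exists but defaults to off.
- **Growth**: Beer's-law interception (k = 0.55) × RUE (0.9 g MJ⁻¹) ×
  min(stress multipliers), converted at 1 g m⁻² = 10 kg ha⁻¹.
- **Canopy**: a seedling exponential expansion phase (relative rate
  0.012 per °Cd, active below LAI 1.5, slowed by the same stresses) hands
  over to biomass-driven leaf growth (leaf fraction 0.45 tapering to zero
  at R5, SLA 0.022 m² g⁻¹, cap 5.5). After flowering, N shortage sheds
  leaf area at up to 8%/day (N-starved soybeans remobilise leaf N and drop
  leaves; vegetative plants replace leaves as nodes form, so shedding is
  gated to R1+). Post-R5 senescence runs on a calendar clock
  (0.055 d⁻¹).
- **Transpiration demand**: potential growth × VPD / transpiration
  efficiency, with the standard 0.75-weighted daytime VPD from Tmax/Tmin
  and a coefficient of 0.005 kPa (≈ 3.3 mm for 11 g m⁻² at 1.5 kPa).
- **Roots**: elongate 25 mm/d to a cultivar maximum (≤ profile depth), and
  stop whenever air-filled porosity at the root front drops below 3% —
  hypoxic arrest of root growth.
- **Nitrogen**: the plant takes soil N first; symbiotic fixation covers the
  residual demand up to a capacity of 2.8 kg N ha⁻¹ d⁻¹ scaled by a stage
  curve (0 at emergence → 1 at R3, plateau through R5 — the pod-fill
  fixation peak — declining to 0.2 at maturity as nodules senesce) and by
  the fixation stress multiplier. Demand follows a critical whole-plant N
  concentration declining from 4.5% at emergence to 2.5% at maturity, with
  a luxury-uptake factor of 1.30 building the reserve that buffers short
  floods. Growth stress uses the pool-based N concentration (between the
  minimum, 0.55 × critical, and the critical), not the raw daily
  supply/demand ratio: an instantaneous ratio would zero growth on the
  first flooded day, contradicting the observed ~25% photosynthesis
  reductions after 48 h.
- **Grain**: between R3 and maturity, 55% of the daily biomass increment
  fills grain, plus retranslocation of up to 0.2%/day of vegetative biomass
  after R5 from a finite mobilizable pool (4% of vegetative biomass at R5).
  Grain carries 6% N drawn from the plant pool; vegetative tissue can be
  stripped to 0.8% N. Yield is the grain pool at maturity.

N conservation holds identically: plant N = seed N + cumulative uptake +
cumulative fixation; grain never exceeds biomass; soil mineral N never goes
negative.

## Synthetic study environments

Three seeded fixtures emulate the kinds of sites where soybean flooding
trials have been run. Their hydraulic values are representative textbook
values for the named textures, not survey profiles, and their weather is
generated, not observed:

- **clay** — a mid-South-US heavy clay (high field capacity, air capacity
  sat−dul ≤ 0.07, slow subsoil ks 15→1 mm/d, 2 mm surface ponding), MG 4,
  sown DOY 130. Water tables perch readily; large rain events pond.
- **silt_loam** — a mid-South silt loam over a dense claypan (fast surface
  horizons, ks 60/45, pan at 0.6 m with ks ≤ 8), MG 4.
- **iowa** — a cooler, wetter Iowa-like silty clay, MG 3, sown DOY 135,
  with a periodic waterlogging schedule (three 4-day calendar episodes).
  Its N supply (60 kg ha⁻¹ initial + 1.2 kg ha⁻¹ d⁻¹ mineralisation)
  yields an unstressed fixation share of aboveground N near 47%, the
  middle of the 35–70% range reported for the region.

The weather generator uses sinusoidal annual cycles for temperature and
radiation with Gaussian day-to-day noise, and a two-state Markov rainfall
occurrence model (wet-spell persistence 0.35) with exponential wet-day
depths matched to monthly totals; long-run monthly means converge within
10% of their targets. Radiation drops 35% on wet days.

Fixture control seasons are run with automatic irrigation (refill of the
root zone to field capacity whenever supply falls short of demand): the
flooding trials these environments emulate were water-replete apart from
the imposed floods, and irrigation keeps the rainfall-addition scenarios
from *helping* yield through drought relief, so scenario penalties isolate
the waterlogging pathway.

Calibration: with no access to the original trials' observation records,
the behavior-bearing defaults (pheno terminal y, persistence and its
saturation scale, denitrification rate, leaf-shed rate, pond capacities)
were calibrated against the published behavior patterns — the ~2% vs >50%
yield response to extending V4 vs R2 floods from 2 to 14 days, the 3–8 day
maturity delay, the ~6/12/27/36% penalties for 1–4 extreme events per
month, and the ~2% penalty for +25% summer rainfall — and then frozen.

## Scenario analysis

The risk driver pairs each scenario year with its same-year control
(identical weather before perturbation, soil and cultivar) and reports the
distribution of percent yield penalties. The built-in scenario set is:
+25% rain in June, July or August separately; +25% in all three; and 50 mm
daily rain events added one to four times per month in June–August, placed
deterministically at round(L·k/(f+1)) within each month of length L (even
spacing, no randomness; events add to existing rain so scenario totals are
monotone in frequency). Multi-year runs reset soil water and mineral N to
their configured initial state each January 1. Problem sizes used by the
reproduction script: 5 seeded years for the duration study and fixation
share, 30 seeded years × 3 fixtures for the scenario analysis.

## Numerical conventions and degenerate inputs

Saturation comparisons use ε = 1e-4 volumetric; the monotonicity of
perturbed y-vectors is enforced by clamping with a warning; zero
transpiration demand gives drought multiplier 1; a zero-duration flood
treatment is the identity; `enable_oxdef: false` restores the
drought-only model bit-for-bit on non-waterlogged seasons (the oxdef
functions evaluate to 1 at field capacity, so the improved model reduces
exactly to the original one on dry profiles). Every run is a pure function
of (config, seed).

## Known limitations

- The tipping bucket has no matric-potential redistribution; recession
  after natural saturation is governed by `ks` and evapotranspiration only.
- Surface pond capacities are small calibrated constants, not
  microtopography.
- No within-plant N remobilisation dynamics beyond the grain-fill draw; no
  leaf-level photosynthesis mechanism; no senescence function driven
  directly by excess water (leaf loss emerges through the N economy); no
  hail, wind or disease covariates that often accompany floods.
- The synthetic weather has no interannual regimes (ENSO-like persistence)
  and the fixtures are emulations; passing tests demonstrate the stress
  machinery's behavior under controlled conditions, not site-level
  predictive skill on real fields.
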