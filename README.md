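# soyflood

A desk-scale, process-based soybean (*Glycine max*) cropping-system
simulator focused on **excess-water ("oxygen deficit") stress**. Most crop
models handle drought well and waterlogging poorly; `soyflood` implements a
daily soil–crop loop in which flooding suppresses three processes through
stage-dependent 0–1 multipliers:

- **photosynthesis** (radiation-use efficiency), driven by the fraction of
  the root system below the water table;
- **phenological development** (thermal-time accumulation), same predictor;
- **symbiotic N fixation**, driven by the water-filled pore-space excess of
  the top 0.45 m of soil (the nodule zone).

Each function is a piecewise-linear set of x/y pairs anchored at x = 0
(field capacity, no stress) and x = 1 (saturation, full stress), deepened
during reproductive stages, and combined with a persistent post-flood
damage term: plants recover fully from vegetative floods but not from
floods at or after flowering. Around these functions sit a layered
tipping-bucket water balance with perched water tables and surface ponding,
a minimal soybean physiology (Beer's-law interception, RUE growth,
transpiration demand via a VPD-normalised transpiration-efficiency
coefficient, aeration-limited root growth, grain fill, and a plant N
economy with soil-uptake-before-fixation priority), a seeded synthetic
weather generator, a flooding-treatment scheduler, and drivers for
multi-year, sensitivity and climate-scenario analyses.

It is intended for agronomists and modellers who want to study flood
timing/duration responses and rainfall-scenario yield risk without a full
cropping-system platform.

## The stress model in brief

For a daily multiplier `y = f(x)` with pairs `(x_i, y_i)`:

```
drought      = min(1, supply / demand)
oxdef_photo  = sev(f_photo(frac_submerged))      # default (0,1) (0.8,1) (1,0.75)
oxdef_pheno  = sev(f_pheno(frac_submerged))      # default (0,1) (0.8,1) (1,0.65)
oxdef_fix    = sev(f_fix(wfps_excess_top45cm))   # default (0,1) (0.5,1) (1,0)
sev(y)       = 1 - (1 - y) * S(stage)            # S ramps 1 -> 1.2 from R1 to R3
```

Daily growth uses `min(drought, oxdef_photo, N stress)`; thermal time is
scaled by `oxdef_pheno` (floods stall development); fixation capacity is
scaled by `oxdef_fix` and is exactly zero on saturated soil. Stress
incurred at or after R1 accumulates as exposure and caps the multipliers at
`1 − 0.65·min(1, exposure/17 d)` for the rest of the season.

## Worked example

```python
from soyflood import clay_fixture, run_flood_experiment

cfg = clay_fixture().make_config(n_years=1, seed=1)
table = run_flood_experiment(cfg, stages=["V4", "R2"], durations=[2, 14])
print(table[["stage", "duration_days", "yield_kg_ha", "penalty_pct"]])
```

prints (one seeded weather year on the heavy-clay fixture):

```
  stage  duration_days  yield_kg_ha  penalty_pct
control              0      4257.29         0.00
     V4              2      4246.03         0.26
     V4             14      4154.78         2.41
     R2              2      4109.04         3.48
     R2             14      2056.83        51.69
```

Extending a flood from 2 to 14 days at the 4th-leaf stage (V4) costs about
2% of yield — the stalled development largely shifts the season — whereas
the same extension at early flowering (R2) destroys more than half the
yield: fixation collapses during peak N demand, the canopy sheds leaves,
and the damage persists through grain fill. The same asymmetry is why
late-season extreme rain events are far more damaging than a uniform
increase in rainfall.

The command-line interface exposes the same machinery
(`soyflood simulate | flood-experiment | risk | sensitivity | evaluate |
fixtures generate`); `soyflood fixtures generate clay --out d/` writes the
soil, cultivar, weather and run-config files for a fixture.

## Layout

- `soyflood.weather` — weather I/O (CSV and a met-like dialect), seeded
  generator, rainfall scenarios
- `soyflood.soil` — layered tipping-bucket water balance, water table,
  ponding, flood forcing, mineral N pool
- `soyflood.stress` — the x/y multiplier framework and stress functions
- `soyflood.crop` — phenology, growth, roots, N economy, grain fill
- `soyflood.engine` — daily loop and experiment drivers
- `soyflood.evaluation` — RRMSE, modelling efficiency, r², penalties
- `soyflood.fixtures` — the three synthetic study environments
- `soyflood.cli`, `soyflood.config` — command line and YAML configs

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
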