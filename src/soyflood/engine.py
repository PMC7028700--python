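"""Daily simulation loop and experiment drivers.

The daily order is fixed: weather -> flood forcing (if a treatment window is
active) -> water balance -> water-table and predictor diagnostics ->
phenology -> root growth -> supply/demand drought stress -> waterlogging
photosynthesis stress with post-flood recovery -> N uptake and fixation ->
growth -> grain fill -> trace append.  A season terminates at maturity or
when the weather series is exhausted (the result is then flagged truncated).

On days when the water table stands at the surface (forced floods or natural
ponding) transpiration is met from free surface water: the crop is not
water-limited while submerged — the binding stress is oxygen deficit, not
drought.  The withdrawn water is logged as flood irrigation so the balance
ledger still closes.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import crop as cr
from . import soil as so
from . import stress as st
from .weather import ClimateScenario, WeatherSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FloodTreatment",
    "SimConfig",
    "SeasonResult",
    "run_season",
    "run_flood_experiment",
    "run_multi_year",
    "run_sensitivity",
    "run_risk_analysis",
]


@dataclass(frozen=True)
class FloodTreatment:
    """A flooding treatment: forced full-profile saturation for
    ``duration_days`` once the crop reaches ``trigger`` (a stage label such
    as "V4"/"R2", a numeric stage code, or a calendar date)."""

    trigger: str | float | dt.date
    duration_days: int

    def __post_init__(self) -> None:
        if self.duration_days < 0:
            raise ValueError("duration_days must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Everything one season run needs.  ``initial_mineral_n`` is the
    total profile mineral N (kg ha^-1), distributed over layers by
    thickness; soil water initialises at field capacity unless
    ``initial_sw`` is given per layer."""

    weather: WeatherSeries
    profile: so.SoilProfile
    cultivar: cr.CultivarParams
    sowing_doy: int = 130
    enable_oxdef: bool = True
    oxdef: st.OxdefParams = field(default_factory=st.OxdefParams)
    treatments: tuple[FloodTreatment, ...] = ()
    scenario: ClimateScenario | None = None
    initial_sw: tuple[float, ...] | None = None
    auto_irrigate: bool = False  # refill root zone to DUL when drought would bind
    initial_mineral_n: float = 50.0
    mineralization_rate: float = 1.0  # kg N ha^-1 d^-1 into the top layer
    denit_rate: float = 0.015  # d^-1 first-order loss from saturated layers
    n_access_frac: float = 0.10  # daily accessible fraction of root-zone mineral N
    seed: int = 0


@dataclass
class SeasonResult:
    """Summary and daily trace of one season."""

    yield_kg_ha: float
    biomass_kg_ha: float
    cum_fixed_n: float
    cum_uptake_n: float
    maturity_date: dt.date | None
    max_root_depth: float
    trace: pd.DataFrame
    truncated: bool
    year: int
    seed: int

    @property
    def fixation_share(self) -> float:
        tot = self.cum_fixed_n + self.cum_uptake_n
        return self.cum_fixed_n / tot if tot > 0 else float("nan")


def _initial_soil_state(config: SimConfig) -> so.SoilWaterState:
    prof = config.profile
    if config.initial_sw is not None:
        sw = np.asarray(config.initial_sw, dtype=float)
        if len(sw) != prof.n_layers:
            raise ValueError("initial_sw length must match layer count")
    else:
        sw = prof.arr("dul").copy()
    th = prof.thickness
    mineral = config.initial_mineral_n * th / th.sum()
    return so.SoilWaterState(sw=sw.copy(), mineral_n=mineral.copy())


def _resolve_trigger(trigger, cultivar: cr.CultivarParams):
    """Normalise a treatment trigger to ('stage', code) or ('date', date)."""
    if isinstance(trigger, dt.date) and not isinstance(trigger, dt.datetime):
        return ("date", trigger)
    if isinstance(trigger, str):
        return ("stage", cultivar.stage_code_of(trigger))
    return ("stage", float(trigger))


class _TreatmentTracker:
    """Tracks which treatment windows are active on a given day."""

    def __init__(self, treatments, cultivar):
        self.windows = []  # (kind, trigger_value, duration)
        for t in treatments:
            kind, val = _resolve_trigger(t.trigger, cultivar)
            self.windows.append({"kind": kind, "value": val, "duration": t.duration_days,
                                 "started": None, "done": False})

    def active(self, date: dt.date, stage_code: float) -> bool:
        hit = False
        for w in self.windows:
            if w["done"] or w["duration"] == 0:
                continue
            if w["started"] is None:
                if w["kind"] == "stage" and stage_code >= w["value"]:
                    w["started"] = date
                    logger.info("flood treatment start %s (stage %.2f)", date, stage_code)
                elif w["kind"] == "date" and date >= w["value"]:
                    w["started"] = date
                    logger.info("flood treatment start %s (calendar)", date)
            if w["started"] is not None:
                days_in = (date - w["started"]).days
                if days_in < w["duration"]:
                    hit = True
                else:
                    if not w["done"]:
                        logger.info("flood treatment end %s", date)
                    w["done"] = True
        return hit

    def any_unstarted_stage_triggers(self) -> list[float]:
        return [w["value"] for w in self.windows
                if w["kind"] == "stage" and w["started"] is None and w["duration"] > 0]


def run_season(config: SimConfig, year: int | None = None) -> SeasonResult:
    """Run one season from sowing to maturity (or weather end)."""
    weather = config.weather
    if config.scenario is not None:
        weather = config.scenario.apply(weather)
    wdf = weather.df
    if year is None:
        year = int(wdf["date"].dt.year.iloc[0])
    sowing = dt.date(year, 1, 1) + dt.timedelta(days=config.sowing_doy - 1)
    wdf = wdf[wdf["date"].dt.date >= sowing].reset_index(drop=True)
    if len(wdf) == 0:
        raise ValueError(f"weather series does not cover sowing date {sowing}")

    prof = config.profile
    cult = config.cultivar
    ox = config.oxdef
    soil_state = _initial_soil_state(config)
    state = cr.CropState(biomass=20.0, lai=0.02, plant_n=1.0)
    tracker = _TreatmentTracker(config.treatments, cult)
    trace_rows: list[dict] = []
    maturity_date: dt.date | None = None
    truncated = False
    tt_r5_mat = cult.tt_targets[4]
    prev_stage = state.stage_code
    prev_flood_forced = False

    for _, wrow in wdf.iterrows():
        date = wrow["date"].date()
        tmax, tmin, radn, rain = (
            float(wrow["tmax"]), float(wrow["tmin"]), float(wrow["radn"]), float(wrow["rain"])
        )

        # --- flood forcing ---
        flood_forced = tracker.active(date, state.stage_code)
        if flood_forced:
            soil_state = so.force_flood(prof, soil_state)
        elif prev_flood_forced:
            # treatment window over: the imposed floodwater is released
            # (the trial fields were surface-drained), returning the profile
            # to field capacity
            released = soil_state.pond_mm
            soil_state.pond_mm = 0.0
            dul_ = prof.arr("dul")
            for i in range(prof.n_layers):
                if soil_state.sw[i] > dul_[i]:
                    released += (soil_state.sw[i] - dul_[i]) * prof.thickness[i]
                    soil_state.sw[i] = dul_[i]
            soil_state.cum_runoff += released
            logger.info("flood release on %s: %.1f mm surface-drained", date, released)
        prev_flood_forced = flood_forced

        # --- morning supply/demand (drives transpiration in the balance) ---
        emerged = state.stage_code >= cr.STAGE_EMERGENCE
        intercepted = cr.intercepted_radiation(radn, state.lai, cult.k_extinction)
        pot_growth_g_m2 = intercepted * cult.rue if emerged else 0.0
        vpd = cr.vpd_from_temps(tmax, tmin)
        demand_mm = cr.transpiration_demand(pot_growth_g_m2, cult.te_coeff, vpd)
        wtd_morning = so.water_table_depth(prof, soil_state)
        ponded = wtd_morning <= so.SAT_EPS
        supply_mm = so.available_supply(prof, soil_state, state.root_depth)

        # optional irrigation: keep control-style runs free of drought stress
        # (the emulated flooding trials were water-replete apart from floods)
        if config.auto_irrigate and not ponded and emerged and supply_mm < demand_mm:
            dul = prof.arr("dul")
            tops_, bottoms_ = prof.tops, prof.bottoms
            added_irr = 0.0
            for i in range(prof.n_layers):
                if min(bottoms_[i], state.root_depth) - tops_[i] <= 0:
                    break
                if soil_state.sw[i] < dul[i]:
                    added_irr += (dul[i] - soil_state.sw[i]) * prof.thickness[i]
                    soil_state.sw[i] = dul[i]
            soil_state.cum_irrigation += added_irr
            supply_mm = so.available_supply(prof, soil_state, state.root_depth)

        th = prof.thickness
        ll15 = prof.arr("ll15")
        sat = prof.arr("sat")
        paw = np.maximum(0.0, (soil_state.sw - ll15) * th)
        if ponded:
            drought_mult = 1.0
            transp_total = demand_mm
            transp_by_layer = None  # met from surface water
        else:
            drought_mult = st.drought_photo_stress(supply_mm, demand_mm)
            transp_total = min(demand_mm, supply_mm)
            weights = np.zeros(prof.n_layers)
            tops, bottoms = prof.tops, prof.bottoms
            for i in range(prof.n_layers):
                t_in = max(0.0, min(bottoms[i], state.root_depth) - tops[i])
                if t_in <= 0 or soil_state.sw[i] >= sat[i] - so.SAT_EPS:
                    continue
                weights[i] = prof.layers[i].kl * paw[i] * (t_in / th[i])
            wsum = weights.sum()
            transp_by_layer = transp_total * weights / wsum if wsum > 0 else np.zeros(prof.n_layers)

        pot_evap = 0.6 * (radn / 2.45) * np.exp(-cult.k_extinction * state.lai)
        if flood_forced:
            evap_demand = 0.0  # evaporation comes off the imposed floodwater
        elif transp_by_layer is not None:
            evap_demand = min(pot_evap, max(0.0, paw[0] - transp_by_layer[0]))
        else:
            evap_demand = pot_evap  # natural ponding: pond evaporates first

        # --- water balance step ---
        soil_state = so.step_water_balance(prof, soil_state, rain, evap_demand, transp_by_layer)
        if ponded:
            # transpiration (and on forced days evaporation) met from the
            # free surface water, logged as flood irrigation for the ledger
            soil_state.cum_transp += transp_total
            soil_state.cum_flood_irrigation += transp_total
            if flood_forced:
                soil_state.cum_evap += pot_evap
                soil_state.cum_flood_irrigation += pot_evap
        soil_state = so.step_mineral_n(
            prof, soil_state, config.mineralization_rate, config.denit_rate
        )
        if flood_forced:
            # the imposed "excessive rainfall" keeps the profile saturated
            # through the day; top up whatever drained during the step
            soil_state = so.force_flood(prof, soil_state)

        # --- diagnostics ---
        wtd = so.water_table_depth(prof, soil_state)
        frac_sub = so.fraction_roots_submerged(max(state.root_depth, 1.0), wtd)
        wfps = so.wfps_excess_fraction(prof, soil_state, ox.fix_activation_depth)

        # --- phenology ---
        tt = cr.daily_thermal_time(tmax, tmin, cult.base_temp, cult.opt_temp)
        if config.enable_oxdef and emerged:
            pheno_mult = st.oxdef_pheno(frac_sub, state.stage_code, ox)
        else:
            pheno_mult = 1.0
        state = cr.advance_phenology(state, tt, pheno_mult, cult)
        if int(state.stage_code) > int(prev_stage):
            logger.info("stage transition to %.1f on %s", state.stage_code, date)
        prev_stage = state.stage_code

        # --- root growth ---
        if emerged:
            state.root_depth = cr.root_growth(state, prof, soil_state, cult)

        # --- photosynthesis stress (waterlogging + recovery, then drought) ---
        if config.enable_oxdef and emerged:
            ox_photo_raw = st.oxdef_photo(frac_sub, state.stage_code, ox)
            photo_floor = st.apply_stage_severity(ox.photo.ys[-1], state.stage_code, ox.stage)
            ox_photo_eff, state.photo_carry = st.post_flood_recovery(
                ox_photo_raw, ox_photo_raw < 1.0 - 1e-12, state.stage_code, ox,
                state.photo_carry, full_stress_y=photo_floor,
            )
        else:
            ox_photo_eff = 1.0
        water_mult = min(drought_mult, ox_photo_eff)

        # --- N uptake and fixation ---
        if config.enable_oxdef and emerged:
            ox_fix_raw = st.oxdef_fix(wfps, state.stage_code, ox)
            ox_fix_eff, state.fix_carry = st.post_flood_recovery(
                ox_fix_raw, ox_fix_raw < 1.0 - 1e-12, state.stage_code, ox, state.fix_carry
            )
        else:
            ox_fix_eff = 1.0
        pot_growth_kg = pot_growth_g_m2 * 10.0
        if state.stage_code < cr.STAGE_R3:
            conc_new = cult.n_conc_veg
        else:
            conc_new = (
                cult.grain_fill_fraction * cult.n_conc_grain
                + (1.0 - cult.grain_fill_fraction) * 0.015
            )
        crit_conc = cult.n_conc_crit(state.stage_code)
        luxury_target = cult.n_luxury * crit_conc * max(state.biomass, 1.0)
        demand_n = max(0.0, pot_growth_kg * conc_new) + 0.3 * max(
            0.0, luxury_target - state.plant_n
        )
        accessible = so.accessible_mineral_n(
            prof, soil_state, state.root_depth, config.n_access_frac
        ) if emerged else 0.0
        uptake, fixed, _n_ratio = cr.n_uptake_and_fixation(
            state, accessible, demand_n, ox_fix_eff, state.stage_code, cult
        )
        if uptake > 0:
            soil_state = so.take_up_mineral_n(prof, soil_state, state.root_depth, uptake)
        state.plant_n += uptake + fixed
        state.cum_uptake_n += uptake
        state.cum_fixed_n += fixed

        # pool-based N stress for growth (plant N concentration between
        # minimum and critical); buffers short interruptions of N supply
        conc = state.plant_n / max(state.biomass, 1.0)
        n_min = cult.n_min_frac * crit_conc
        n_stress_growth = float(
            np.clip((conc - n_min) / (crit_conc - n_min), 0.0, 1.0)
        )

        # --- growth ---
        if emerged:
            dW = cr.daily_growth(intercepted, cult.rue, water_mult, n_stress_growth)
        else:
            dW = 0.0
        state.biomass += dW
        # leaf area: thermal exponential expansion while the canopy is open,
        # then biomass-driven expansion to R5, senescence after
        if state.stage_code < cr.STAGE_R5:
            leaf_frac = cult.leaf_fraction * float(
                np.interp(state.stage_code, [cr.STAGE_R3, cr.STAGE_R5], [1.0, 0.0])
            )
            inc = leaf_frac * (dW / 10.0) * cult.sla
            if state.lai < 1.5 and emerged:
                # seedling phase: relative expansion on stress-modified
                # thermal time (waterlogging and N stress slow it too)
                rel = 0.012 * tt * pheno_mult * min(water_mult, n_stress_growth)
                inc = max(inc, state.lai * rel)
            state.lai = min(cult.max_lai, state.lai + inc)
            # After flowering, N shortage strips leaf N and sheds leaf area;
            # vegetative plants replace leaves as new nodes form, so shedding
            # only depresses the canopy once node production has ceased.
            if state.stage_code >= cr.STAGE_R1:
                state.lai *= 1.0 - 0.08 * (1.0 - n_stress_growth)
        else:
            # post-R5 senescence runs on a calendar clock (leaf ageing and
            # shortening days), so late-maturing crops senesce before finishing
            state.lai *= float(np.exp(-0.055))

        # --- grain fill ---
        state = cr.grain_fill(state, dW, cult)

        trace_rows.append(
            {
                "date": date,
                "stage_code": state.stage_code,
                "v_stage": state.v_stage,
                "biomass": state.biomass,
                "dW": dW,
                "lai": state.lai,
                "grain": state.grain,
                "root_depth": state.root_depth,
                "plant_n": state.plant_n,
                "cum_fixed_n": state.cum_fixed_n,
                "cum_uptake_n": state.cum_uptake_n,
                "water_table_mm": wtd,
                "frac_roots_submerged": frac_sub,
                "wfps_excess": wfps,
                "drought_mult": drought_mult,
                "oxdef_photo_mult": ox_photo_eff,
                "oxdef_pheno_mult": pheno_mult,
                "oxdef_fix_mult": ox_fix_eff,
                "n_stress": n_stress_growth,
                "rain": rain,
                "flood_forced": flood_forced,
                "sw_mean": float(np.mean(soil_state.sw)),
                "stored_water": soil_state.stored_water(prof),
                "cum_rain": soil_state.cum_rain,
                "cum_runoff": soil_state.cum_runoff,
                "cum_drainage": soil_state.cum_drainage,
                "cum_evap": soil_state.cum_evap,
                "cum_transp": soil_state.cum_transp,
                "cum_flood_irrigation": soil_state.cum_flood_irrigation,
                "cum_irrigation": soil_state.cum_irrigation,
                "soil_mineral_n": float(soil_state.mineral_n.sum()),
            }
        )

        if state.stage_code >= cr.STAGE_MATURITY:
            maturity_date = date
            break
    else:
        truncated = True
        warnings.warn(f"weather exhausted before maturity (year {year})", stacklevel=2)

    unreached = tracker.any_unstarted_stage_triggers()
    if unreached:
        raise ValueError(
            f"flood treatment trigger stage(s) {unreached} never reached in year {year}"
        )

    trace = pd.DataFrame(trace_rows)
    return SeasonResult(
        yield_kg_ha=state.grain,
        biomass_kg_ha=state.biomass,
        cum_fixed_n=state.cum_fixed_n,
        cum_uptake_n=state.cum_uptake_n,
        maturity_date=maturity_date,
        max_root_depth=state.root_depth,
        trace=trace,
        truncated=truncated,
        year=year,
        seed=config.seed,
    )


def run_flood_experiment(
    config: SimConfig,
    stages: list[str],
    durations: list[int],
    year: int | None = None,
) -> pd.DataFrame:
    """Factorial flood-timing x duration experiment with a paired control.

    Returns one row per (stage, duration) plus the control, with yields and
    percent penalties relative to the control.
    """
    if not stages or not durations:
        raise ValueError("stages and durations must be non-empty")
    control = run_season(replace(config, treatments=()), year)
    rows = [
        {
            "stage": "control",
            "duration_days": 0,
            "yield_kg_ha": control.yield_kg_ha,
            "biomass_kg_ha": control.biomass_kg_ha,
            "cum_fixed_n": control.cum_fixed_n,
            "maturity_date": control.maturity_date,
            "penalty_pct": 0.0,
        }
    ]
    for stage in stages:
        for dur in durations:
            res = run_season(
                replace(config, treatments=(FloodTreatment(stage, dur),)), year
            )
            penalty = (
                100.0 * (control.yield_kg_ha - res.yield_kg_ha) / control.yield_kg_ha
                if control.yield_kg_ha > 0
                else float("nan")
            )
            rows.append(
                {
                    "stage": stage,
                    "duration_days": dur,
                    "yield_kg_ha": res.yield_kg_ha,
                    "biomass_kg_ha": res.biomass_kg_ha,
                    "cum_fixed_n": res.cum_fixed_n,
                    "maturity_date": res.maturity_date,
                    "penalty_pct": penalty,
                }
            )
    return pd.DataFrame(rows)


def run_multi_year(config: SimConfig, start_year: int, end_year: int) -> list[SeasonResult]:
    """Independent seasons per calendar year; soil water and mineral N reset
    to their configured initial values on January 1 of each year."""
    years = config.weather.years
    out = []
    for y in range(start_year, end_year + 1):
        if y not in years:
            raise ValueError(f"weather series does not cover year {y}")
        cfg = replace(config, weather=config.weather.year_slice(y))
        out.append(run_season(cfg, y))
    return out


SENSITIVITY_OUTPUTS = (
    "yield_kg_ha",
    "biomass_kg_ha",
    "cum_fixed_n",
    "cum_uptake_n",
    "max_root_depth",
)


def _mean_outputs(results: list[SeasonResult]) -> dict[str, float]:
    return {k: float(np.mean([getattr(r, k) for r in results])) for k in SENSITIVITY_OUTPUTS}


def run_sensitivity(
    config: SimConfig,
    sd_table: dict[str, tuple[float, ...]] | None = None,
    start_year: int | None = None,
    end_year: int | None = None,
    functions: tuple[str, ...] = ("photo", "pheno", "fix"),
    n_sds: tuple[int, ...] = (-2, -1, 1, 2),
    treatments_grid: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Perturb one oxdef function at a time by +/-1 and +/-2 SD and report
    the percent change, relative to the default parameterisation, of each
    output averaged over all flood treatments and years.  The fixation
    y(x=1)=0 anchor is never adjusted."""
    years = config.weather.years
    start_year = start_year if start_year is not None else years[0]
    end_year = end_year if end_year is not None else years[-1]
    if treatments_grid is None:
        treatments_grid = [("V4", 7), ("R2", 7)]

    def all_runs(cfg: SimConfig) -> list[SeasonResult]:
        runs = []
        for stage, dur in treatments_grid:
            c = replace(cfg, treatments=(FloodTreatment(stage, dur),))
            runs.extend(run_multi_year(c, start_year, end_year))
        return runs

    base = _mean_outputs(all_runs(config))
    rows = []
    for fn in functions:
        for n_sd in n_sds:
            perturbed = st.perturb_params(config.oxdef, fn, n_sd, sd_table)
            outs = _mean_outputs(all_runs(replace(config, oxdef=perturbed)))
            row = {
                "function": fn,
                "n_sd": n_sd,
                "pinned_saturation_anchor": fn == "fix",
            }
            for k in SENSITIVITY_OUTPUTS:
                row[f"pct_change_{k}"] = (
                    100.0 * (outs[k] - base[k]) / base[k] if base[k] != 0 else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_risk_analysis(
    config: SimConfig,
    scenario_set: list[ClimateScenario],
    start_year: int | None = None,
    end_year: int | None = None,
) -> pd.DataFrame:
    """Paired control-vs-scenario runs across years.

    Each scenario shares the unperturbed weather, soil, and cultivar of its
    same-year control; the output is the distribution of percent yield
    penalties per scenario.
    """
    years = config.weather.years
    start_year = start_year if start_year is not None else years[0]
    end_year = end_year if end_year is not None else years[-1]
    controls = run_multi_year(replace(config, scenario=None), start_year, end_year)
    rows = []
    for scen in scenario_set:
        treated = run_multi_year(replace(config, scenario=scen), start_year, end_year)
        penalties = []
        for c, t in zip(controls, treated):
            if c.yield_kg_ha > 0:
                penalties.append(100.0 * (c.yield_kg_ha - t.yield_kg_ha) / c.yield_kg_ha)
        penalties = np.asarray(penalties)
        rows.append(
            {
                "scenario": scen.name or scen.kind,
                "kind": scen.kind,
                "events_per_month": scen.events_per_month,
                "scale_factor": scen.scale_factor,
                "mean_penalty_pct": float(penalties.mean()) if len(penalties) else float("nan"),
                "median_penalty_pct": float(np.median(penalties)) if len(penalties) else float("nan"),
                "p10_penalty_pct": float(np.percentile(penalties, 10)) if len(penalties) else float("nan"),
                "p90_penalty_pct": float(np.percentile(penalties, 90)) if len(penalties) else float("nan"),
                "n_years": len(penalties),
            }
        )
    return pd.DataFrame(rows)
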