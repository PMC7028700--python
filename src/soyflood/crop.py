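"""Minimal soybean physiology: thermal-time phenology on a V/R stage scale,
Beer's-law light interception with radiation-use-efficiency growth,
transpiration demand, aeration-limited root elongation, grain fill, and a
plant N economy with soil uptake followed by symbiotic fixation.

Stage codes: 0 sowing, 1 emergence, 3 R1 (flowering), 4 R3 (pod-fill start),
5 R5 (pod-fill end), 6 maturity.  The vegetative V-stage number is tracked
by phyllochron within the emergence-R1 phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .soil import SoilProfile, SoilWaterState, air_filled_porosity_at
from .stress import RecoveryCarry

__all__ = [
    "CultivarParams",
    "CropState",
    "daily_thermal_time",
    "advance_phenology",
    "intercepted_radiation",
    "daily_growth",
    "transpiration_demand",
    "vpd_from_temps",
    "root_growth",
    "n_uptake_and_fixation",
    "grain_fill",
    "MG_PRESETS",
]

# stage-code anchors
STAGE_SOWING = 0.0
STAGE_EMERGENCE = 1.0
STAGE_R1 = 3.0
STAGE_R3 = 4.0
STAGE_R5 = 5.0
STAGE_MATURITY = 6.0

AFP_ROOT_ARREST = 0.03  # air-filled porosity below which root growth stops


@dataclass(frozen=True)
class CultivarParams:
    """Cultivar parameter set; maturity-group presets ship in MG_PRESETS.

    Thermal-time targets are degree-days per phase (sowing-emergence,
    emergence-R1, R1-R3, R3-R5, R5-maturity).
    """

    maturity_group: float = 4.0
    tt_targets: tuple[float, float, float, float, float] = (90.0, 700.0, 250.0, 450.0, 480.0)
    base_temp: float = 8.0  # degC
    opt_temp: float = 30.0  # degC
    rue: float = 0.9  # g biomass per MJ intercepted
    te_coeff: float = 0.005  # transpiration-efficiency coefficient, kPa
    k_extinction: float = 0.55
    max_root_depth: float = 1500.0  # mm
    root_elong_rate: float = 25.0  # mm d^-1
    max_lai: float = 5.5
    grain_fill_fraction: float = 0.55
    n_conc_veg: float = 0.030  # g N g^-1 vegetative growth
    n_conc_grain: float = 0.060  # g N g^-1 grain
    potential_fix_rate: float = 2.8  # kg N ha^-1 d^-1 at the R3-R5 plateau
    phyllochron: float = 70.0  # degCd per V-stage
    sla: float = 0.022  # m2 leaf per g leaf
    leaf_fraction: float = 0.45  # of new biomass to leaf, pre-R3
    n_luxury: float = 1.30  # luxury uptake factor on critical N
    n_conc_crit_early: float = 0.045  # critical whole-plant N conc at emergence
    n_conc_crit_late: float = 0.025  # critical whole-plant N conc at maturity
    n_min_frac: float = 0.55  # minimum N conc as a fraction of critical
    retranslocation_frac: float = 0.002  # of vegetative biomass per day after R5
    retranslocation_pool_frac: float = 0.04  # mobilizable share of veg biomass at R5
    n_conc_straw: float = 0.008  # residual N conc of vegetative tissue at maturity
    photoperiod_catchup: float = 0.0  # pre-R1 extra dev rate while behind schedule

    def __post_init__(self) -> None:
        if not 3.0 <= self.maturity_group <= 5.5:
            raise ValueError("maturity_group must be within 3-5.5")
        if self.base_temp >= self.opt_temp:
            raise ValueError("base_temp must be below opt_temp")
        for name in (
            "rue",
            "te_coeff",
            "k_extinction",
            "max_root_depth",
            "root_elong_rate",
            "max_lai",
            "grain_fill_fraction",
            "n_conc_veg",
            "n_conc_grain",
            "potential_fix_rate",
            "phyllochron",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def n_conc_crit(self, stage_code: float) -> float:
        """Critical whole-plant N concentration, declining with ontogeny
        (dilution of structural tissue)."""
        return float(
            np.interp(
                stage_code,
                [STAGE_EMERGENCE, STAGE_R3, STAGE_MATURITY],
                [self.n_conc_crit_early, 0.032, self.n_conc_crit_late],
            )
        )

    def stage_code_of(self, label: str) -> float:
        """Map an agronomic stage label (V4, R1, R2, R3, R5, ...) to the
        continuous stage code for this cultivar."""
        label = label.strip().upper()
        if label.startswith("V"):
            v = int(label[1:])
            tt_veg = self.tt_targets[1]
            frac = min(1.0, v * self.phyllochron / tt_veg)
            return STAGE_EMERGENCE + 2.0 * frac
        r_anchors = {"R1": 3.0, "R2": 3.5, "R3": 4.0, "R4": 4.5, "R5": 5.0, "R6": 5.5, "R8": 6.0}
        if label in r_anchors:
            return r_anchors[label]
        raise ValueError(f"unknown stage label: {label!r}")


@dataclass
class CropState:
    """Daily crop state; pools in kg ha^-1, depths in mm."""

    stage_code: float = STAGE_SOWING
    cum_tt: float = 0.0
    pot_cum_tt: float = 0.0  # thermal time without stress, for flowering catch-up
    v_stage: float = 0.0
    biomass: float = 0.0
    lai: float = 0.0
    root_depth: float = 30.0
    grain: float = 0.0
    grain_n: float = 0.0
    retrans_pool: float = -1.0  # mobilizable assimilate, set when R5 is reached
    plant_n: float = 0.0
    cum_fixed_n: float = 0.0
    cum_uptake_n: float = 0.0
    photo_carry: RecoveryCarry = field(default_factory=RecoveryCarry)
    fix_carry: RecoveryCarry = field(default_factory=RecoveryCarry)

    def copy(self) -> "CropState":
        return CropState(
            stage_code=self.stage_code,
            cum_tt=self.cum_tt,
            pot_cum_tt=self.pot_cum_tt,
            v_stage=self.v_stage,
            biomass=self.biomass,
            lai=self.lai,
            root_depth=self.root_depth,
            grain=self.grain,
            grain_n=self.grain_n,
            retrans_pool=self.retrans_pool,
            plant_n=self.plant_n,
            cum_fixed_n=self.cum_fixed_n,
            cum_uptake_n=self.cum_uptake_n,
            photo_carry=self.photo_carry.copy(),
            fix_carry=self.fix_carry.copy(),
        )


def daily_thermal_time(tmax: float, tmin: float, base_temp: float, opt_temp: float) -> float:
    """Degree-days from the daily mean, linear above base and capped at the
    optimum."""
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    mean = 0.5 * (tmax + tmin)
    return max(0.0, min(mean, opt_temp) - base_temp)


def _stage_from_tt(cum_tt: float, cultivar: CultivarParams) -> float:
    """Continuous stage code from accumulated thermal time."""
    t = cultivar.tt_targets
    bounds = np.cumsum(t)
    anchors = [STAGE_SOWING, STAGE_EMERGENCE, STAGE_R1, STAGE_R3, STAGE_R5, STAGE_MATURITY]
    if cum_tt >= bounds[-1]:
        return STAGE_MATURITY
    prev = 0.0
    for i, b in enumerate(bounds):
        if cum_tt < b:
            frac = (cum_tt - prev) / (b - prev)
            return anchors[i] + frac * (anchors[i + 1] - anchors[i])
        prev = b
    return STAGE_MATURITY


def advance_phenology(
    state: CropState, tt_today: float, pheno_multiplier: float, cultivar: CultivarParams
) -> CropState:
    """Accumulate stress-modified thermal time and update the stage code.

    A multiplier of 0 freezes development (phenological stall during a
    flood); 1 is unstressed progression.  Before flowering, a crop running
    behind its unstressed schedule partially catches up once the stress has
    passed (flowering in this short-day crop is anchored by photoperiod, so
    vegetative stalls delay R1 by less than their full length); reproductive
    development is strictly thermal.
    """
    if not 0.0 <= pheno_multiplier <= 1.0:
        raise ValueError("pheno_multiplier must lie in [0, 1]")
    s = state.copy()
    s.pot_cum_tt += tt_today
    s.cum_tt += tt_today * pheno_multiplier
    if s.stage_code < STAGE_R1 and pheno_multiplier >= 1.0 - 1e-12:
        deficit = max(0.0, s.pot_cum_tt - s.cum_tt)
        s.cum_tt += min(cultivar.photoperiod_catchup * tt_today, deficit)
    s.stage_code = max(s.stage_code, _stage_from_tt(s.cum_tt, cultivar))
    if STAGE_EMERGENCE <= s.stage_code < STAGE_R1:
        tt_since_emergence = s.cum_tt - cultivar.tt_targets[0]
        s.v_stage = max(s.v_stage, tt_since_emergence / cultivar.phyllochron)
    return s


def intercepted_radiation(radn: float, lai: float, k_extinction: float) -> float:
    """Beer's-law canopy light interception, MJ m^-2."""
    if lai < 0:
        raise ValueError("lai must be non-negative")
    return radn * (1.0 - math.exp(-k_extinction * lai))


def daily_growth(
    intercepted: float,
    rue: float,
    water_photo_multiplier: float,
    n_stress_multiplier: float,
) -> float:
    """Daily biomass increment, kg ha^-1.

    Water (the tighter of drought and waterlogging stress) and N stress
    combine through a minimum; 1 g m^-2 = 10 kg ha^-1.
    """
    for m in (water_photo_multiplier, n_stress_multiplier):
        if not 0.0 <= m <= 1.0:
            raise ValueError("stress multipliers must lie in [0, 1]")
    return intercepted * rue * min(water_photo_multiplier, n_stress_multiplier) * 10.0


def vpd_from_temps(tmax: float, tmin: float) -> float:
    """Daytime vapour-pressure deficit (kPa) from the standard 0.75-weighted
    saturation-vapour-pressure difference."""

    def svp(t: float) -> float:
        return 0.6108 * math.exp(17.27 * t / (t + 237.3))

    return max(0.01, 0.75 * (svp(tmax) - svp(tmin)))


def transpiration_demand(potential_growth_g_m2: float, te_coeff: float, vpd_kpa: float) -> float:
    """Transpiration demand (mm) to realise a potential growth rate, via a
    transpiration-efficiency coefficient normalised for VPD."""
    if vpd_kpa <= 0:
        raise ValueError("vpd must be positive")
    if potential_growth_g_m2 < 0:
        raise ValueError("potential growth must be non-negative")
    # te_coeff (kPa) / vpd -> kg biomass per kg water; 1 mm = 1 kg m^-2
    te_g_m2_per_mm = 1000.0 * te_coeff / vpd_kpa
    return potential_growth_g_m2 / te_g_m2_per_mm


def root_growth(
    state: CropState,
    profile: SoilProfile,
    soil_state: SoilWaterState,
    cultivar: CultivarParams,
) -> float:
    """New root depth: elongates at the cultivar rate unless air-filled
    porosity at the root front is below 3% (hypoxic arrest); capped at the
    cultivar maximum and the profile depth; never shrinks."""
    front = min(state.root_depth, profile.depth)
    afp = air_filled_porosity_at(profile, soil_state, front)
    if afp < AFP_ROOT_ARREST:
        return state.root_depth
    new_depth = state.root_depth + cultivar.root_elong_rate
    return min(new_depth, cultivar.max_root_depth, profile.depth)


def stage_fix_curve(stage_code: float) -> float:
    """Relative N-fixation capacity over the season: ramps 0 to 1 from
    emergence to R3 (nodule establishment), holds 1 through pod fill (the
    R3-R5 peak), then declines as nodules senesce toward maturity."""
    return float(
        np.interp(
            stage_code,
            [STAGE_EMERGENCE, STAGE_R3, STAGE_R5, STAGE_MATURITY],
            [0.0, 1.0, 1.0, 0.2],
        )
    )


def n_uptake_and_fixation(
    state: CropState,
    soil_mineral_n: float,
    n_demand: float,
    fix_multiplier: float,
    stage_code: float,
    cultivar: CultivarParams,
) -> tuple[float, float, float]:
    """Daily N acquisition: soil uptake first, fixation covers the residual.

    ``soil_mineral_n`` is the accessible pool (root-zone, non-saturated
    layers).  Returns (uptake, fixed, n_stress_multiplier); the stress
    multiplier is the supplied fraction of demand, 1 when demand is zero.
    """
    if min(soil_mineral_n, n_demand, fix_multiplier) < 0:
        raise ValueError("inputs must be non-negative")
    uptake = min(n_demand, soil_mineral_n)
    fix_capacity = cultivar.potential_fix_rate * stage_fix_curve(stage_code) * fix_multiplier
    fixed = min(max(0.0, n_demand - uptake), fix_capacity)
    if n_demand <= 0:
        return 0.0, 0.0, 1.0
    n_stress = min(1.0, (uptake + fixed) / n_demand)
    return uptake, fixed, n_stress


def grain_fill(
    state: CropState, daily_biomass_increment: float, cultivar: CultivarParams
) -> CropState:
    """Allocate growth to grain between R3 and maturity, plus a small
    retranslocation from vegetative biomass after R5.  Grain growth is
    N-limited: each kg of grain requires grain-concentration N drawn from the
    plant pool, with vegetative tissue strippable down to a minimum
    concentration."""
    s = state.copy()
    if s.stage_code < STAGE_R3 or s.stage_code >= STAGE_MATURITY:
        return s
    inc = cultivar.grain_fill_fraction * max(0.0, daily_biomass_increment)
    veg_biomass = max(0.0, s.biomass - s.grain)
    if s.stage_code >= STAGE_R5:
        if s.retrans_pool < 0:
            s.retrans_pool = cultivar.retranslocation_pool_frac * veg_biomass
        retrans = min(cultivar.retranslocation_frac * veg_biomass, s.retrans_pool)
        s.retrans_pool -= retrans
        inc += retrans
    inc = min(inc, max(0.0, s.biomass - s.grain))
    # N limitation on grain fill
    n_avail = (s.plant_n - s.grain_n) - cultivar.n_conc_straw * veg_biomass
    n_needed = cultivar.n_conc_grain * inc
    if n_needed > 0 and n_avail < n_needed:
        inc *= max(0.0, n_avail) / n_needed
    s.grain += inc
    s.grain_n += cultivar.n_conc_grain * inc
    return s


MG_PRESETS: dict[str, CultivarParams] = {
    "MG3": CultivarParams(maturity_group=3.0, tt_targets=(90.0, 600.0, 230.0, 420.0, 440.0)),
    "MG4": CultivarParams(maturity_group=4.0, tt_targets=(90.0, 700.0, 250.0, 450.0, 480.0)),
    "MG5": CultivarParams(maturity_group=5.0, tt_targets=(90.0, 790.0, 270.0, 480.0, 510.0)),
    "MG5.5": CultivarParams(maturity_group=5.5, tt_targets=(90.0, 840.0, 280.0, 490.0, 530.0)),
}
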