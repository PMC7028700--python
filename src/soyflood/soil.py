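"""Layered tipping-bucket soil water balance with perched water-table
tracking, flood forcing, and the root-zone diagnostics the waterlogging
stress functions consume.

Depths are in mm below the surface; layers are indexed top-down with
half-open intervals [top, bottom).  Volumetric water contents are bounded by
``ll15`` (lower limit of plant extraction), ``dul`` (drained upper limit /
field capacity) and ``sat`` (saturation).  Water in excess of ``dul`` drains
to the layer below at most at the layer's ``ks``; water that cannot drain
backs up, which is how a low-conductivity subsoil perches a water table.

A small per-layer mineral-N pool rides along with the water state: a fixed
daily mineralisation input feeds the top layer, plants withdraw from
non-saturated root-zone layers only, and saturated layers lose nitrate to
denitrification/leaching at a first-order rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilWaterState",
    "SAT_EPS",
    "step_water_balance",
    "water_table_depth",
    "force_flood",
    "fraction_roots_submerged",
    "wfps_excess_fraction",
    "available_supply",
    "air_filled_porosity_at",
    "accessible_mineral_n",
    "take_up_mineral_n",
    "step_mineral_n",
]

SAT_EPS = 1e-4  # volumetric tolerance for "saturated" comparisons


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer: geometry, hydraulic limits and extraction parameters."""

    thickness: float  # mm
    ll15: float  # volumetric lower limit
    dul: float  # volumetric drained upper limit (field capacity)
    sat: float  # volumetric saturation
    bd: float  # bulk density, g cm^-3
    ks: float  # saturated drainage rate to the layer below, mm d^-1
    kl: float = 0.10  # fraction of plant-available water extractable per day

    def __post_init__(self) -> None:
        if not (0.0 < self.ll15 < self.dul < self.sat < 1.0):
            raise ValueError(
                f"require 0 < ll15 < dul < sat < 1, got "
                f"ll15={self.ll15}, dul={self.dul}, sat={self.sat}"
            )
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.ks < 0 or self.kl < 0:
            raise ValueError("ks and kl must be non-negative")


@dataclass(frozen=True)
class SoilProfile:
    """Ordered layers plus the surface ponding capacity: infiltration-excess
    water accumulates in a surface pond (up to ``pond_capacity`` mm, e.g. on
    flat graded fields) and re-infiltrates on later days; only overflow
    beyond the pond runs off."""

    layers: tuple[SoilLayer, ...]
    pond_capacity: float = 0.0  # mm of surface storage before runoff

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.pond_capacity < 0:
            raise ValueError("pond_capacity must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def thickness(self) -> np.ndarray:
        return np.array([l.thickness for l in self.layers])

    @property
    def depth(self) -> float:
        """Total profile depth, mm."""
        return float(self.thickness.sum())

    @property
    def tops(self) -> np.ndarray:
        t = np.concatenate([[0.0], np.cumsum(self.thickness)])
        return t[:-1]

    @property
    def bottoms(self) -> np.ndarray:
        return np.cumsum(self.thickness)

    def arr(self, attr: str) -> np.ndarray:
        return np.array([getattr(l, attr) for l in self.layers])

    def layer_at(self, depth_mm: float) -> int:
        """Index of the layer containing ``depth_mm`` ([top, bottom))."""
        if depth_mm < 0 or depth_mm > self.depth:
            raise ValueError(f"depth {depth_mm} mm outside profile (0-{self.depth})")
        if depth_mm == self.depth:
            return self.n_layers - 1
        return int(np.searchsorted(self.bottoms, depth_mm, side="right"))


@dataclass
class SoilWaterState:
    """Daily soil water and mineral-N state plus cumulative ledgers (mm)."""

    sw: np.ndarray  # volumetric water content per layer
    mineral_n: np.ndarray  # kg N ha^-1 per layer
    pond_mm: float = 0.0  # standing surface water
    cum_drainage: float = 0.0
    cum_runoff: float = 0.0
    cum_evap: float = 0.0
    cum_transp: float = 0.0
    cum_rain: float = 0.0
    cum_flood_irrigation: float = 0.0  # water added by flood forcing
    cum_irrigation: float = 0.0  # water added by auto-irrigation
    cum_denit: float = 0.0  # kg N ha^-1 lost from saturated layers
    ponded: bool = False

    def copy(self) -> "SoilWaterState":
        return SoilWaterState(
            sw=self.sw.copy(),
            mineral_n=self.mineral_n.copy(),
            pond_mm=self.pond_mm,
            cum_drainage=self.cum_drainage,
            cum_runoff=self.cum_runoff,
            cum_evap=self.cum_evap,
            cum_transp=self.cum_transp,
            cum_rain=self.cum_rain,
            cum_flood_irrigation=self.cum_flood_irrigation,
            cum_irrigation=self.cum_irrigation,
            cum_denit=self.cum_denit,
            ponded=self.ponded,
        )

    def stored_water(self, profile: SoilProfile) -> float:
        """Total stored water including any surface pond, mm."""
        return float(np.sum(self.sw * profile.thickness)) + self.pond_mm


def step_water_balance(
    profile: SoilProfile,
    state: SoilWaterState,
    rain_mm: float,
    soil_evap_demand_mm: float,
    transpiration_by_layer_mm: np.ndarray | None = None,
) -> SoilWaterState:
    """Advance the water balance by one day.

    Order: infiltrate rain plus yesterday's surface pond and cascade (fill
    to ``dul``, drain above-``dul`` water downward at ``ks``, back up water
    above ``sat``); surface excess refills the pond up to ``pond_capacity``
    and only the overflow runs off.  Then evaporation (pond first, then
    layer 1 down to ``ll15``), then transpiration withdrawal per layer.
    Bottom-layer outflow is drainage.
    """
    if rain_mm < 0 or soil_evap_demand_mm < 0:
        raise ValueError("rain and evaporation demand must be non-negative")
    s = state.copy()
    th = profile.thickness
    dul = profile.arr("dul")
    sat = profile.arr("sat")
    ll15 = profile.arr("ll15")
    ks = profile.arr("ks")
    n = profile.n_layers

    # --- infiltration + gravity drainage (single top-down pass) ---
    inflow = rain_mm + s.pond_mm
    s.pond_mm = 0.0
    drainage = 0.0
    for i in range(n):
        s.sw[i] += inflow / th[i]
        drainable = max(0.0, (s.sw[i] - dul[i]) * th[i])
        outflow = min(ks[i], drainable)
        s.sw[i] -= outflow / th[i]
        inflow = outflow
    drainage = inflow

    # --- back-flooding: push water above saturation upward; the surface
    # excess ponds up to capacity, the rest runs off
    runoff = 0.0
    for i in range(n - 1, -1, -1):
        excess = max(0.0, (s.sw[i] - sat[i]) * th[i])
        if excess > 0.0:
            s.sw[i] = sat[i]
            if i == 0:
                s.pond_mm = min(excess, profile.pond_capacity)
                runoff += excess - s.pond_mm
            else:
                s.sw[i - 1] += excess / th[i - 1]

    # --- evaporation: standing water first, then layer 1 down to ll15 ---
    evap = min(soil_evap_demand_mm, s.pond_mm)
    s.pond_mm -= evap
    soil_evap = min(
        soil_evap_demand_mm - evap, max(0.0, (s.sw[0] - ll15[0]) * th[0])
    )
    s.sw[0] -= soil_evap / th[0]
    evap += soil_evap

    # --- transpiration withdrawal ---
    transp_total = 0.0
    if transpiration_by_layer_mm is not None:
        transp = np.asarray(transpiration_by_layer_mm, dtype=float)
        if np.any(transp < 0):
            raise ValueError("transpiration must be non-negative")
        avail = np.maximum(0.0, (s.sw - ll15) * th)
        if np.any(transp > avail + 1e-9):
            raise ValueError("transpiration exceeds plant-available water in a layer")
        s.sw -= transp / th
        transp_total = float(transp.sum())

    s.cum_rain += rain_mm
    s.cum_drainage += drainage
    s.cum_runoff += runoff
    s.cum_evap += evap
    s.cum_transp += transp_total
    s.ponded = bool(water_table_depth(profile, s) <= SAT_EPS)
    return s


def water_table_depth(profile: SoilProfile, state: SoilWaterState) -> float:
    """Depth (mm) to the top of the deepest contiguous block of saturated
    layers — the groundwater table when the block reaches the profile
    bottom, or a perched table sitting on a restrictive layer otherwise.
    Returns the full profile depth if no layer is saturated; 0 whenever
    water is standing on the surface."""
    if state.pond_mm > 0:
        return 0.0
    sat = profile.arr("sat")
    tops = profile.tops
    is_sat = state.sw >= sat - SAT_EPS
    depth = profile.depth
    i = profile.n_layers - 1
    while i >= 0:
        if is_sat[i]:
            top = i
            while top > 0 and is_sat[top - 1]:
                top -= 1
            depth = float(tops[top])
            break
        i -= 1
    return depth


def force_flood(profile: SoilProfile, state: SoilWaterState) -> SoilWaterState:
    """Saturate the whole profile (water table at the surface), logging the
    added water as forced irrigation.  Idempotent on saturated states."""
    s = state.copy()
    sat = profile.arr("sat")
    added = float(np.sum(np.maximum(0.0, sat - s.sw) * profile.thickness))
    s.sw = sat.copy()
    s.cum_flood_irrigation += added
    s.ponded = True
    return s


def fraction_roots_submerged(root_depth_mm: float, water_table_depth_mm: float) -> float:
    """Fraction of the root system below the water table, clamped to [0, 1]."""
    if root_depth_mm <= 0:
        raise ValueError("root_depth must be positive")
    return float(min(1.0, max(0.0, (root_depth_mm - water_table_depth_mm) / root_depth_mm)))


def wfps_excess_fraction(
    profile: SoilProfile, state: SoilWaterState, activation_depth_mm: float = 450.0
) -> float:
    """Thickness-weighted mean, over the top ``activation_depth_mm`` of soil,
    of the position of water content between field capacity (0) and
    saturation (1).  The predictor of the N-fixation stress function."""
    if activation_depth_mm <= 0:
        raise ValueError("activation_depth must be positive")
    tops, bottoms = profile.tops, profile.bottoms
    dul = profile.arr("dul")
    sat = profile.arr("sat")
    w_sum = 0.0
    t_sum = 0.0
    for i in range(profile.n_layers):
        t_in = max(0.0, min(bottoms[i], activation_depth_mm) - tops[i])
        if t_in <= 0:
            break
        frac = (state.sw[i] - dul[i]) / (sat[i] - dul[i])
        w_sum += t_in * min(1.0, max(0.0, frac))
        t_sum += t_in
    return w_sum / t_sum if t_sum > 0 else 0.0


def available_supply(
    profile: SoilProfile, state: SoilWaterState, root_depth_mm: float
) -> float:
    """Daily plant-available water supply (mm) from the root zone.

    Saturated layers are excluded: uptake ceases from layers saturated with
    water.  Each remaining layer contributes its plant-available water times
    its extraction coefficient ``kl``.
    """
    if root_depth_mm < 0:
        raise ValueError("root_depth must be non-negative")
    tops, bottoms = profile.tops, profile.bottoms
    sat = profile.arr("sat")
    ll15 = profile.arr("ll15")
    supply = 0.0
    for i in range(profile.n_layers):
        t_in = max(0.0, min(bottoms[i], root_depth_mm) - tops[i])
        if t_in <= 0:
            break
        if state.sw[i] >= sat[i] - SAT_EPS:
            continue
        supply += t_in * max(0.0, state.sw[i] - ll15[i]) * profile.layers[i].kl
    return supply


def air_filled_porosity_at(
    profile: SoilProfile, state: SoilWaterState, depth_mm: float
) -> float:
    """Air-filled porosity (sat - sw) of the layer containing ``depth_mm``."""
    i = profile.layer_at(depth_mm)
    return float(profile.layers[i].sat - state.sw[i])


def accessible_mineral_n(
    profile: SoilProfile,
    state: SoilWaterState,
    root_depth_mm: float,
    daily_access_frac: float = 0.10,
) -> float:
    """Mineral N (kg ha^-1) the plant can take up today: a fraction of the
    pool in root-zone layers, excluding saturated layers (the same exclusion
    rule as water supply)."""
    tops, bottoms = profile.tops, profile.bottoms
    sat = profile.arr("sat")
    total = 0.0
    for i in range(profile.n_layers):
        t_in = max(0.0, min(bottoms[i], root_depth_mm) - tops[i])
        if t_in <= 0:
            break
        if state.sw[i] >= sat[i] - SAT_EPS:
            continue
        total += state.mineral_n[i] * (t_in / profile.layers[i].thickness)
    return total * daily_access_frac


def take_up_mineral_n(
    profile: SoilProfile, state: SoilWaterState, root_depth_mm: float, amount: float
) -> SoilWaterState:
    """Remove ``amount`` kg N ha^-1 from non-saturated root-zone layers,
    proportionally to each layer's accessible pool."""
    s = state.copy()
    if amount <= 0:
        return s
    tops, bottoms = profile.tops, profile.bottoms
    sat = profile.arr("sat")
    weights = np.zeros(profile.n_layers)
    for i in range(profile.n_layers):
        t_in = max(0.0, min(bottoms[i], root_depth_mm) - tops[i])
        if t_in <= 0 or s.sw[i] >= sat[i] - SAT_EPS:
            continue
        weights[i] = s.mineral_n[i] * (t_in / profile.layers[i].thickness)
    total = weights.sum()
    if total <= 0:
        if amount > 1e-9:
            raise ValueError("cannot take up N: no accessible mineral N")
        return s
    if amount > total + 1e-9:
        raise ValueError("N uptake exceeds accessible mineral N")
    s.mineral_n -= amount * weights / total
    s.mineral_n = np.maximum(s.mineral_n, 0.0)
    return s


def step_mineral_n(
    profile: SoilProfile,
    state: SoilWaterState,
    mineralization_rate: float,
    denit_rate: float,
) -> SoilWaterState:
    """Daily mineral-N bookkeeping: a fixed mineralisation input to the top
    layer (insensitive to excess moisture) and first-order loss from
    saturated layers (denitrification plus leaching)."""
    s = state.copy()
    sat = profile.arr("sat")
    s.mineral_n[0] += mineralization_rate
    for i in range(profile.n_layers):
        if s.sw[i] >= sat[i] - SAT_EPS:
            loss = s.mineral_n[i] * denit_rate
            s.mineral_n[i] -= loss
            s.cum_denit += loss
    return s
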