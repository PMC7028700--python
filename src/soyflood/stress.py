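"""Moisture stress functions: drought supply/demand stress and the three
oxygen-deficit ("oxdef") waterlogging multipliers.

All stress functions are 0-1 multipliers built from piecewise-linear x/y
pairs, where x is a soil-moisture predictor and y the relative rate of the
affected process.  The excess-water functions share two anchors: x = 0 at
field capacity (no stress) and x = 1 at saturation (full stress).  Three
processes are affected:

* ``oxdef_photo`` -- radiation-use efficiency (canopy photosynthesis),
  driven by the fraction of the root system under the water table.
* ``oxdef_pheno`` -- thermal-time accumulation (development rate), same
  predictor as photosynthesis.
* ``oxdef_fix``   -- symbiotic N fixation, driven by the water-filled
  pore-space excess fraction of the top 0.45 m (the nodule zone).

A stage-severity wrapper deepens the stress during reproductive stages, and
an explicit recovery carry-over realises the observed asymmetry: plants
recover fully from vegetative floods but retain part of the damage when the
flood occurs at or after flowering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PiecewiseMultiplier",
    "StageSeverity",
    "RecoveryCarry",
    "OxdefParams",
    "evaluate_multiplier",
    "drought_photo_stress",
    "apply_stage_severity",
    "oxdef_photo",
    "oxdef_pheno",
    "oxdef_fix",
    "post_flood_recovery",
    "perturb_params",
    "DEFAULT_SD_TABLE",
]

# Stage codes used by the severity ramp (see crop.py for the full scale).
STAGE_R1 = 3.0  # beginning flowering
STAGE_R3 = 4.0  # beginning pod fill


@dataclass(frozen=True)
class PiecewiseMultiplier:
    """A 0-1 response function defined by x/y pairs, linearly interpolated
    between pairs and clamped to the terminal y values outside the x range."""

    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __post_init__(self) -> None:
        xs = tuple(float(v) for v in self.xs)
        ys = tuple(float(v) for v in self.ys)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)
        if len(xs) != len(ys):
            raise ValueError("xs and ys must have equal length")
        if len(xs) < 2:
            raise ValueError("need at least two x/y pairs")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("xs must be strictly increasing")
        if any(not 0.0 <= y <= 1.0 for y in ys):
            raise ValueError("all ys must lie in [0, 1]")

    def __call__(self, x: float) -> float:
        return evaluate_multiplier(self, x)


def evaluate_multiplier(fn: PiecewiseMultiplier, x: float) -> float:
    """Interpolate the multiplier at predictor value ``x`` (clamped)."""
    return float(np.interp(x, fn.xs, fn.ys))


def drought_photo_stress(supply_mm: float, demand_mm: float) -> float:
    """Drought multiplier: the soil-water supply to transpiration-demand
    ratio, capped at 1.  Stress appears only when the ratio falls below 1."""
    if supply_mm < 0 or demand_mm < 0:
        raise ValueError("supply and demand must be non-negative")
    if demand_mm == 0:
        return 1.0
    return min(1.0, supply_mm / demand_mm)


@dataclass(frozen=True)
class StageSeverity:
    """Stage dependency of waterlogging stress.

    The severity factor S multiplies the stress *depth* (1 - y).  It holds at
    ``severity_veg`` before ``sensitive_stage_start`` (user-defined, default
    R1) and ramps linearly to ``severity_rep`` at pod-fill onset (R3),
    staying there through maturity.
    """

    sensitive_stage_start: float = STAGE_R1
    severity_veg: float = 1.0
    severity_rep: float = 1.2

    def __post_init__(self) -> None:
        if self.severity_veg < 0 or self.severity_rep < self.severity_veg:
            raise ValueError("require 0 <= severity_veg <= severity_rep")

    def factor(self, stage_code: float) -> float:
        return float(
            np.interp(
                stage_code,
                [self.sensitive_stage_start, STAGE_R3],
                [self.severity_veg, self.severity_rep],
            )
        )


def apply_stage_severity(base_y: float, stage_code: float, stage: StageSeverity) -> float:
    """Deepen a base multiplier by the stage-severity factor:
    y_eff = 1 - (1 - y) * S(stage), clamped to [0, 1]."""
    if not 0.0 <= base_y <= 1.0:
        raise ValueError("base_y must lie in [0, 1]")
    s = stage.factor(stage_code)
    return float(min(1.0, max(0.0, 1.0 - (1.0 - base_y) * s)))


@dataclass
class RecoveryCarry:
    """Mutable carry-over state for post-flood recovery of one process.

    Accumulates the season's waterlogging exposure incurred at or after the
    sensitive stage, in full-stress-equivalent days; exposure before the
    sensitive stage leaves no trace (full vegetative recovery).
    """

    exposure: float = 0.0  # cumulative reproductive-stage stress exposure, days

    @property
    def cap(self) -> float:  # backward-compatible view for traces
        return self.exposure

    def copy(self) -> "RecoveryCarry":
        return RecoveryCarry(self.exposure)


@dataclass(frozen=True)
class OxdefParams:
    """Parameter set for the excess-water stress functions.

    Default x/y pairs honour the calibration anchors: photosynthesis and
    phenology respond only once ~80% of the root system is submerged;
    fixation responds beyond a pore-space excess of 0.5 and stops entirely
    at saturation.  Terminal photosynthesis depth (25% at full submergence,
    vegetative) sits inside the 16-33% range reported for 48-h V4 floods.
    """

    photo: PiecewiseMultiplier = field(
        default_factory=lambda: PiecewiseMultiplier((0.0, 0.8, 1.0), (1.0, 1.0, 0.75))
    )
    pheno: PiecewiseMultiplier = field(
        default_factory=lambda: PiecewiseMultiplier((0.0, 0.8, 1.0), (1.0, 1.0, 0.65))
    )
    fix: PiecewiseMultiplier = field(
        default_factory=lambda: PiecewiseMultiplier((0.0, 0.5, 1.0), (1.0, 1.0, 0.0))
    )
    stage: StageSeverity = field(default_factory=StageSeverity)
    fix_activation_depth: float = 450.0  # mm; nodule zone, user-definable
    recovery_persistence: float = 0.65
    recovery_saturation_days: float = 17.0  # full-stress days to maximum persistent damage

    def __post_init__(self) -> None:
        if self.fix.ys[-1] != 0.0:
            raise ValueError("oxdef_fix must satisfy y = 0 at x = 1 (saturation)")
        if self.fix_activation_depth <= 0:
            raise ValueError("fix_activation_depth must be positive")
        if not 0.0 <= self.recovery_persistence <= 1.0:
            raise ValueError("recovery_persistence must lie in [0, 1]")
        if self.recovery_saturation_days <= 0:
            raise ValueError("recovery_saturation_days must be positive")


def oxdef_photo(frac_submerged: float, stage_code: float, params: OxdefParams) -> float:
    """RUE multiplier under excess water, stage-adjusted."""
    base = evaluate_multiplier(params.photo, frac_submerged)
    return apply_stage_severity(base, stage_code, params.stage)


def oxdef_pheno(frac_submerged: float, stage_code: float, params: OxdefParams) -> float:
    """Development-rate multiplier under excess water, stage-adjusted."""
    base = evaluate_multiplier(params.pheno, frac_submerged)
    return apply_stage_severity(base, stage_code, params.stage)


def oxdef_fix(wfps_excess: float, stage_code: float, params: OxdefParams) -> float:
    """N-fixation multiplier driven by nodule-zone pore-space excess.

    The x = 1 anchor is pinned: fixation is exactly zero on saturated soil
    regardless of stage severity.
    """
    if wfps_excess >= params.fix.xs[-1]:
        return float(params.fix.ys[-1])  # pinned anchor: 0 at saturation
    base = evaluate_multiplier(params.fix, wfps_excess)
    return apply_stage_severity(base, stage_code, params.stage)


def post_flood_recovery(
    stress_today: float,
    flood_active: bool,
    stage_code: float,
    params: OxdefParams,
    carry: RecoveryCarry,
    full_stress_y: float = 0.0,
) -> tuple[float, RecoveryCarry]:
    """Apply the recover/not-recover asymmetry to a daily stress multiplier.

    Waterlogging stress incurred at or after the sensitive stage (default
    R1) accumulates as exposure in full-stress-equivalent days: each active
    day contributes its stress depth relative to the function's maximum
    depth at saturation (``1 - full_stress_y``), so a day at the function's
    floor counts as one full day.  The effective multiplier is capped at
    ``1 - persistence * min(1, exposure / saturation_days)`` for the rest of
    the season: persistent damage (lost leaf area and nodule function)
    deepens with total flooded time and saturates once cumulative exposure
    reaches ``recovery_saturation_days``.  Stress incurred before the
    sensitive stage accrues no exposure, so the plant recovers fully from
    vegetative floods.
    """
    carry = carry.copy()
    if flood_active and stage_code >= params.stage.sensitive_stage_start:
        max_depth = max(1e-9, 1.0 - full_stress_y)
        carry.exposure += min(1.0, (1.0 - stress_today) / max_depth)
    damage = params.recovery_persistence * min(
        1.0, carry.exposure / params.recovery_saturation_days
    )
    return min(stress_today, 1.0 - damage), carry


# Per-y-parameter standard deviations used by the sensitivity analysis.
# The interior/terminal y values of each function are perturbed; the shipped
# default reflects the spread of per-environment calibrations and is
# user-overridable.
DEFAULT_SD_TABLE: dict[str, tuple[float, ...]] = {
    "photo": (0.0, 0.05, 0.05),
    "pheno": (0.0, 0.05, 0.05),
    "fix": (0.0, 0.05, 0.0),  # the x=1 anchor (y=0) is never adjusted
}


def perturb_params(
    params: OxdefParams,
    which_function: str,
    n_sd: int,
    sd_table: dict[str, tuple[float, ...]] | None = None,
) -> OxdefParams:
    """Return a copy of ``params`` with one function's y values shifted by
    ``n_sd`` standard deviations (clamped to [0, 1]; the fixation y(1) = 0
    anchor is held fixed)."""
    if which_function not in ("photo", "pheno", "fix"):
        raise ValueError(f"unknown oxdef function: {which_function!r}")
    table = dict(DEFAULT_SD_TABLE)
    if sd_table:
        table.update(sd_table)
    fn: PiecewiseMultiplier = getattr(params, which_function)
    sds = table[which_function]
    if len(sds) != len(fn.ys):
        raise ValueError("sd_table entry length must match the function's y count")
    ys = [min(1.0, max(0.0, y + n_sd * sd)) for y, sd in zip(fn.ys, sds)]
    if which_function == "fix":
        ys[-1] = 0.0  # saturated-soil anchor: fixation stops, never adjusted
    # keep left-anchor unity so unflooded soil stays stress-free
    ys[0] = fn.ys[0]
    for i in range(1, len(ys)):
        if ys[i] > ys[i - 1] and fn.ys[i] <= fn.ys[i - 1]:
            warnings.warn(
                "perturbation would break monotone non-increasing ys; clamping",
                stacklevel=2,
            )
            ys[i] = ys[i - 1]
    return replace(params, **{which_function: PiecewiseMultiplier(fn.xs, tuple(ys))})
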