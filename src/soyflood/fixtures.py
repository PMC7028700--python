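"""Synthetic study environments: representative soil profiles, cultivar
presets and seeded weather climates emulating the kinds of sites where
soybean flooding experiments have been run (a mid-South-US heavy clay, a
mid-South silt loam, and an Iowa silty clay with periodic waterlogging).

Hydraulic values are representative textbook values for the named soil
textures, not survey-database profiles; each fixture pins a base seed so
simulation experiments are reproducible offline.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .crop import MG_PRESETS, CultivarParams
from .engine import FloodTreatment, SimConfig
from .soil import SoilLayer, SoilProfile
from .weather import ClimateParams, WeatherSeries, generate_synthetic_weather

__all__ = ["FixtureSet", "clay_fixture", "silt_loam_fixture", "iowa_fixture", "all_fixtures"]


@dataclass(frozen=True)
class FixtureSet:
    """A named study environment: soil, cultivar, climate, management."""

    name: str
    profile: SoilProfile
    cultivar: CultivarParams
    climate: ClimateParams
    sowing_doy: int
    base_seed: int
    flood_stages: tuple[str, ...] = ("V4", "R2")
    flood_durations: tuple[int, ...] = (2, 4, 7, 14)
    periodic_windows: tuple[tuple[int, int], ...] = ()  # (start DOY, duration d)
    initial_mineral_n: float = 50.0
    mineralization_rate: float = 1.0
    auto_irrigate: bool = True  # the emulated trials were water-replete between floods

    def weather(self, n_years: int = 1, seed: int = 0, start_year: int = 2001) -> WeatherSeries:
        """Seeded synthetic weather; ``seed`` offsets the fixture base seed
        so different experiment replicates draw different years."""
        return generate_synthetic_weather(
            self.climate, (self.base_seed + 7919 * seed) % (2**31 - 1), n_years, start_year
        )

    def make_config(
        self,
        n_years: int = 1,
        seed: int = 0,
        start_year: int = 2001,
        enable_oxdef: bool = True,
        **overrides,
    ) -> SimConfig:
        return SimConfig(
            weather=self.weather(n_years, seed, start_year),
            profile=self.profile,
            cultivar=self.cultivar,
            sowing_doy=self.sowing_doy,
            enable_oxdef=enable_oxdef,
            initial_mineral_n=self.initial_mineral_n,
            mineralization_rate=self.mineralization_rate,
            auto_irrigate=self.auto_irrigate,
            seed=seed,
            **overrides,
        )

    def periodic_treatments(self, year: int) -> tuple[FloodTreatment, ...]:
        """Calendar-triggered flooding episodes (periodic waterlogging)."""
        return tuple(
            FloodTreatment(dt.date(year, 1, 1) + dt.timedelta(days=doy - 1), dur)
            for doy, dur in self.periodic_windows
        )


def _mid_south_climate() -> ClimateParams:
    return ClimateParams(
        tmax_mean=22.5,
        tmax_amp=10.5,
        tmin_mean=10.5,
        tmin_amp=10.0,
        radn_mean=15.0,
        radn_amp=10.0,
        peak_doy=199,
        temp_sd=2.5,
        monthly_rain_mm=(100, 110, 130, 130, 130, 95, 105, 80, 80, 100, 120, 130),
        wet_day_freq=(0.32, 0.32, 0.32, 0.30, 0.30, 0.30, 0.30, 0.28, 0.26, 0.25, 0.30, 0.32),
    )


def _iowa_climate() -> ClimateParams:
    return ClimateParams(
        tmax_mean=16.0,
        tmax_amp=15.5,
        tmin_mean=4.5,
        tmin_amp=14.5,
        radn_mean=14.5,
        radn_amp=9.0,
        peak_doy=199,
        temp_sd=3.0,
        monthly_rain_mm=(20, 25, 55, 95, 120, 130, 115, 110, 80, 70, 45, 30),
        wet_day_freq=(0.20, 0.20, 0.26, 0.30, 0.32, 0.30, 0.28, 0.27, 0.25, 0.24, 0.22, 0.20),
    )


def clay_fixture() -> FixtureSet:
    """Heavy clay: high field capacity, narrow dul-sat gap, slow subsoil
    drainage so perched water tables form readily after large rain events."""
    profile = SoilProfile(
        (
            SoilLayer(150, 0.24, 0.38, 0.45, 1.35, ks=15.0, kl=0.10),
            SoilLayer(150, 0.24, 0.38, 0.45, 1.38, ks=8.0, kl=0.09),
            SoilLayer(300, 0.25, 0.39, 0.46, 1.40, ks=3.0, kl=0.07),
            SoilLayer(300, 0.25, 0.39, 0.46, 1.42, ks=1.5, kl=0.05),
            SoilLayer(300, 0.26, 0.40, 0.46, 1.45, ks=1.2, kl=0.03),
            SoilLayer(300, 0.26, 0.40, 0.46, 1.45, ks=1.0, kl=0.02),
        ),
        pond_capacity=2.0,
    )
    return FixtureSet(
        name="clay",
        profile=profile,
        cultivar=MG_PRESETS["MG4"],
        climate=_mid_south_climate(),
        sowing_doy=130,
        base_seed=11,
        initial_mineral_n=50.0,
    )


def silt_loam_fixture() -> FixtureSet:
    """Silt loam over a dense claypan subsoil: the surface horizons hold a
    wider dul-sat gap and drain fast, but percolation through the pan is
    slow, so sustained wet spells perch a table at moderate depth.  The same
    flood designs produce milder penalties than on the clay."""
    profile = SoilProfile(
        (
            SoilLayer(150, 0.15, 0.30, 0.42, 1.40, ks=60.0, kl=0.10),
            SoilLayer(150, 0.15, 0.30, 0.42, 1.42, ks=45.0, kl=0.09),
            SoilLayer(300, 0.16, 0.31, 0.42, 1.45, ks=8.0, kl=0.07),
            SoilLayer(300, 0.20, 0.34, 0.42, 1.52, ks=2.0, kl=0.05),
            SoilLayer(300, 0.20, 0.34, 0.42, 1.52, ks=1.2, kl=0.03),
            SoilLayer(300, 0.20, 0.34, 0.42, 1.52, ks=0.8, kl=0.02),
        ),
        pond_capacity=0.8,
    )
    return FixtureSet(
        name="silt_loam",
        profile=profile,
        cultivar=MG_PRESETS["MG4"],
        climate=_mid_south_climate(),
        sowing_doy=130,
        base_seed=22,
        initial_mineral_n=55.0,
    )


def iowa_fixture() -> FixtureSet:
    """Iowa-like silty clay, MG3 cultivar, cooler climate, with a periodic
    waterlogging treatment (three calendar-scheduled episodes)."""
    profile = SoilProfile(
        (
            SoilLayer(150, 0.20, 0.35, 0.44, 1.35, ks=20.0, kl=0.10),
            SoilLayer(150, 0.20, 0.35, 0.44, 1.38, ks=10.0, kl=0.09),
            SoilLayer(300, 0.21, 0.36, 0.44, 1.40, ks=4.0, kl=0.07),
            SoilLayer(300, 0.22, 0.36, 0.45, 1.42, ks=3.0, kl=0.05),
            SoilLayer(300, 0.22, 0.37, 0.45, 1.45, ks=2.0, kl=0.03),
            SoilLayer(300, 0.22, 0.37, 0.45, 1.45, ks=1.5, kl=0.02),
        ),
        pond_capacity=0.8,
    )
    return FixtureSet(
        name="iowa",
        profile=profile,
        cultivar=MG_PRESETS["MG3"],
        climate=_iowa_climate(),
        sowing_doy=135,
        base_seed=33,
        periodic_windows=((170, 4), (190, 4), (210, 4)),
        initial_mineral_n=60.0,
        mineralization_rate=1.2,
    )


def all_fixtures() -> list[FixtureSet]:
    return [clay_fixture(), silt_loam_fixture(), iowa_fixture()]
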