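"""Structured-text (YAML) run configuration: load/save soil profiles,
cultivars, stress parameters and full run configs.

A run config has sections ``weather``, ``soil``, ``cultivar``, ``oxdef``,
``treatment``, ``scenario`` and ``run``; every stress x/y pair is
overridable from the file, and ``oxdef.enable: false`` restores the
original (drought-only) model.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import yaml

from . import fixtures as fx
from .crop import MG_PRESETS, CultivarParams
from .engine import FloodTreatment, SimConfig
from .soil import SoilLayer, SoilProfile
from .stress import OxdefParams, PiecewiseMultiplier, StageSeverity
from .weather import ClimateScenario, WeatherSeries, read_weather, write_weather

__all__ = [
    "load_config",
    "profile_from_dict",
    "profile_to_dict",
    "cultivar_from_dict",
    "oxdef_from_dict",
    "scenario_from_dict",
    "write_fixture_files",
]

LAYER_FIELDS = ("thickness", "ll15", "dul", "sat", "bd", "ks", "kl")


def profile_from_dict(d: dict) -> SoilProfile:
    layers = []
    for i, ld in enumerate(d["layers"]):
        try:
            layers.append(SoilLayer(**{k: float(ld[k]) for k in LAYER_FIELDS}))
        except (KeyError, ValueError) as e:
            raise ValueError(f"soil layer {i + 1}: {e}") from e
    return SoilProfile(tuple(layers), pond_capacity=float(d.get("pond_capacity", 0.0)))


def profile_to_dict(profile: SoilProfile) -> dict:
    return {
        "pond_capacity": profile.pond_capacity,
        "layers": [{k: getattr(l, k) for k in LAYER_FIELDS} for l in profile.layers],
    }


def cultivar_from_dict(d: dict) -> CultivarParams:
    if "preset" in d:
        base = MG_PRESETS[d["preset"]]
        over = {k: v for k, v in d.items() if k != "preset"}
        if "tt_targets" in over:
            over["tt_targets"] = tuple(over["tt_targets"])
        return dataclasses.replace(base, **over)
    d = dict(d)
    if "tt_targets" in d:
        d["tt_targets"] = tuple(d["tt_targets"])
    return CultivarParams(**d)


def cultivar_to_dict(c: CultivarParams) -> dict:
    d = dataclasses.asdict(c)
    d["tt_targets"] = list(d["tt_targets"])
    return d


def oxdef_from_dict(d: dict) -> OxdefParams:
    kw = {}
    for fn in ("photo", "pheno", "fix"):
        if fn in d:
            kw[fn] = PiecewiseMultiplier(tuple(d[fn]["xs"]), tuple(d[fn]["ys"]))
    if "stage" in d:
        kw["stage"] = StageSeverity(**d["stage"])
    for k in ("fix_activation_depth", "recovery_persistence"):
        if k in d:
            kw[k] = float(d[k])
    return OxdefParams(**kw)


def oxdef_to_dict(p: OxdefParams) -> dict:
    return {
        "photo": {"xs": list(p.photo.xs), "ys": list(p.photo.ys)},
        "pheno": {"xs": list(p.pheno.xs), "ys": list(p.pheno.ys)},
        "fix": {"xs": list(p.fix.xs), "ys": list(p.fix.ys)},
        "stage": dataclasses.asdict(p.stage),
        "fix_activation_depth": p.fix_activation_depth,
        "recovery_persistence": p.recovery_persistence,
    }


def scenario_from_dict(d: dict) -> ClimateScenario:
    return ClimateScenario(
        kind=d.get("kind", "none"),
        months=frozenset(d.get("months", [])),
        scale_factor=float(d.get("scale_factor", 1.0)),
        event_depth=float(d.get("event_depth", 0.0)),
        events_per_month=int(d.get("events_per_month", 0)),
        name=d.get("name", ""),
    )


def _treatment_from_dict(d: dict) -> FloodTreatment:
    trig = d["trigger"]
    if isinstance(trig, str):
        try:
            trig = dt.date.fromisoformat(trig)
        except ValueError:
            pass  # stage label
    return FloodTreatment(trig, int(d["duration_days"]))


def load_config(path: str | Path, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a YAML run-config file.

    The weather section either names a file (``path`` + ``dialect``) or a
    built-in fixture climate (``fixture`` + ``n_years`` [+ ``start_year``]).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    run = raw.get("run", {})
    seed = seed if seed is not None else int(run.get("seed", 0))

    w = raw["weather"]
    if "path" in w:
        wpath = Path(w["path"])
        if not wpath.is_absolute():
            wpath = path.parent / wpath
        weather = read_weather(wpath, w.get("dialect", "csv"))
    elif "fixture" in w:
        fixture = {f.name: f for f in fx.all_fixtures()}[w["fixture"]]
        weather = fixture.weather(
            int(w.get("n_years", 1)), seed, int(w.get("start_year", 2001))
        )
    else:
        raise ValueError("weather section needs 'path' or 'fixture'")

    profile = profile_from_dict(raw["soil"])
    cultivar = cultivar_from_dict(raw["cultivar"])
    oxdef_raw = raw.get("oxdef", {})
    enable = bool(oxdef_raw.get("enable", True))
    oxdef = oxdef_from_dict(oxdef_raw)
    treatments = tuple(_treatment_from_dict(t) for t in raw.get("treatment", []) or [])
    scenario = scenario_from_dict(raw["scenario"]) if raw.get("scenario") else None

    return SimConfig(
        weather=weather,
        profile=profile,
        cultivar=cultivar,
        sowing_doy=int(run.get("sowing_doy", 130)),
        enable_oxdef=enable,
        oxdef=oxdef,
        treatments=treatments,
        scenario=scenario,
        auto_irrigate=bool(run.get("auto_irrigate", False)),
        initial_mineral_n=float(run.get("initial_mineral_n", 50.0)),
        mineralization_rate=float(run.get("mineralization_rate", 1.0)),
        denit_rate=float(run.get("denit_rate", 0.015)),
        seed=seed,
    )


def write_fixture_files(fixture: fx.FixtureSet, out_dir: str | Path,
                        n_years: int = 1, seed: int = 0) -> dict[str, Path]:
    """Write a fixture's soil, cultivar, weather and run-config files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "soil": out / "soil.yaml",
        "cultivar": out / "cultivar.yaml",
        "weather": out / "weather.csv",
        "config": out / "config.yaml",
    }
    paths["soil"].write_text(yaml.safe_dump(profile_to_dict(fixture.profile), sort_keys=False))
    paths["cultivar"].write_text(yaml.safe_dump(cultivar_to_dict(fixture.cultivar), sort_keys=False))
    write_weather(fixture.weather(n_years, seed), paths["weather"], "csv")
    cfg = {
        "weather": {"path": "weather.csv", "dialect": "csv"},
        "soil": profile_to_dict(fixture.profile),
        "cultivar": cultivar_to_dict(fixture.cultivar),
        "oxdef": {"enable": True, **oxdef_to_dict(OxdefParams())},
        "run": {
            "sowing_doy": fixture.sowing_doy,
            "seed": seed,
            "auto_irrigate": fixture.auto_irrigate,
            "initial_mineral_n": fixture.initial_mineral_n,
            "mineralization_rate": fixture.mineralization_rate,
        },
    }
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths
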